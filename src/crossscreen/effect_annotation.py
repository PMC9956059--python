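"""Miniature variant-effect annotator and HGVS substitution toolkit.

Covers exactly what the candidate-narrowing chain needs: classify each
screened site as intergenic / non-coding / CDS against intronless-or-spliced
toy gene models, and for CDS sites emit the HGVS coding change ("c.652A>G"),
the codon change and the three-letter protein change ("Thr218Ala") under the
standard genetic code, with an effect class (missense, synonymous,
stop_gained, stop_lost, stop_retained, start_lost).

The parsers accept both the compact spelling "c.349G>T" and the spaced
spelling "c.652A > G" seen in published tables; emission always uses the
compact form.  A coding position and a residue number are mutually
consistent when residue = ((pos − 1) div 3) + 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import GeneModelError, HgvsParseError, JoinError, ReferenceMismatchError
from .formats_io import VariantSite
from .mendelian_screen import ScreenDecision

EFFECT_CLASSES = ("missense", "synonymous", "stop_gained", "stop_lost",
                  "stop_retained", "start_lost")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

_AA3 = {seq3(a) for a in "ACDEFGHIKLMNPQRSTVWY"} | {"Ter"}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One transcript: ordered CDS intervals on a scaffold, 1-based inclusive."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_intervals: tuple[tuple[int, int], ...]  # ascending genomic order

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = 0
        for start, end in self.cds_intervals:
            if start < 1 or end < start:
                raise GeneModelError(
                    f"{self.transcript_id}: bad interval ({start}, {end})")
            if start <= prev_end:
                raise GeneModelError(
                    f"{self.transcript_id}: intervals overlap or out of order")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.transcript_id}: CDS length {self.cds_length} not a "
                f"multiple of 3")

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_intervals)

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to the 1-based spliced CDS coordinate."""
        offset = 0
        for start, end in self.cds_intervals:
            if start <= pos <= end:
                plus_pos = offset + (pos - start) + 1
                if self.strand == "+":
                    return plus_pos
                return self.cds_length - plus_pos + 1
            offset += end - start + 1
        return None

    def spliced_cds(self, reference: Mapping[str, str]) -> str:
        seq = "".join(reference[self.chrom][s - 1:e] for s, e in self.cds_intervals)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(frozen=True)
class CodingChange:
    """A single-base substitution in spliced CDS coordinates."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise HgvsParseError(f"coding position must be >= 1, got {self.pos}")
        for base in (self.ref, self.alt):
            if base not in "ACGT":
                raise HgvsParseError(f"invalid base {base!r}")
        if self.ref == self.alt:
            raise HgvsParseError(f"ref equals alt ({self.ref}) at c.{self.pos}")

    def __str__(self) -> str:
        return f"c.{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class ProteinChange:
    """A residue substitution in three-letter code; 'Ter' is the stop."""

    residue: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise HgvsParseError(f"residue number must be >= 1, got {self.residue}")
        for aa in (self.ref, self.alt):
            if aa not in _AA3:
                raise HgvsParseError(f"unknown residue code {aa!r}")

    @property
    def effect(self) -> str:
        return classify_effect(self.ref, self.alt, self.residue)

    def __str__(self) -> str:
        return f"{self.ref}{self.residue}{self.alt}"


@dataclass(frozen=True)
class EffectRecord:
    """Annotation outcome for one site against one (or no) gene model."""

    chrom: str
    pos: int
    region: str  # intergenic | non_coding | CDS
    gene_id: str | None = None
    transcript_id: str | None = None
    coding_change: str | None = None
    codon_change: str | None = None
    protein_change: str | None = None
    effect: str | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


# ---------------------------------------------------------------------------
# Parsing and classification
# ---------------------------------------------------------------------------

_HGVS_C_RE = re.compile(r"^c\.(\d+)\s*([ACGT])\s*>\s*([ACGT])$")
_HGVS_P_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_hgvs_c(text: str) -> CodingChange:
    """Parse an HGVS coding substitution, spaced or compact spelling."""
    m = _HGVS_C_RE.match(text.strip())
    if not m:
        raise HgvsParseError(f"not an HGVS coding substitution: {text!r}")
    return CodingChange(int(m.group(1)), m.group(2), m.group(3))


def parse_protein_change(text: str) -> ProteinChange:
    """Parse a three-letter protein substitution like 'Thr218Ala' or 'Ter287Ter'."""
    m = _HGVS_P_RE.match(text.strip())
    if not m:
        raise HgvsParseError(f"not a protein substitution: {text!r}")
    return ProteinChange(int(m.group(2)), m.group(1), m.group(3))


def classify_effect(ref_aa: str, alt_aa: str, residue: int) -> str:
    """Effect class as a pure function of the residue pair (three-letter codes)."""
    if ref_aa == alt_aa:
        return "stop_retained" if ref_aa == "Ter" else "synonymous"
    if alt_aa == "Ter":
        return "stop_gained"
    if ref_aa == "Ter":
        return "stop_lost"
    if residue == 1 and ref_aa == "Met":
        return "start_lost"
    return "missense"


def check_consistency(coding: CodingChange, protein: ProteinChange
                      ) -> tuple[bool, str]:
    """Does the coding position fall in the codon of the stated residue?"""
    expected = (coding.pos - 1) // 3 + 1
    if expected == protein.residue:
        return True, f"c.{coding.pos} lies in codon {expected}"
    return False, (f"c.{coding.pos} lies in codon {expected}, "
                   f"but protein change names residue {protein.residue}")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "Ter"
    return seq3(_STANDARD_TABLE.forward_table[codon])


def read_gene_models(path) -> list[GeneModel]:
    """Load gene models from the TSV format (one CDS interval per row)."""
    from .formats_io import read_gene_model_table

    df = read_gene_model_table(path)
    models = []
    for (gene, tx), sub in df.groupby(["gene_id", "transcript_id"], sort=False):
        sub = sub.sort_values("cds_start")
        strands = set(sub["seqid"]), set(sub["strand"])
        if len(strands[0]) != 1 or len(strands[1]) != 1:
            raise GeneModelError(f"{tx}: intervals on mixed scaffolds or strands")
        models.append(GeneModel(
            gene_id=str(gene), transcript_id=str(tx),
            chrom=sub["seqid"].iloc[0], strand=sub["strand"].iloc[0],
            cds_intervals=tuple(zip(sub["cds_start"], sub["cds_end"])),
        ))
    return models


def annotate_variant(
    site: VariantSite,
    models: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> EffectRecord:
    """Annotate one biallelic site against the gene models.

    Region is CDS when the position falls inside a model's CDS interval,
    non_coding when inside the model's genomic span but between CDS
    intervals, intergenic otherwise.  For CDS sites the genomic change is
    mapped to spliced-CDS coordinates (reverse-complemented on '-' models)
    and the ref/alt codons are translated with the standard genetic code.
    """
    ref_base_genome = reference[site.chrom][site.pos - 1]
    if site.ref != ref_base_genome:
        raise ReferenceMismatchError(
            f"{site.chrom}:{site.pos}: VCF REF {site.ref} != reference "
            f"{ref_base_genome}"
        )
    hit = None
    for model in models:
        if model.chrom != site.chrom:
            continue
        if model.contains(site.pos):
            hit = model
            break
        lo, hi = model.span
        if lo <= site.pos <= hi:
            return EffectRecord(site.chrom, site.pos, "non_coding",
                                model.gene_id, model.transcript_id)
    if hit is None:
        return EffectRecord(site.chrom, site.pos, "intergenic")

    cds_pos = hit.genomic_to_cds(site.pos)
    cds_seq = hit.spliced_cds(reference)
    ref_base, alt_base = site.ref, site.alts[0]
    if hit.strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        ref_base, alt_base = ref_base.translate(comp), alt_base.translate(comp)
    if cds_seq[cds_pos - 1] != ref_base:
        raise ReferenceMismatchError(
            f"{hit.transcript_id}: spliced CDS base {cds_seq[cds_pos - 1]} at "
            f"c.{cds_pos} != strand-adjusted REF {ref_base}"
        )
    coding = CodingChange(cds_pos, ref_base, alt_base)
    codon_idx = (cds_pos - 1) // 3
    within = (cds_pos - 1) % 3
    ref_codon = cds_seq[3 * codon_idx: 3 * codon_idx + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    protein = ProteinChange(codon_idx + 1, _translate_codon(ref_codon),
                            _translate_codon(alt_codon))
    return EffectRecord(
        site.chrom, site.pos, "CDS", hit.gene_id, hit.transcript_id,
        str(coding), f"{ref_codon}>{alt_codon}", str(protein), protein.effect,
    )


def annotate_all(
    sites: Iterable[VariantSite],
    models: Sequence[GeneModel],
    reference: Mapping[str, str],
) -> list[EffectRecord]:
    return [annotate_variant(s, models, reference) for s in sites]


# ---------------------------------------------------------------------------
# Narrowing
# ---------------------------------------------------------------------------

@dataclass
class NarrowResult:
    """Staged candidate sets: screened → exonic (CDS) → missense."""

    stage_pass: list[tuple[str, int]]
    stage_cds: list[tuple[str, int]]
    stage_missense: list[tuple[str, int]]
    per_chromosome: dict[str, int]      # screened candidates per scaffold
    effect_tally: dict[str, int]        # effect classes among exonic candidates

    @property
    def stage_sizes(self) -> tuple[int, int, int]:
        return (len(self.stage_pass), len(self.stage_cds),
                len(self.stage_missense))


def narrow_candidates(
    decisions: Sequence[ScreenDecision],
    effects: Sequence[EffectRecord],
) -> NarrowResult:
    """Intersect screen passes with annotation: all → CDS → missense.

    Every passing site must be annotated; orphans on either side of the join
    raise :class:`JoinError`.
    """
    effect_by_key = {e.key: e for e in effects}
    decision_keys = {d.key for d in decisions}
    orphans = [d.key for d in decisions
               if d.passed and d.key not in effect_by_key]
    if orphans:
        raise JoinError(f"{len(orphans)} passing sites lack annotation: "
                        f"{orphans[:5]}")
    extra = [k for k in effect_by_key if k not in decision_keys]
    if extra:
        raise JoinError(f"{len(extra)} annotated sites were never screened: "
                        f"{extra[:5]}")

    stage_pass = [d.key for d in decisions if d.passed]
    stage_cds = [k for k in stage_pass if effect_by_key[k].region == "CDS"]
    stage_missense = [k for k in stage_cds
                      if effect_by_key[k].effect == "missense"]

    per_chromosome: dict[str, int] = {}
    for chrom, _ in stage_pass:
        per_chromosome[chrom] = per_chromosome.get(chrom, 0) + 1
    effect_tally: dict[str, int] = {}
    for k in stage_cds:
        eff = effect_by_key[k].effect or "unknown"
        effect_tally[eff] = effect_tally.get(eff, 0) + 1
    return NarrowResult(stage_pass, stage_cds, stage_missense,
                        per_chromosome, effect_tally)


def write_effects(effects: Iterable[EffectRecord], path) -> None:
    rows = [
        {"chrom": e.chrom, "pos": e.pos, "region": e.region,
         "gene_id": e.gene_id or ".", "transcript_id": e.transcript_id or ".",
         "coding_change": e.coding_change or ".",
         "codon_change": e.codon_change or ".",
         "protein_change": e.protein_change or ".",
         "effect": e.effect or "."}
        for e in effects
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_effects(path) -> list[EffectRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for r in df.itertuples(index=False):
        out.append(EffectRecord(
            chrom=r.chrom, pos=int(r.pos), region=r.region,
            gene_id=None if r.gene_id == "." else r.gene_id,
            transcript_id=None if r.transcript_id == "." else r.transcript_id,
            coding_change=None if r.coding_change == "." else r.coding_change,
            codon_change=None if r.codon_change == "." else r.codon_change,
            protein_change=None if r.protein_change == "." else r.protein_change,
            effect=None if r.effect == "." else r.effect,
        ))
    return out
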