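"""Readers and writers for every format the pipeline touches.

Formats: multi-sample VCF v4.2 (GT only), sample-group manifest TSV, gene
models as a GFF3-like TSV (1-based inclusive CDS intervals), reference FASTA,
truth-table TSV, screen-decision and candidate TSVs, and the two packaged
fixtures transcribed from the source study's printed tables (sequencing QC
statistics; the 39 candidate-SNP HGVS records).

Conventions: all coordinates are 1-based inclusive; genotypes are unordered
(0/1 == 1/0); only GT is consumed from VCF; thousands separators in fixtures
are stripped on load, percent columns are kept as printed text.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    FixtureIntegrityError,
    FormatError,
    ManifestError,
    VcfParseError,
)

VALID_GROUPS = ("founder", "F2", "F3")


# ---------------------------------------------------------------------------
# Core value types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genotype:
    """One diploid call as a pair of allele indices, unordered; or missing.

    Allele indices refer to the site's allele list (0 = REF, 1 = first ALT).
    A missing call carries no indices: ``Genotype(None, None)``.
    """

    a1: int | None
    a2: int | None

    def __post_init__(self) -> None:
        if (self.a1 is None) != (self.a2 is None):
            raise ValueError("half-missing genotypes are not supported")
        if self.a1 is not None and self.a2 is not None and self.a1 > self.a2:
            # normalise so 1/0 == 0/1 under dataclass equality/hash
            lo, hi = self.a2, self.a1
            object.__setattr__(self, "a1", lo)
            object.__setattr__(self, "a2", hi)

    @classmethod
    def missing(cls) -> "Genotype":
        return cls(None, None)

    @property
    def is_missing(self) -> bool:
        return self.a1 is None

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.a1 != self.a2

    def is_hom(self, allele: int) -> bool:
        return self.a1 == allele and self.a2 == allele

    def to_vcf(self) -> str:
        if self.is_missing:
            return "./."
        return f"{self.a1}/{self.a2}"


MISSING = Genotype.missing()


@dataclass(frozen=True)
class VariantSite:
    """One variant record: coordinates, alleles and per-sample genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref in self.alts:
            raise ValueError(f"REF {self.ref!r} duplicated in ALT at {self.chrom}:{self.pos}")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class CandidateRecord:
    """One row of the candidate-SNP table: locus plus HGVS coding/protein change."""

    snp_id: str
    chrom: str
    pos: int
    gene_id: str
    transcript_id: str
    coding_change: str   # HGVS c., verbatim as printed
    protein_change: str  # three-letter p. notation without the "p." prefix


@dataclass(frozen=True)
class QcSampleRecord:
    """Per-sample sequencing summary counts with percent columns as printed."""

    sample: str
    total_reads: int
    unaligned_reads: int
    unaligned_pct_text: str
    uniquely_aligned_reads: int
    uniquely_aligned_pct_text: str
    clean_paired_reads: int
    gc_pct_text: str
    q30_pct_text: str

    def __post_init__(self) -> None:
        if min(self.total_reads, self.unaligned_reads,
               self.uniquely_aligned_reads, self.clean_paired_reads) < 0:
            raise ValueError(f"negative read count for sample {self.sample}")
        if self.unaligned_reads + self.uniquely_aligned_reads > self.total_reads:
            raise ValueError(
                f"unaligned + uniquely aligned exceeds total reads for {self.sample}"
            )

    @property
    def q30_value(self) -> float:
        return float(self.q30_pct_text.rstrip("%"))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[list[VariantSite], list[str]]:
    """Read a VCF into :class:`VariantSite` records plus the sample order.

    Both ``/`` and ``|`` genotype separators are accepted; phasing is
    discarded.  Multiallelic records are retained (``is_biallelic`` False).
    Raises :class:`VcfParseError` on malformed input and :class:`FormatError`
    when a record carries no GT.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    samples = list(vcf.header.samples)
    sites: list[VariantSite] = []
    try:
        for rec in vcf:
            if "GT" not in rec.format:
                raise FormatError(
                    f"{path}:{rec.chrom}:{rec.pos}: record has no GT field"
                )
            genos: dict[str, Genotype] = {}
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or any(a is None for a in gt):
                    genos[s] = MISSING
                elif len(gt) != 2:
                    raise VcfParseError(
                        f"{path}:{rec.chrom}:{rec.pos}: non-diploid GT for {s}: {gt}"
                    )
                else:
                    genos[s] = Genotype(gt[0], gt[1])
            alts = tuple(rec.alts) if rec.alts else ()
            try:
                sites.append(
                    VariantSite(rec.chrom, rec.pos, rec.ref, alts, genos)
                )
            except ValueError as exc:
                raise VcfParseError(f"{path}:{rec.chrom}:{rec.pos}: {exc}") from exc
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed record: {exc}") from exc
    finally:
        vcf.close()
    return sites, samples


def write_vcf(
    sites: Sequence[VariantSite],
    samples: Sequence[str],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic-or-not sites as a minimal VCF v4.2 with GT only."""
    path = Path(path)
    contigs: dict[str, int] = dict(contig_lengths or {})
    for site in sites:
        contigs.setdefault(site.chrom, 0)
        contigs[site.chrom] = max(contigs[site.chrom], site.pos)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=crossscreen\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for site in sites:
            gts = "\t".join(site.genotypes.get(s, MISSING).to_vcf() for s in samples)
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{','.join(site.alts)}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> dict[str, str]:
    """Read the two-column (sample_id, group) manifest TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["sample_id", "group"]
    if list(df.columns) != expected:
        raise ManifestError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ManifestError(f"{path}: samples listed twice: {dups}")
    bad = sorted(set(df["group"]) - set(VALID_GROUPS))
    if bad:
        raise ManifestError(f"{path}: unknown groups {bad}; expected {VALID_GROUPS}")
    return dict(zip(df["sample_id"], df["group"]))


def write_manifest(manifest: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in manifest.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# Gene models / reference / truth table
# ---------------------------------------------------------------------------

GENE_MODEL_COLUMNS = ["gene_id", "transcript_id", "seqid", "strand", "cds_start", "cds_end"]


def write_gene_models(rows: Iterable[tuple], path: str | Path) -> None:
    """Write one CDS interval per row (multi-interval transcripts span rows)."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(GENE_MODEL_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_gene_model_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str,
                                            "seqid": str, "strand": str})
    if list(df.columns) != GENE_MODEL_COLUMNS:
        raise FormatError(f"{path}: expected columns {GENE_MODEL_COLUMNS}")
    return df


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "founder_allele": str,
                                              "planted_class": str})


# ---------------------------------------------------------------------------
# Decisions / candidates round-trip TSVs
# ---------------------------------------------------------------------------

DECISION_COLUMNS = ["chrom", "pos", "passed", "founder_allele", "reason"]
CANDIDATE_COLUMNS = ["snp_id", "chrom", "pos", "gene_id", "transcript_id",
                     "coding_change", "protein_change"]


def write_decisions(decisions: Iterable, path: str | Path) -> None:
    """Write screen decisions as TSV in the fixed documented column order."""
    with Path(path).open("w") as fh:
        fh.write("\t".join(DECISION_COLUMNS) + "\n")
        for d in decisions:
            allele = d.founder_allele if d.founder_allele is not None else "."
            fh.write(f"{d.chrom}\t{d.pos}\t{int(d.passed)}\t{allele}\t{d.reason}\n")


def read_decisions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "founder_allele": str,
                                            "reason": str})
    if list(df.columns) != DECISION_COLUMNS:
        raise FormatError(f"{path}: expected columns {DECISION_COLUMNS}")
    return df


def write_candidates(records: Iterable[CandidateRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.gene_id}\t"
                     f"{r.transcript_id}\t{r.coding_change}\t{r.protein_change}\n")


def read_candidates(path: str | Path) -> list[CandidateRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != CANDIDATE_COLUMNS:
        raise FormatError(f"{path}: expected columns {CANDIDATE_COLUMNS}")
    return [
        CandidateRecord(r.snp_id, r.chrom, int(r.pos), r.gene_id,
                        r.transcript_id, r.coding_change, r.protein_change)
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed printed tables, checksum-audited)
# ---------------------------------------------------------------------------

def _fixture_text(name: str) -> str:
    ref = resources.files("crossscreen.data").joinpath(name)
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise FixtureIntegrityError(f"packaged fixture {name} is missing") from exc
    sums = resources.files("crossscreen.data").joinpath("fixtures.sha256").read_text()
    expected = dict(line.split()[::-1] for line in sums.strip().splitlines())
    digest = hashlib.sha256(text.encode()).hexdigest()
    if expected.get(name) != digest:
        raise FixtureIntegrityError(
            f"fixture {name} checksum {digest} != recorded {expected.get(name)}"
        )
    return text


def _parse_int(text: str) -> int:
    return int(text.replace(",", ""))


def load_table3_fixture() -> list[CandidateRecord]:
    """The 39 candidate-SNP records (locus, gene, HGVS c. and p. columns)."""
    lines = _fixture_text("candidate_snps.tsv").strip().splitlines()
    header = lines[0].split("\t")
    records = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        records.append(
            CandidateRecord(
                snp_id=row["snp_id"],
                chrom=row["chrom"],
                pos=_parse_int(row["pos"]),
                gene_id=row["gene_id"],
                transcript_id=row["transcript_id"],
                coding_change=row["coding_change"],
                protein_change=row["protein_change"],
            )
        )
    return records


def load_table2_fixture() -> list[QcSampleRecord]:
    """The 15 per-sample sequencing summary rows (counts plus printed percents)."""
    lines = _fixture_text("sequencing_stats.tsv").strip().splitlines()
    header = lines[0].split("\t")
    records = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        records.append(
            QcSampleRecord(
                sample=row["sample"],
                total_reads=_parse_int(row["total_reads"]),
                unaligned_reads=_parse_int(row["unaligned_reads"]),
                unaligned_pct_text=row["unaligned_pct"],
                uniquely_aligned_reads=_parse_int(row["uniquely_aligned_reads"]),
                uniquely_aligned_pct_text=row["uniquely_aligned_pct"],
                clean_paired_reads=_parse_int(row["clean_paired_reads"]),
                gc_pct_text=row["gc_pct"],
                q30_pct_text=row["q30_pct"],
            )
        )
    return records
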