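"""Synthetic two-breed cross simulator with planted candidate-pattern sites.

The simulator emulates the study design the screen assumes: a purebred
founder population (Zhedong-like, "ZD"), a second breed (Zi-like, "ZI"),
F1 hybrids from ZD × ZI matings, F2 from F1 intercrosses and F3 from F2
intercrosses.  Five birds per sequenced group (founder, F2, F3) are sampled
by default.  Sites are independent (free recombination), biallelic, and fall
into two planted classes recorded in a truth table:

candidate
    Fixed for allele A in every ZD founder and allele B in every ZI founder.
    Mendelian segregation in an F2 intercross still produces B/B with
    probability 1/4, so the candidate *pattern* (founders homozygous A, no
    offspring B/B, at least one heterozygote) is enforced on the sequenced
    sets by per-site rejection sampling of the transmissions, mirroring the
    empirical pattern the screen selects for.

background
    Segregating within the ZD founder population (allele frequency drawn
    uniformly from a configurable band, Hardy–Weinberg genotypes in both
    breeds).  Each background site is conditioned, again by per-site
    rejection, to violate the screen pattern on the clean sequenced set —
    a founder heterozygote or mixed homozygotes, or an offspring homozygous
    for the non-founder allele — so that with zero noise the screen's
    false-positive set against the truth table is empty by construction.

Observation noise is applied after breeding: each emitted genotype is
independently dropped to missing, else perturbed to a uniformly chosen
different diploid genotype.

A single integer seed drives everything through four sub-streams (founders,
breeding/rejection, noise, genome layout) spawned in fixed order, so an
identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import formats_io
from .errors import ConfigError, PedigreeError, RejectionError
from .formats_io import Genotype, VariantSite

GENERATIONS = ("ZD", "ZI", "F1", "F2", "F3")
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic cross.

    ``n_background_sites`` is derived (= n_sites − n_candidate_sites); the
    background allele-frequency band keeps background sites informative
    (neither near-fixed nor degenerate).
    """

    n_sites: int = 10_000
    n_candidate_sites: int = 60
    samples_per_group: int = 5
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    n_chromosomes: int = 3
    seed: int = 0
    background_freq_range: tuple[float, float] = (0.2, 0.8)
    cds_fraction: float = 0.3
    rejection_cap: int = 1000
    group_prefixes: tuple[str, str, str] = ("C", "B", "O")

    @property
    def n_background_sites(self) -> int:
        return self.n_sites - self.n_candidate_sites

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if not 0 <= self.n_candidate_sites <= self.n_sites:
            raise ConfigError("n_candidate_sites must be in [0, n_sites]")
        if self.samples_per_group < 1:
            raise ConfigError("samples_per_group must be >= 1")
        for name in ("genotype_error_rate", "missing_rate", "cds_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.background_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ConfigError("background_freq_range must satisfy 0 < lo <= hi < 1")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.rejection_cap < 1:
            raise ConfigError("rejection_cap must be >= 1")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None
    dam: str | None
    generation: str


@dataclass(frozen=True)
class Pedigree:
    """Ordered pedigree (parents precede offspring) plus sequenced sample ids."""

    individuals: tuple[Individual, ...]
    sequenced: Mapping[str, tuple[str, ...]]  # group -> sample ids

    def validate(self) -> None:
        seen: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.generation not in GENERATIONS:
                raise PedigreeError(f"{ind.id}: unknown generation {ind.generation!r}")
            founderish = ind.generation in ("ZD", "ZI")
            if founderish != (ind.sire is None and ind.dam is None):
                raise PedigreeError(f"{ind.id}: parent/generation mismatch")
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    if parent not in seen:
                        raise PedigreeError(
                            f"{ind.id}: parent {parent!r} unknown or declared later"
                        )
                    expected = {"F1": ("ZD", "ZI"), "F2": ("F1",), "F3": ("F2",)}
                    if seen[parent].generation not in expected[ind.generation]:
                        raise PedigreeError(
                            f"{ind.id}: parent {parent} has generation "
                            f"{seen[parent].generation}, invalid for {ind.generation}"
                        )
            if ind.id in seen:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            seen[ind.id] = ind
        for group, ids in self.sequenced.items():
            for sid in ids:
                if sid not in seen:
                    raise PedigreeError(f"sequenced sample {sid!r} not in pedigree")

    def by_generation(self, generation: str) -> list[str]:
        return [i.id for i in self.individuals if i.generation == generation]


def default_pedigree(config: SimConfig) -> Pedigree:
    """Build the stock pedigree: ZD/ZI founders, F1, F2, F3, round-robin matings.

    Sequenced ids follow the study's prefixes (C = founder Zhedong, B = F2,
    O = F3); the ZI founders breed but are not sequenced.
    """
    spg = config.samples_per_group
    c, b, o = config.group_prefixes
    n_zd = n_zi = spg + 2
    n_f1 = 6
    n_f2 = n_f3 = spg + 3

    zd = [Individual(f"{c}{401 + i}", None, None, "ZD") for i in range(n_zd)]
    zi = [Individual(f"Z{101 + i}", None, None, "ZI") for i in range(n_zi)]
    f1 = [Individual(f"F1_{i + 1}", zd[i % n_zd].id, zi[i % n_zi].id, "F1")
          for i in range(n_f1)]
    f2 = [Individual(f"{b}{311 + i}", f1[i % n_f1].id, f1[(i + 1) % n_f1].id, "F2")
          for i in range(n_f2)]
    f3 = [Individual(f"{o}{1101 + i}", f2[i % n_f2].id, f2[(i + 1) % n_f2].id, "F3")
          for i in range(n_f3)]
    ped = Pedigree(
        individuals=tuple(zd + zi + f1 + f2 + f3),
        sequenced={
            "founder": tuple(i.id for i in zd[:spg]),
            "F2": tuple(i.id for i in f2[:spg]),
            "F3": tuple(i.id for i in f3[:spg]),
        },
    )
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def simulate_founders(
    config: SimConfig, rng: np.random.Generator | None = None,
    pedigree: Pedigree | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Draw founder allele pairs per site and the site truth table.

    Internal allele coding: 0 is the ZD-attributed allele "A" at candidate
    sites (fixed in ZD, fixed-opposite in ZI); at background sites alleles
    are arbitrary labels with Hardy–Weinberg genotypes at a per-site
    frequency drawn from ``background_freq_range``.

    Returns ``(genotypes, truth)`` where genotypes maps founder id to an
    ``(n_sites, 2)`` int8 array and truth has one row per site with columns
    site_index, planted_class and founder_allele_index, plus the per-site
    background frequency used (NaN at candidate sites).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pedigree = pedigree or default_pedigree(config)
    n = config.n_sites
    cand_idx = np.sort(rng.choice(n, size=config.n_candidate_sites, replace=False))
    is_cand = np.zeros(n, dtype=bool)
    is_cand[cand_idx] = True

    lo, hi = config.background_freq_range
    freq_b = rng.uniform(lo, hi, size=n)  # frequency of allele 1
    freq_b[is_cand] = np.nan

    genotypes: dict[str, np.ndarray] = {}
    for ind in pedigree.individuals:
        if ind.generation == "ZD":
            g = (rng.random((n, 2)) < freq_b[:, None]).astype(np.int8)
            g[is_cand] = 0
            genotypes[ind.id] = g
        elif ind.generation == "ZI":
            g = (rng.random((n, 2)) < freq_b[:, None]).astype(np.int8)
            g[is_cand] = 1
            genotypes[ind.id] = g

    truth = pd.DataFrame(
        {
            "site_index": np.arange(n),
            "planted_class": np.where(is_cand, "candidate", "background"),
            "founder_allele_index": np.zeros(n, dtype=int),
            "background_freq": freq_b,
        }
    )
    return genotypes, truth


# ---------------------------------------------------------------------------
# Breeding with per-site conditioning
# ---------------------------------------------------------------------------

def _transmit(
    genotypes: dict[str, np.ndarray],
    pedigree: Pedigree,
    rng: np.random.Generator,
    site_idx: np.ndarray,
) -> None:
    """(Re)draw Mendelian transmissions at the given site columns, in place."""
    k = len(site_idx)
    rows = np.arange(k)
    for ind in pedigree.individuals:
        if ind.sire is None:
            continue
        child = genotypes.setdefault(
            ind.id, np.zeros_like(next(iter(genotypes.values())))
        )
        for slot, parent in enumerate((ind.sire, ind.dam)):
            if parent not in genotypes:
                raise PedigreeError(f"{ind.id}: no genotypes for parent {parent!r}")
            pg = genotypes[parent][site_idx]
            child[site_idx, slot] = pg[rows, rng.integers(0, 2, size=k)]


def _stack(genotypes: dict[str, np.ndarray], ids: Sequence[str],
           site_idx: np.ndarray | None = None) -> np.ndarray:
    mats = [genotypes[i] if site_idx is None else genotypes[i][site_idx] for i in ids]
    return np.stack(mats, axis=0)  # (n_ind, k, 2)


def _pattern_masks(founder: np.ndarray, offspring: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (conforms, segregates) under the screen pattern, noise-free.

    conforms: founders uniformly homozygous for one allele and no offspring
    homozygous for the other.  segregates: >=1 heterozygous offspring.
    """
    a = founder[0, :, 0]
    uniform = np.all(founder == a[None, :, None], axis=(0, 2))
    hom_other = np.any(np.all(offspring == (1 - a)[None, :, None], axis=2), axis=0)
    het = np.any(offspring[:, :, 0] != offspring[:, :, 1], axis=0)
    return uniform & ~hom_other, het


def breed(
    pedigree: Pedigree,
    founder_genotypes: dict[str, np.ndarray],
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Breed every non-founder by per-site gamete draws, then condition.

    Candidate sites are redrawn until the sequenced founder/F2/F3 sets show
    the full candidate pattern (founders homozygous A, no offspring B/B, at
    least one heterozygote); background sites are redrawn until they violate
    it.  Raises :class:`RejectionError` past ``config.rejection_cap`` retries.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genotypes = {k: v.copy() for k, v in founder_genotypes.items()}
    n = config.n_sites
    all_sites = np.arange(n)
    _transmit(genotypes, pedigree, rng, all_sites)

    is_cand = (truth["planted_class"] == "candidate").to_numpy()
    seq_f = list(pedigree.sequenced["founder"])
    seq_off = list(pedigree.sequenced["F2"]) + list(pedigree.sequenced["F3"])
    lo, hi = config.background_freq_range
    freq_b = truth["background_freq"].to_numpy()

    pending = all_sites
    for attempt in range(config.rejection_cap + 1):
        founder = _stack(genotypes, seq_f, pending)
        offspring = _stack(genotypes, seq_off, pending)
        conforms, segregates = _pattern_masks(founder, offspring)
        cand = is_cand[pending]
        ok = np.where(cand, conforms & segregates, ~conforms)
        pending = pending[~ok]
        if len(pending) == 0:
            break
        if attempt == config.rejection_cap:
            raise RejectionError(
                f"{len(pending)} sites still unconditioned after "
                f"{config.rejection_cap} redraws (first: {pending[:5].tolist()})"
            )
        # background sites get fresh founder genotypes too (same frequency)
        bg_pending = pending[~is_cand[pending]]
        if len(bg_pending) > 0:
            p = freq_b[bg_pending]
            for ind in pedigree.individuals:
                if ind.generation in ("ZD", "ZI"):
                    genotypes[ind.id][bg_pending] = (
                        rng.random((len(bg_pending), 2)) < p[:, None]
                    ).astype(np.int8)
        _transmit(genotypes, pedigree, rng, pending)
    return genotypes


def mate(parent1: tuple[int, int], parent2: tuple[int, int],
         n_offspring: int, rng: np.random.Generator) -> np.ndarray:
    """Draw offspring allele pairs from two parent genotypes (one gamete each)."""
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    g1 = p1[rng.integers(0, 2, n_offspring)]
    g2 = p2[rng.integers(0, 2, n_offspring)]
    return np.stack([g1, g2], axis=1)


# ---------------------------------------------------------------------------
# Observation noise
# ---------------------------------------------------------------------------

def apply_noise(
    codes: np.ndarray, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Perturb a genotype-code matrix (0 = A/A, 1 = A/B, 2 = B/B).

    Each entry independently becomes missing (−1) with ``missing_rate``,
    else with ``genotype_error_rate`` is replaced by a uniformly chosen
    *different* diploid genotype.  Returns the observed matrix and a log of
    how many entries were dropped or perturbed.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    observed = codes.astype(np.int8).copy()
    miss = rng.random(codes.shape) < config.missing_rate
    err = (~miss) & (rng.random(codes.shape) < config.genotype_error_rate)
    shift = rng.integers(1, 3, size=codes.shape)
    observed[err] = ((observed[err] + shift[err]) % 3).astype(np.int8)
    observed[miss] = -1
    return observed, {"n_missing": int(miss.sum()), "n_errors": int(err.sum())}


# ---------------------------------------------------------------------------
# Genome layout and dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, in memory."""

    config: SimConfig
    pedigree: Pedigree
    sites: list[VariantSite]
    sample_order: list[str]
    manifest: dict[str, str]
    truth: pd.DataFrame
    gene_models: list[tuple]
    reference: dict[str, str]
    noise_log: dict[str, int]
    codes: np.ndarray  # observed genotype codes, (n_samples, n_sites)


_SITE_SPACING = 60


def _layout_genome(config: SimConfig, rng: np.random.Generator
                   ) -> tuple[list[str], np.ndarray, dict[str, str], list[tuple]]:
    """Assign sites to scaffolds, draw reference sequences and toy gene models.

    One intronless CDS per scaffold covers roughly ``cds_fraction`` of its
    sites; CDS length is padded to a codon multiple.  Returns per-site
    (chrom, pos) plus the reference and gene-model rows.
    """
    n = config.n_sites
    per_chrom = np.array_split(np.arange(n), config.n_chromosomes)
    chroms: list[str] = [""] * n
    pos = np.zeros(n, dtype=int)
    reference: dict[str, str] = {}
    gene_rows: list[tuple] = []
    for c, sites_here in enumerate(per_chrom, start=1):
        name = f"scaffold_{c}"
        m = len(sites_here)
        length = _SITE_SPACING * (m + 2) + 12
        seq = rng.choice(_BASES, size=length)
        positions = _SITE_SPACING * (np.arange(m) + 1)  # 1-based, spaced
        for j, site in enumerate(sites_here):
            chroms[site] = name
            pos[site] = positions[j]
        n_in_cds = int(round(config.cds_fraction * m))
        if n_in_cds > 0:
            first, last = positions[0], positions[n_in_cds - 1]
            start = max(1, first - 5)
            span = last + 5 - start + 1
            span += (-span) % 3
            end = start + span - 1  # always < length by construction
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"gene_{c}", f"tx_{c}", name, strand, start, end))
        reference[name] = "".join(seq)
    return chroms, pos, reference, gene_rows


_CODE_TO_PAIR = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: founders → breeding → noise → genome layout."""
    config.validate()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(4)]
    rng_founders, rng_breed, rng_noise, rng_layout = streams

    pedigree = default_pedigree(config)
    founder_genos, truth = simulate_founders(config, rng_founders, pedigree)
    genotypes = breed(pedigree, founder_genos, truth, config, rng_breed)

    sample_order = [s for g in ("founder", "F2", "F3")
                    for s in pedigree.sequenced[g]]
    manifest = {s: g for g in ("founder", "F2", "F3")
                for s in pedigree.sequenced[g]}
    clean = _stack(genotypes, sample_order)          # (n_samples, n_sites, 2)
    clean_codes = clean.sum(axis=2)                  # 0/1/2
    codes, noise_log = apply_noise(clean_codes, config, rng_noise)

    chroms, pos, reference, gene_rows = _layout_genome(config, rng_layout)

    # REF/ALT bases: REF is the base already present in the reference
    # sequence; the ZD allele "A" is assigned to REF or ALT by a fair coin so
    # downstream logic cannot lean on which allele is REF.
    n = config.n_sites
    swap = rng_layout.random(n) < 0.5  # True: internal allele 0 is ALT
    alt_offset = rng_layout.integers(1, 4, size=n)
    sites: list[VariantSite] = []
    truth_founder_base: list[str] = []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for i in range(n):
        ref_base = reference[chroms[i]][pos[i] - 1]
        alt_base = "ACGT"[(base_idx[ref_base] + alt_offset[i]) % 4]
        genos: dict[str, Genotype] = {}
        for s_i, sample in enumerate(sample_order):
            code = int(codes[s_i, i])
            a1, a2 = _CODE_TO_PAIR[code]
            if a1 is None:
                genos[sample] = Genotype.missing()
            elif swap[i]:
                genos[sample] = Genotype(1 - a1, 1 - a2)
            else:
                genos[sample] = Genotype(a1, a2)
        sites.append(VariantSite(chroms[i], int(pos[i]), ref_base, (alt_base,), genos))
        truth_founder_base.append(alt_base if swap[i] else ref_base)

    truth = truth.assign(
        chrom=chroms, pos=pos, founder_allele=truth_founder_base
    )[["site_index", "chrom", "pos", "planted_class", "founder_allele",
       "background_freq"]]
    return SimulatedDataset(
        config=config, pedigree=pedigree, sites=sites,
        sample_order=sample_order, manifest=manifest, truth=truth,
        gene_models=gene_rows, reference=reference, noise_log=noise_log,
        codes=codes,
    )


def emit_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset's files (VCF, manifest, gene models, FASTA, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "manifest": outdir / "manifest.tsv",
        "gene_models": outdir / "gene_models.tsv",
        "reference": outdir / "reference.fa",
        "truth": outdir / "truth.tsv",
    }
    contig_lengths = {name: len(seq) for name, seq in dataset.reference.items()}
    formats_io.write_vcf(dataset.sites, dataset.sample_order, paths["vcf"],
                         contig_lengths)
    formats_io.write_manifest(dataset.manifest, paths["manifest"])
    formats_io.write_gene_models(dataset.gene_models, paths["gene_models"])
    formats_io.write_fasta(dataset.reference, paths["reference"])
    formats_io.write_truth_table(dataset.truth, paths["truth"])
    return paths
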