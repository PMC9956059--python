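"""Per-site Mendelian-consistency screen over founder / F2 / F3 groups.

The screen keeps a biallelic site when the sequenced purebred founders are
uniformly homozygous for one allele (call it A), and every non-missing
offspring genotype in both hybrid generations is A/A or A/B — the pattern
expected when the alternate allele B entered only through the other parental
breed, so that a B/B offspring is impossible under Mendelian transmission from
homozygous-A founders crossed out once.

The alternate allele B is defined as the non-founder allele: it is never tied
to which allele happens to be REF in the VCF, so relabelling REF/ALT leaves
every decision unchanged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ManifestError
from .formats_io import Genotype, VariantSite

#: Reason codes in fixed violation-precedence order (PASS excluded).
REASONS = (
    "NON_BIALLELIC",
    "FOUNDER_MISSING_EXCESS",
    "FOUNDER_NOT_HOMOZYGOUS",
    "OFFSPRING_HOM_ALT",
    "NOT_SEGREGATING",
    "OFFSPRING_MISSING_EXCESS",
)

OFFSPRING_GROUPS = ("F2", "F3")


@dataclass(frozen=True)
class ScreenPolicy:
    """Tunable screen thresholds.

    require_segregation
        Demand at least one heterozygous offspring call, so sites invariant
        across every sequenced bird (uninformative for the cross) are dropped.
    max_founder_missing
        Missing founder calls tolerated before the site is rejected outright.
    max_offspring_missing
        Missing calls tolerated per offspring group; ``None`` means group
        size − 1 (at least one informative call per group).
    """

    require_segregation: bool = True
    max_founder_missing: int = 0
    max_offspring_missing: int | None = None


@dataclass(frozen=True)
class GroupGenotypeSummary:
    """Genotype class counts for one sample group at one site."""

    group: str
    n_hom: tuple[int, int]  # homozygote count per allele index (0-based)
    n_het: int
    n_missing: int
    n_other: int  # genotypes touching alleles beyond the first ALT
    uniform_hom_allele: int | None  # allele all non-missing calls are hom for

    @property
    def n_total(self) -> int:
        return sum(self.n_hom) + self.n_het + self.n_missing + self.n_other


@dataclass(frozen=True)
class ScreenDecision:
    """Outcome of the screen at one site."""

    chrom: str
    pos: int
    passed: bool
    founder_allele: str | None  # base fixed in the founder group, when inferable
    reason: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _group_samples(manifest: Mapping[str, str], group: str) -> list[str]:
    samples = [s for s, g in manifest.items() if g == group]
    if not samples:
        raise ManifestError(f"group {group!r} has no samples in the manifest")
    return samples


def summarize_group(
    site: VariantSite, manifest: Mapping[str, str], group: str
) -> GroupGenotypeSummary:
    """Count genotype classes for one group, treating calls as unordered."""
    if group not in set(manifest.values()):
        raise ManifestError(f"unknown group {group!r}")
    n_hom = [0, 0]
    n_het = n_missing = n_other = 0
    for sample in _group_samples(manifest, group):
        gt = site.genotypes.get(sample, Genotype.missing())
        if gt.is_missing:
            n_missing += 1
        elif gt.a1 > 1 or gt.a2 > 1:
            n_other += 1
        elif gt.a1 == gt.a2:
            n_hom[gt.a1] += 1
        else:
            n_het += 1
    uniform: int | None = None
    non_missing = sum(n_hom) + n_het + n_other
    for allele in (0, 1):
        if non_missing > 0 and n_hom[allele] == non_missing:
            uniform = allele
    return GroupGenotypeSummary(group, (n_hom[0], n_hom[1]), n_het,
                                n_missing, n_other, uniform)


def screen_site(
    site: VariantSite, manifest: Mapping[str, str], policy: ScreenPolicy | None = None
) -> ScreenDecision:
    """Classify one site; the first violated condition names the reason."""
    policy = policy or ScreenPolicy()

    if not site.is_biallelic:
        return ScreenDecision(site.chrom, site.pos, False, None, "NON_BIALLELIC")

    founders = summarize_group(site, manifest, "founder")
    if founders.n_missing > policy.max_founder_missing:
        return ScreenDecision(site.chrom, site.pos, False, None, "FOUNDER_MISSING_EXCESS")
    if founders.uniform_hom_allele is None:
        return ScreenDecision(site.chrom, site.pos, False, None, "FOUNDER_NOT_HOMOZYGOUS")

    allele_a = founders.uniform_hom_allele
    allele_b = 1 - allele_a
    founder_base = site.ref if allele_a == 0 else site.alts[0]

    offspring = [summarize_group(site, manifest, g) for g in OFFSPRING_GROUPS]
    if any(s.n_hom[allele_b] > 0 for s in offspring):
        return ScreenDecision(site.chrom, site.pos, False, founder_base, "OFFSPRING_HOM_ALT")
    if policy.require_segregation and sum(s.n_het for s in offspring) == 0:
        return ScreenDecision(site.chrom, site.pos, False, founder_base, "NOT_SEGREGATING")
    for summary in offspring:
        cap = (policy.max_offspring_missing
               if policy.max_offspring_missing is not None
               else summary.n_total - 1)
        if summary.n_missing > cap:
            return ScreenDecision(site.chrom, site.pos, False, founder_base,
                                  "OFFSPRING_MISSING_EXCESS")
    return ScreenDecision(site.chrom, site.pos, True, founder_base, "PASS")


def screen_all(
    sites: Iterable[VariantSite],
    manifest: Mapping[str, str],
    policy: ScreenPolicy | None = None,
) -> tuple[list[ScreenDecision], Counter]:
    """Screen every site in input order; also tally decisions per reason code."""
    policy = policy or ScreenPolicy()
    decisions = [screen_site(site, manifest, policy) for site in sites]
    tallies = Counter(d.reason for d in decisions)
    return decisions, tallies
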