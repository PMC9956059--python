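"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results from first principles (direct rule
evaluation, exact combinatorics) without calling the implementation paths
they are checked against.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def brute_screen_reason(
    founders: list[str],
    f2: list[str],
    f3: list[str],
    require_segregation: bool = True,
    max_founder_missing: int = 0,
    max_offspring_missing: int | None = None,
) -> str:
    """Direct evaluation of the screen rule on genotype mnemonics.

    Genotypes are 'RR', 'RA', 'AA' (hom-ref, het, hom-alt relative to the
    VCF allele order) or '..' (missing).  The founder allele is whichever
    single allele every non-missing founder is homozygous for.
    """
    def alleles(call: str) -> tuple[str, str] | None:
        return None if call == ".." else (call[0], call[1])

    f_calls = [alleles(c) for c in founders]
    n_f_missing = sum(c is None for c in f_calls)
    if n_f_missing > max_founder_missing:
        return "FOUNDER_MISSING_EXCESS"
    present = [c for c in f_calls if c is not None]
    hom_alleles = {c[0] for c in present if c[0] == c[1]}
    if not present or any(c[0] != c[1] for c in present) or len(hom_alleles) != 1:
        return "FOUNDER_NOT_HOMOZYGOUS"
    founder_allele = hom_alleles.pop()
    other = {"R": "A", "A": "R"}[founder_allele]

    offspring = [alleles(c) for c in f2 + f3]
    if any(c == (other, other) for c in offspring if c is not None):
        return "OFFSPRING_HOM_ALT"
    if require_segregation and not any(
        c is not None and c[0] != c[1] for c in offspring
    ):
        return "NOT_SEGREGATING"
    for group in (f2, f3):
        cap = (max_offspring_missing if max_offspring_missing is not None
               else len(group) - 1)
        if sum(c == ".." for c in group) > cap:
            return "OFFSPRING_MISSING_EXCESS"
    return "PASS"


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P[X >= k] as an exact rational by direct summation over the tail."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return Fraction(acc, total)
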