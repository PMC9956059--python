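"""Hypergeometric over-representation test for candidate-gene term enrichment.

The universe is gene-level, not SNP-level: several candidate SNPs in one gene
count once, avoiding pseudo-replication.  For each term with K annotated
genes in a universe of N, and a candidate set of n genes overlapping the term
in k, the p-value is the hypergeometric upper tail P[X >= k].  Results carry
both raw p and Benjamini–Hochberg q across the tested terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import EnrichmentDomainError


@dataclass(frozen=True)
class TermAnnotation:
    """One term and the genes annotated to it."""

    term_id: str
    term_name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # candidates annotated to the term
    n: int  # candidate-set size (within the universe)
    K: int  # term size
    N: int  # universe size
    p_value: float
    q_value: float


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise EnrichmentDomainError(f"require 0 <= K,n <= N; got k={k} n={n} K={K} N={N}")
    if not (0 <= k <= min(n, K)):
        raise EnrichmentDomainError(f"require 0 <= k <= min(n, K); got k={k} n={n} K={K}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def enrich_terms(
    candidate_genes: Collection[str],
    annotations: Sequence[TermAnnotation],
    universe: Collection[str],
) -> list[EnrichmentResult]:
    """Test every term for over-representation of the candidate genes.

    Candidates outside the universe are reported via a warning and dropped.
    Results are sorted by ascending p (ties by term id).
    """
    universe_set = set(universe)
    if not universe_set:
        raise EnrichmentDomainError("empty gene universe")
    candidates = set(candidate_genes)
    outside = candidates - universe_set
    if outside:
        warnings.warn(
            f"{len(outside)} candidate genes outside the universe were dropped: "
            f"{sorted(outside)[:5]}", stacklevel=2)
        candidates &= universe_set

    N = len(universe_set)
    n = len(candidates)
    raw: list[tuple[TermAnnotation, int, int, float]] = []
    for term in annotations:
        genes = term.genes & universe_set
        K = len(genes)
        k = len(genes & candidates)
        raw.append((term, k, K, hypergeom_upper_tail(k, n, K, N)))
    qvals = _bh_adjust([p for *_, p in raw])
    results = [
        EnrichmentResult(term.term_id, term.term_name, k, n, K, N, p, q)
        for (term, k, K, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def top_terms(results: Sequence[EnrichmentResult], limit: int = 25
              ) -> list[EnrichmentResult]:
    """The most significant terms (smallest p), the usual report length."""
    return list(results[:limit])


# ---------------------------------------------------------------------------
# I/O (GAF-like TSV: gene_id, term_id, term_name)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> tuple[list[TermAnnotation], set[str]]:
    """Load term annotations; the default universe is every gene in the file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["gene_id", "term_id", "term_name"]
    if list(df.columns) != expected:
        raise EnrichmentDomainError(f"{path}: expected columns {expected}")
    annotations = []
    for term_id, sub in df.groupby("term_id", sort=True):
        annotations.append(TermAnnotation(
            term_id=str(term_id),
            term_name=str(sub["term_name"].iloc[0]),
            genes=frozenset(sub["gene_id"]),
        ))
    return annotations, set(df["gene_id"])


def write_annotations(annotations: Iterable[TermAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\tterm_id\tterm_name\n")
        for term in annotations:
            for gene in sorted(term.genes):
                fh.write(f"{gene}\t{term.term_id}\t{term.term_name}\n")


def write_results(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {"term_id": r.term_id, "term_name": r.term_name, "k": r.k, "n": r.n,
         "K": r.K, "N": r.N, "p_value": f"{r.p_value:.6g}",
         "q_value": f"{r.q_value:.6g}"}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
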