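"""Alignment-summary arithmetic and sequencing quality gates.

Recomputes per-sample alignment percentages from raw read counts and applies
the study's QC gate (Q30 ≥ 80%).  Percentages are exact rationals internally;
formatting rounds half-even at six significant figures and strips trailing
zeros, the policy that reproduces every printed value in the packaged
sequencing-statistics fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal, localcontext
from fractions import Fraction
from typing import Iterable

from .errors import ConfigError
from .formats_io import QcSampleRecord


def format_sigfig(value: Fraction, sig: int = 6) -> str:
    """Format an exact rational to ``sig`` significant figures, half-even.

    Trailing zeros are stripped after rounding (printed-table convention);
    zero renders with full width, e.g. "0.00000" at six figures.
    """
    if value == 0:
        return "0." + "0" * (sig - 1)
    with localcontext() as ctx:
        ctx.prec = 60
        x = Decimal(value.numerator) / Decimal(value.denominator)
        q = x.quantize(Decimal(1).scaleb(x.adjusted() - sig + 1),
                       rounding=ROUND_HALF_EVEN)
    s = format(q, "f")
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s


@dataclass(frozen=True)
class QcReportRow:
    """Recomputed percentages for one sample, exact and formatted."""

    sample: str
    unaligned_pct: Fraction
    uniquely_aligned_pct: Fraction
    residual_pct: Fraction  # multi-mapped / otherwise unaccounted reads
    unaligned_pct_text: str
    uniquely_aligned_pct_text: str

    def __post_init__(self) -> None:
        total = self.unaligned_pct + self.uniquely_aligned_pct + self.residual_pct
        assert total == 100, f"percentages sum to {total}, not 100"


@dataclass(frozen=True)
class QcThresholds:
    min_q30_pct: float = 80.0
    min_clean_bases: int | None = None  # only checkable when read length known
    read_length: int | None = None


def alignment_percentages(record: QcSampleRecord, sig: int = 6) -> QcReportRow:
    """Exact unaligned / uniquely-aligned / residual percentages for one sample."""
    if record.total_reads == 0:
        raise ConfigError(f"{record.sample}: total_reads is zero")
    unaligned = Fraction(100 * record.unaligned_reads, record.total_reads)
    unique = Fraction(100 * record.uniquely_aligned_reads, record.total_reads)
    residual = Fraction(100) - unaligned - unique
    return QcReportRow(
        sample=record.sample,
        unaligned_pct=unaligned,
        uniquely_aligned_pct=unique,
        residual_pct=residual,
        unaligned_pct_text=format_sigfig(unaligned, sig),
        uniquely_aligned_pct_text=format_sigfig(unique, sig),
    )


def quality_gate(
    record: QcSampleRecord, thresholds: QcThresholds | None = None
) -> tuple[bool, list[str]]:
    """Apply the QC gate; returns (passed, failed-criterion names)."""
    thresholds = thresholds or QcThresholds()
    failures: list[str] = []
    if record.q30_value < thresholds.min_q30_pct:
        failures.append("Q30")
    if thresholds.min_clean_bases is not None and thresholds.read_length is not None:
        clean_bases = 2 * record.clean_paired_reads * thresholds.read_length
        if clean_bases < thresholds.min_clean_bases:
            failures.append("clean_bases")
    return (not failures, failures)


def qc_report(
    records: Iterable[QcSampleRecord], thresholds: QcThresholds | None = None
) -> list[dict]:
    """One report row per sample: recomputed percentages plus the gate verdict."""
    rows = []
    for rec in records:
        pct = alignment_percentages(rec)
        passed, reasons = quality_gate(rec, thresholds)
        rows.append({
            "sample": rec.sample,
            "total_reads": rec.total_reads,
            "unaligned_pct": pct.unaligned_pct_text,
            "uniquely_aligned_pct": pct.uniquely_aligned_pct_text,
            "q30_pct": rec.q30_pct_text,
            "qc_pass": passed,
            "qc_failures": ",".join(reasons) or ".",
        })
    return rows
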