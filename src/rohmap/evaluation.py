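"""Base-pair level comparison of a detected ROH set against a reference.

Sensitivity and specificity are asymmetric by construction: the reference is
size-filtered for sensitivity (only reference ROHs larger than 1 or 5 Mb —
the regions worth finding — enter the denominator), while the *test* set is
size-filtered for specificity (only confidently reported test ROHs are held
to account).  Assembly gap regions (centromeres, telomeres, short arms,
heterochromatin) are subtracted before size filtering, since no caller can
be scored inside them:

    sensitivity (%) = overlap(test_all, ref_filtered) / total(ref_filtered)
    specificity (%) = overlap(test_filtered, ref_all) / total(test_filtered)
    F-score         = 2 * sensitivity * specificity / (sensitivity + specificity)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genome_annotation import IntervalSet, load_bed
from .roh_detection import MB, ROH

__all__ = [
    "EvalResult",
    "rohs_to_intervals",
    "filter_rohs",
    "overlap_bp",
    "total_bp",
    "sensitivity",
    "specificity",
    "f_score",
    "evaluate",
    "load_roh_bed",
]


@dataclass
class EvalResult:
    """Per-sample evaluation summary (percentages, or None if undefined)."""

    sensitivity: float | None
    specificity: float | None
    f_score: float | None
    total_ref_bp: int
    total_test_bp: int
    overlap_bp: int


def rohs_to_intervals(rohs: list[ROH]) -> IntervalSet:
    """Union of ROHs as a merged 0-based half-open interval set."""
    return IntervalSet((r.chrom, r.start - 1, r.end) for r in rohs)


def _intervals_to_rohs(iset: IntervalSet) -> list[ROH]:
    return [ROH(chrom, s + 1, e) for chrom, s, e in iset]


def filter_rohs(
    rohs: list[ROH],
    min_size_mb: float,
    gaps: IntervalSet | None = None,
    strict: bool = True,
) -> list[ROH]:
    """Subtract gap regions, then keep fragments larger than ``min_size_mb``.

    Gap subtraction precedes the size threshold: a gap-spanning ROH's usable
    extent is what the size should measure.  ``strict=True`` (default) reads
    "larger than" literally (>); set False for >=.  Variant counts are not
    carried onto the fragments (they are only used for overlap accounting).
    """
    iset = rohs_to_intervals(rohs)
    if gaps is not None and not gaps.is_empty:
        iset = iset.subtract(gaps)
    thr = min_size_mb * MB
    out = []
    for roh in _intervals_to_rohs(iset):
        if roh.size > thr if strict else roh.size >= thr:
            out.append(roh)
    return out


def overlap_bp(a: list[ROH], b: list[ROH]) -> int:
    """Total base pairs in the intersection of the two ROH-set unions."""
    return rohs_to_intervals(a).intersection_bp(rohs_to_intervals(b))


def total_bp(rohs: list[ROH]) -> int:
    return rohs_to_intervals(rohs).total_bp()


def sensitivity(test_all: list[ROH], ref_filtered: list[ROH]) -> float | None:
    """Percent of the (filtered) reference recovered by the unfiltered test set.

    None when the filtered reference is empty (metric not applicable).
    """
    denom = total_bp(ref_filtered)
    if denom == 0:
        return None
    return 100.0 * overlap_bp(test_all, ref_filtered) / denom


def specificity(test_filtered: list[ROH], ref_all: list[ROH]) -> float | None:
    """Percent of the (filtered) test set backed by the unfiltered reference."""
    denom = total_bp(test_filtered)
    if denom == 0:
        return None
    return 100.0 * overlap_bp(test_filtered, ref_all) / denom


def f_score(sens: float | None, spec: float | None) -> float | None:
    """Harmonic mean of sensitivity and specificity (percent)."""
    if sens is None or spec is None:
        return None
    if sens + spec == 0:
        return 0.0
    return 2.0 * sens * spec / (sens + spec)


def evaluate(
    test_rohs: list[ROH],
    ref_rohs: list[ROH],
    gaps: IntervalSet | None = None,
    min_size_mb: float = 1.0,
    strict: bool = True,
) -> EvalResult:
    """Full evaluation of a test ROH set against a reference ROH set."""
    ref_filtered = filter_rohs(ref_rohs, min_size_mb, gaps, strict)
    test_filtered = filter_rohs(test_rohs, min_size_mb, gaps, strict)
    sens = sensitivity(test_rohs, ref_filtered)
    spec = specificity(test_filtered, ref_rohs)
    return EvalResult(
        sensitivity=sens,
        specificity=spec,
        f_score=f_score(sens, spec),
        total_ref_bp=total_bp(ref_filtered),
        total_test_bp=total_bp(test_filtered),
        overlap_bp=overlap_bp(test_rohs, ref_rohs),
    )


def load_roh_bed(path: str | Path) -> list[ROH]:
    """Read an ROH set from BED3 (e.g. a reference set exported upstream)."""
    return _intervals_to_rohs(load_bed(path))
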