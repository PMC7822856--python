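"""Detection, refinement and filtering of runs of homozygosity.

The core segmentation is a sliding window over consecutive (post-filter)
variant calls: a window of ``window`` variants passes when it holds at least
``windowthres`` homozygous calls; a variant is covered when it lies in at
least one passing window; maximal runs of covered variants become candidate
ROHs.  Candidates are then

* trimmed so both ends sit on homozygous variants,
* extended outward by up to ``extend`` Mb on each side — never past the
  chromosome end, and never across a surviving heterozygous call (which
  would re-admit exactly the evidence trimming removed); ROHs that meet
  after extension are merged,
* split wherever two consecutive member variants are more than ``maxgap``
  Mb apart (the variant-free stretch belongs to neither part),
* kept only if they reach a minimal size, variant count and percentage of
  homozygous variants.

chrX is excluded by default; when included, hemizygous calls (male X) count
as homozygous, and a female X is treated exactly like an autosome.  chrY and
the mitochondrial contig are never scanned.

All ROH coordinates are 1-based inclusive; ``size = end - start + 1``.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace

import numpy as np

from .genome_annotation import GenomeAnnotation
from .variant_filter import (
    FilterParams,
    FilterReport,
    apply_filters,
    assert_min_variants,
)
from .vcf_io import SampleTable, VariantCall, chrom_sort_key, normalize_chrom

__all__ = [
    "MB",
    "DetectionParams",
    "ROH",
    "seed_windows",
    "trim",
    "extend",
    "split_on_gaps",
    "final_filter",
    "detect",
    "detect_with_report",
    "infer_sex",
]

MB = 1_000_000


@dataclass
class DetectionParams:
    """Segmentation parameters (defaults are the standard settings).

    window / windowthres:
        sliding-window size in variants and the minimum number of
        homozygous variants for a window to pass.
    maxgap:
        maximum variant-free stretch tolerated inside an ROH (Mb).
    extend:
        maximum outward extension of each ROH boundary (Mb).
    minsize / minvar / minperc:
        final-filter thresholds: minimum size (Mb), minimum number of
        variants, minimum percentage of homozygous variants (all inclusive).
    include_chrX:
        scan chrX as well (hemizygous calls count as homozygous).
    """

    window: int = 7
    windowthres: int = 5
    maxgap: float = 10.0
    extend: float = 1.0
    minsize: float = 1.0
    minvar: int = 25
    minperc: float = 88.0
    include_chrX: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.windowthres <= self.window:
            raise ValueError("require 1 <= windowthres <= window")
        for name in ("maxgap", "extend", "minsize"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.minperc <= 100:
            raise ValueError("minperc must be in [0, 100]")
        if self.minvar < 0:
            raise ValueError("minvar must be >= 0")


@dataclass
class ROH:
    """One run of homozygosity (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    n_variants: int = 0
    n_homozygous: int = 0

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def perc_homozygous(self) -> float:
        if self.n_variants == 0:
            return 0.0
        return 100.0 * self.n_homozygous / self.n_variants

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"ROH end {self.end} < start {self.start}")


# ---------------------------------------------------------------------------
# per-chromosome index helpers


class _ChromIndex:
    """Sorted position / homozygosity arrays for one chromosome's calls."""

    def __init__(self, calls: list[VariantCall]):
        self.calls = calls
        self.pos = [c.pos for c in calls]
        self.hom = np.array([c.is_homozygous for c in calls], dtype=bool)
        self.het_pos = [c.pos for c in calls if not c.is_homozygous]

    def slice(self, start: int, end: int) -> tuple[int, int]:
        """Index range [i, j) of calls with start <= pos <= end."""
        return bisect_left(self.pos, start), bisect_right(self.pos, end)

    def counts(self, start: int, end: int) -> tuple[int, int]:
        i, j = self.slice(start, end)
        return j - i, int(self.hom[i:j].sum())


def _group_by_chrom(calls) -> dict[str, list[VariantCall]]:
    groups: dict[str, list[VariantCall]] = {}
    for c in calls:
        groups.setdefault(c.chrom, []).append(c)
    return groups


def _with_counts(roh: ROH, idx: _ChromIndex) -> ROH:
    n, h = idx.counts(roh.start, roh.end)
    return replace(roh, n_variants=n, n_homozygous=h)


# ---------------------------------------------------------------------------
# pipeline stages


def seed_windows(
    calls: SampleTable | list[VariantCall], params: DetectionParams
) -> list[ROH]:
    """Sliding-window seeding of candidate ROHs.

    Returns maximal runs of variants covered by at least one passing window,
    with boundaries at the first/last covered variant's position.  Windows
    never span chromosomes; a chromosome with fewer variants than ``window``
    yields no candidates.
    """
    out: list[ROH] = []
    for chrom in sorted(_group_by_chrom(calls), key=chrom_sort_key):
        chrom_calls = _group_by_chrom(calls)[chrom]
        out.extend(_seed_one_chrom(chrom, chrom_calls, params))
    return out


def _seed_one_chrom(
    chrom: str, chrom_calls: list[VariantCall], params: DetectionParams
) -> list[ROH]:
    n = len(chrom_calls)
    w = params.window
    if n < w:
        return []
    idx = _ChromIndex(chrom_calls)
    hom = idx.hom.astype(np.int64)
    wsum = np.convolve(hom, np.ones(w, dtype=np.int64), mode="valid")
    passing = wsum >= params.windowthres
    # covered[i] == variant i lies in >= 1 passing window; mark via a
    # difference array so the cost stays O(n)
    diff = np.zeros(n + 1, dtype=np.int64)
    starts = np.flatnonzero(passing)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + w, -1)
    covered = np.cumsum(diff[:-1]) > 0
    out: list[ROH] = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j + 1 < n and covered[j + 1]:
                j += 1
            roh = ROH(chrom, idx.pos[i], idx.pos[j])
            out.append(_with_counts(roh, idx))
            i = j + 1
        else:
            i += 1
    return out


def trim(
    candidate: ROH, calls: SampleTable | list[VariantCall]
) -> ROH | None:
    """Move both ends inward to the outermost homozygous variants.

    Returns None when the candidate holds no homozygous variant.
    """
    idx = _ChromIndex(
        [c for c in calls if normalize_chrom(c.chrom) == normalize_chrom(candidate.chrom)]
    )
    i, j = idx.slice(candidate.start, candidate.end)
    hom_idx = [k for k in range(i, j) if idx.hom[k]]
    if not hom_idx:
        return None
    roh = ROH(candidate.chrom, idx.pos[hom_idx[0]], idx.pos[hom_idx[-1]])
    return _with_counts(roh, idx)


def extend(
    rohs: list[ROH],
    calls: SampleTable | list[VariantCall],
    annot: GenomeAnnotation,
    params: DetectionParams,
) -> list[ROH]:
    """Extend each boundary outward by up to ``extend`` Mb; merge collisions.

    Extension stops early at the chromosome end and just inside the nearest
    surviving heterozygous variant outside the ROH, so no het call is ever
    swallowed.  ROHs that overlap or abut afterwards are merged and their
    variant counts recomputed.
    """
    ext = int(round(params.extend * MB))
    by_chrom = _group_by_chrom(calls)
    out: list[ROH] = []
    groups: dict[str, list[ROH]] = {}
    for roh in rohs:
        groups.setdefault(roh.chrom, []).append(roh)
    for chrom in sorted(groups, key=chrom_sort_key):
        idx = _ChromIndex(by_chrom.get(chrom, []))
        chrom_len = annot.length_of(chrom)
        extended: list[ROH] = []
        for roh in sorted(groups[chrom], key=lambda r: r.start):
            new_start = max(roh.start - ext, 1)
            k = bisect_left(idx.het_pos, roh.start)
            if k > 0:  # nearest het strictly below the ROH
                new_start = max(new_start, idx.het_pos[k - 1] + 1)
            new_end = min(roh.end + ext, chrom_len)
            k = bisect_right(idx.het_pos, roh.end)
            if k < len(idx.het_pos):  # nearest het strictly above
                new_end = min(new_end, idx.het_pos[k] - 1)
            extended.append(ROH(chrom, new_start, new_end))
        merged: list[ROH] = []
        for roh in extended:
            if merged and roh.start <= merged[-1].end + 1:
                merged[-1] = ROH(
                    chrom, merged[-1].start, max(merged[-1].end, roh.end)
                )
            else:
                merged.append(roh)
        out.extend(_with_counts(r, idx) for r in merged)
    return out


def split_on_gaps(
    rohs: list[ROH],
    calls: SampleTable | list[VariantCall],
    params: DetectionParams,
) -> list[ROH]:
    """Split ROHs at variant-free stretches longer than ``maxgap`` Mb.

    The split happens at the flanking variants' positions; the empty stretch
    belongs to neither part.
    """
    maxgap = params.maxgap * MB
    by_chrom = _group_by_chrom(calls)
    out: list[ROH] = []
    for roh in rohs:
        idx = _ChromIndex(by_chrom.get(roh.chrom, []))
        i, j = idx.slice(roh.start, roh.end)
        positions = idx.pos[i:j]
        if len(positions) < 2:
            out.append(_with_counts(roh, idx))
            continue
        piece_start = roh.start
        for a, b in zip(positions, positions[1:]):
            if b - a > maxgap:
                out.append(_with_counts(ROH(roh.chrom, piece_start, a), idx))
                piece_start = b
        out.append(_with_counts(ROH(roh.chrom, piece_start, roh.end), idx))
    return out


def final_filter(rohs: list[ROH], params: DetectionParams) -> list[ROH]:
    """Keep ROHs meeting all of minsize, minvar, minperc (inclusive)."""
    minsize_bp = params.minsize * MB
    return [
        r
        for r in rohs
        if r.size >= minsize_bp
        and r.n_variants >= params.minvar
        and r.perc_homozygous >= params.minperc - 1e-9
    ]


# ---------------------------------------------------------------------------
# composition


def _scanned_chroms(table: SampleTable, include_chrX: bool) -> list[str]:
    skip = {"Y", "M", "MT"} | (set() if include_chrX else {"X"})
    return [c for c in table.chromosomes() if normalize_chrom(c) not in skip]


def infer_sex(table: SampleTable) -> str:
    """Heuristic sex call from chrX heterozygosity (< 5% het -> male).

    Informational only: detection itself is genotype-driven (hemizygous
    calls always count as homozygous).  Returns 'male', 'female' or
    'unknown' when chrX carries no calls.
    """
    x_calls = table.calls_for("X")
    if not x_calls:
        return "unknown"
    het = sum(1 for c in x_calls if c.is_het)
    return "male" if het / len(x_calls) < 0.05 else "female"


def detect_with_report(
    table: SampleTable,
    annot: GenomeAnnotation,
    filter_params: FilterParams | None = None,
    det_params: DetectionParams | None = None,
) -> tuple[list[ROH], FilterReport]:
    """Full pipeline; returns the ROH list plus the filter report.

    Raises :class:`~rohmap.variant_filter.InsufficientVariantsError` when
    fewer than ``min_surviving_variants`` calls survive filtering.
    """
    fp = filter_params or FilterParams()
    dp = det_params or DetectionParams()

    chroms = _scanned_chroms(table, dp.include_chrX)
    keep = set(chroms)
    table = table.subset(c for c in table.calls if c.chrom in keep)

    table, report = apply_filters(table, annot.repeats, fp)
    assert_min_variants(table, fp)

    candidates: list[ROH] = []
    by_chrom = _group_by_chrom(table.calls)
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        chrom_calls = by_chrom[chrom]
        for cand in _seed_one_chrom(chrom, chrom_calls, dp):
            trimmed = trim(cand, chrom_calls)
            if trimmed is not None:
                candidates.append(trimmed)

    rohs = extend(candidates, table.calls, annot, dp)
    rohs = split_on_gaps(rohs, table.calls, dp)
    rohs = final_filter(rohs, dp)
    rohs.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start))
    return rohs, report


def detect(
    table: SampleTable,
    annot: GenomeAnnotation,
    filter_params: FilterParams | None = None,
    det_params: DetectionParams | None = None,
) -> list[ROH]:
    """Detect runs of homozygosity in one sample's variant table."""
    rohs, _ = detect_with_report(table, annot, filter_params, det_params)
    return rohs
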