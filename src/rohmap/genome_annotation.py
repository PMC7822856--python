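"""Interval resources the detector and the evaluation depend on.

Three tracks matter: repeat regions (variants inside them are unreliable and
removed before detection), assembly gap regions (centromeres, telomeres,
short arms, heterochromatin — excluded from performance accounting), and
chromosome lengths (bounding ROH extension).

All internal interval arithmetic is 0-based half-open (the BED convention);
every user-facing coordinate is 1-based inclusive (the VCF convention).  The
conversion happens in exactly one place each way: :meth:`IntervalSet.contains`
(query side) and the ROH/BED writers (output side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .vcf_io import chrom_sort_key, normalize_chrom

__all__ = ["IntervalSet", "GenomeAnnotation", "load_bed", "load_chrom_lengths"]


class IntervalSet:
    """Per-chromosome sorted, merged, half-open intervals [start, end)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        raw: dict[str, list[tuple[int, int]]] = {}
        self._names: dict[str, str] = {}  # normalized -> first-seen spelling
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(
                    f"invalid interval {chrom}:{start}-{end} (end <= start)"
                )
            key = normalize_chrom(chrom)
            self._names.setdefault(key, chrom)
            raw.setdefault(key, []).append((int(start), int(end)))
        self._data: dict[str, np.ndarray] = {
            key: _merge(ivs) for key, ivs in raw.items()
        }

    # -- construction ------------------------------------------------------

    @classmethod
    def _from_arrays(
        cls, data: dict[str, np.ndarray], names: dict[str, str]
    ) -> "IntervalSet":
        out = cls()
        out._data = {k: v for k, v in data.items() if len(v)}
        out._names = dict(names)
        return out

    # -- queries -----------------------------------------------------------

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        arr = self._data.get(normalize_chrom(chrom))
        if arr is None or not len(arr):
            return False
        p0 = pos - 1  # the single 1-based -> 0-based conversion point
        i = int(np.searchsorted(arr[:, 0], p0, side="right")) - 1
        return i >= 0 and p0 < arr[i, 1]

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        arr = self._data.get(normalize_chrom(chrom))
        return [] if arr is None else [(int(s), int(e)) for s, e in arr]

    def chromosomes(self) -> list[str]:
        keys = sorted(self._data, key=chrom_sort_key)
        return [self._names.get(k, k) for k in keys]

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for key in sorted(self._data, key=chrom_sort_key):
            name = self._names.get(key, key)
            for s, e in self._data[key]:
                yield name, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def total_bp(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._data.values())
        )

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    # -- set algebra -------------------------------------------------------

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        data: dict[str, np.ndarray] = {}
        for key, a in self._data.items():
            b = other._data.get(key)
            if b is None:
                continue
            ivs = _intersect(a, b)
            if len(ivs):
                data[key] = ivs
        return IntervalSet._from_arrays(data, self._names)

    def intersection_bp(self, other: "IntervalSet") -> int:
        return self.intersect(other).total_bp()

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        data: dict[str, np.ndarray] = {}
        for key, a in self._data.items():
            b = other._data.get(key)
            ivs = a if b is None else _subtract(a, b)
            if len(ivs):
                data[key] = np.asarray(ivs)
        return IntervalSet._from_arrays(data, self._names)


def _merge(intervals: list[tuple[int, int]]) -> np.ndarray:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def _intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((int(s), int(e)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = int(s)
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, int(b[k, 0])))
            cur = max(cur, int(b[k, 1]))
            k += 1
        if cur < e:
            out.append((cur, int(e)))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def load_bed(path: str | Path) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into a merged IntervalSet."""
    intervals: list[tuple[str, int, int]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append((chrom, start, end))
    return IntervalSet(intervals)


def load_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (name, length) table; keys are normalized names."""
    lengths: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need name and length")
            lengths[normalize_chrom(parts[0])] = int(parts[1])
    return lengths


@dataclass
class GenomeAnnotation:
    """Repeat regions, assembly gaps, chromosome lengths."""

    repeats: IntervalSet = field(default_factory=IntervalSet)
    gaps: IntervalSet = field(default_factory=IntervalSet)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @classmethod
    def load(
        cls,
        repeats: str | Path | None = None,
        gaps: str | Path | None = None,
        chrom_lengths: str | Path | None = None,
    ) -> "GenomeAnnotation":
        return cls(
            repeats=load_bed(repeats) if repeats else IntervalSet(),
            gaps=load_bed(gaps) if gaps else IntervalSet(),
            chrom_lengths=(
                load_chrom_lengths(chrom_lengths) if chrom_lengths else {}
            ),
        )

    def length_of(self, chrom: str) -> int:
        key = normalize_chrom(chrom)
        try:
            return self.chrom_lengths[key]
        except KeyError:
            raise KeyError(
                f"no length recorded for chromosome {chrom!r}; the "
                "chromosome-length table must cover every chromosome with "
                "candidate ROHs"
            ) from None
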