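"""Variant-level quality filtering.

WES genotype calls carry a sizeable fraction of false heterozygous calls
(mapping and capture artifacts).  Inside a truly autozygous segment a single
surviving false het can fragment one ROH into several, or hide it entirely,
so calls are removed *individually* before any segmentation:

1. calls in repeat regions (unreliable mapping);
2. calls below a minimum total depth (default 8 reads);
3. heterozygous calls whose alt-read fraction falls outside the allele-balance
   band [0.25, 0.75] — true hets cluster near 0.5, artifacts skew toward
   0 or 1;
4. heterozygous calls failing an exact two-sided binomial test of
   alt vs. ref read counts against p=0.5 (default threshold 1e-6).

Homozygous and hemizygous calls are subject only to the depth criterion.
If fewer than 10,000 calls survive, the sample is judged uninformative and
the analysis stops.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from scipy.stats import binomtest

from .genome_annotation import IntervalSet
from .vcf_io import SampleTable, VariantCall, Zygosity

__all__ = [
    "FilterParams",
    "FilterReport",
    "InsufficientVariantsError",
    "binomial_two_sided_p",
    "remove_repeat_variants",
    "quality_filter",
    "apply_filters",
    "assert_min_variants",
]


class InsufficientVariantsError(RuntimeError):
    """Too few variants survive filtering for a reliable analysis."""

    def __init__(self, surviving: int, required: int):
        self.surviving = surviving
        self.required = required
        super().__init__(
            f"insufficient variants: {surviving} survive filtering but at "
            f"least {required} are required"
        )


@dataclass
class FilterParams:
    """Variant-filter thresholds (defaults are the standard settings).

    min_depth:
        minimum total read depth, inclusive (reads).
    min_alt_fraction / max_alt_fraction:
        inclusive allele-balance band applied to heterozygous calls.
    binomial_p:
        heterozygous calls with a two-sided binomial p-value *below* this
        are removed.
    min_surviving_variants:
        hard stop if fewer calls survive all variant-level filters.
    binomial_alternative:
        'two-sided' (default) or 'less'/'greater' for a one-sided variant.
    """

    min_depth: int = 8
    min_alt_fraction: float = 0.25
    max_alt_fraction: float = 0.75
    binomial_p: float = 1e-6
    min_surviving_variants: int = 10_000
    binomial_alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 <= self.min_alt_fraction < self.max_alt_fraction <= 1:
            raise ValueError(
                "require 0 <= min_alt_fraction < max_alt_fraction <= 1"
            )
        if not 0 < self.binomial_p < 1:
            raise ValueError("binomial_p must be in (0, 1)")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.binomial_alternative not in ("two-sided", "less", "greater"):
            raise ValueError("binomial_alternative must be two-sided/less/greater")


@dataclass
class FilterReport:
    """Per-reason removal counts; reasons + surviving == input."""

    n_input: int = 0
    removed_repeat: int = 0
    removed_depth: int = 0
    removed_alt_fraction: int = 0
    removed_binomial: int = 0
    removed_missing: int = 0
    surviving: int = 0

    def conserved(self) -> bool:
        return (
            self.removed_repeat
            + self.removed_depth
            + self.removed_alt_fraction
            + self.removed_binomial
            + self.removed_missing
            + self.surviving
            == self.n_input
        )

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


@lru_cache(maxsize=100_000)
def _binom_p(alt_reads: int, total_reads: int, alternative: str) -> float:
    return binomtest(alt_reads, total_reads, 0.5, alternative=alternative).pvalue


def binomial_two_sided_p(
    alt_reads: int, total_reads: int, alternative: str = "two-sided"
) -> float:
    """Exact binomial test p-value for alt vs. ref read counts at p=0.5.

    Two-sided value is the sum of the probabilities of all outcomes no more
    probable than the observed one (pmf summation).
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError("alt_reads must be in [0, total_reads]")
    return _binom_p(alt_reads, total_reads, alternative)


def remove_repeat_variants(
    table: SampleTable, repeats: IntervalSet
) -> tuple[SampleTable, int]:
    """Drop calls located in repeat regions; returns (table, n_removed)."""
    kept = [
        c for c in table.calls if not repeats.contains(c.chrom, c.pos)
    ]
    return table.subset(kept), len(table) - len(kept)


def _failure_reason(call: VariantCall, params: FilterParams) -> str | None:
    """First failing criterion, or None if the call survives.

    Criteria are checked depth -> allele balance -> binomial; the *surviving
    set* does not depend on this order, only the per-reason counts do.
    """
    if call.depth < params.min_depth:
        return "depth"
    if call.zygosity is Zygosity.HET:
        if call.alt_fraction is None or call.alt_reads is None:
            # het without usable allele counts cannot be validated
            return "missing"
        if not (
            params.min_alt_fraction
            <= call.alt_fraction
            <= params.max_alt_fraction
        ):
            return "alt_fraction"
        p = binomial_two_sided_p(
            call.alt_reads, call.depth, params.binomial_alternative
        )
        if p < params.binomial_p:
            return "binomial"
    return None


def quality_filter(
    table: SampleTable, params: FilterParams | None = None
) -> tuple[SampleTable, FilterReport]:
    """Apply the depth / allele-balance / binomial criteria individually."""
    params = params or FilterParams()
    report = FilterReport(n_input=len(table))
    kept: list[VariantCall] = []
    for call in table.calls:
        reason = _failure_reason(call, params)
        if reason is None:
            kept.append(call)
        elif reason == "depth":
            report.removed_depth += 1
        elif reason == "alt_fraction":
            report.removed_alt_fraction += 1
        elif reason == "binomial":
            report.removed_binomial += 1
        else:
            report.removed_missing += 1
    report.surviving = len(kept)
    return table.subset(kept), report


def apply_filters(
    table: SampleTable,
    repeats: IntervalSet | None = None,
    params: FilterParams | None = None,
) -> tuple[SampleTable, FilterReport]:
    """Repeat removal followed by the quality filter, with a joint report."""
    params = params or FilterParams()
    n_input = len(table)
    if repeats is not None and not repeats.is_empty:
        table, n_repeat = remove_repeat_variants(table, repeats)
    else:
        n_repeat = 0
    table, report = quality_filter(table, params)
    report.n_input = n_input
    report.removed_repeat = n_repeat
    return table, report


def assert_min_variants(table: SampleTable, params: FilterParams) -> None:
    """Stop the analysis when too few variants survive (strict '<')."""
    if len(table) < params.min_surviving_variants:
        raise InsufficientVariantsError(
            len(table), params.min_surviving_variants
        )
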