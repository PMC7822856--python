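"""Reading and writing per-sample variant calls in VCF.

The detector works on one sample at a time: a :class:`SampleTable` is the
ordered list of that sample's variant sites with the three quantities the
downstream filters need — zygosity, total read depth and the fraction of
reads supporting the alternative allele.  A usable VCF must declare the GT
format field plus either AD (allelic depths) or DP4 (strand-split ref/alt
counts); anything else is rejected up front rather than half-parsed.

Zygosity is derived from GT alone:

* two identical non-reference alleles (``1/1``, ``2|2``) → ``HOM_ALT``
* two different alleles (``0/1``, ``1/2``) → ``HET``
* a single-allele (haploid) genotype, as callers emit on male chrX/chrY → ``HEMI``
* any missing allele (``./.``, ``./1``) → ``MISSING`` (dropped, counted)

Homozygous-reference records (``0/0``) are dropped: the algorithm is defined
over variant sites only and single-sample VCFs do not normally emit them.
Multiallelic records are decomposed into one call per alternative allele
present in the genotype.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

__all__ = [
    "Zygosity",
    "VariantCall",
    "ReadStats",
    "SampleTable",
    "UnusableVCFError",
    "compute_alt_fraction",
    "read_vcf",
    "write_vcf",
    "normalize_chrom",
    "chrom_sort_key",
]

_BASES = frozenset("ACGT")


class UnusableVCFError(ValueError):
    """The VCF lacks a field the algorithm requires, or the sample is absent."""


class Zygosity(str, enum.Enum):
    HOM_ALT = "hom_alt"
    HET = "het"
    HEMI = "hemi"
    MISSING = "missing"


def normalize_chrom(name: str) -> str:
    """Map 'chr1'/'1' spellings onto one key ('1'); case-fold X/Y/MT."""
    s = name[3:] if name.lower().startswith("chr") else name
    return s.upper() if s.upper() in ("X", "Y", "M", "MT") else s


def chrom_sort_key(name: str):
    """Natural chromosome order: 1..22, then X, Y, MT, then the rest."""
    n = normalize_chrom(name)
    if n.isdigit():
        return (0, int(n), "")
    order = {"X": 0, "Y": 1, "M": 2, "MT": 2}
    if n in order:
        return (1, order[n], "")
    return (2, 0, n)


@dataclass(slots=True)
class VariantCall:
    """One variant site for one sample."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    zygosity: Zygosity
    depth: int
    alt_reads: int | None = None
    alt_fraction: float | None = None

    @property
    def is_homozygous(self) -> bool:
        # Hemizygous calls (single-copy chrX/chrY) count as homozygous for
        # ROH purposes: one allele is trivially a run of identical genotypes.
        return self.zygosity in (Zygosity.HOM_ALT, Zygosity.HEMI)

    @property
    def is_het(self) -> bool:
        return self.zygosity is Zygosity.HET


@dataclass(slots=True)
class ReadStats:
    """Counts of records a parse dropped or skipped, by reason."""

    dropped_missing: int = 0
    dropped_hom_ref: int = 0
    skipped_symbolic: int = 0
    skipped_malformed: int = 0

    @property
    def n_warnings(self) -> int:
        return (
            self.dropped_missing
            + self.skipped_symbolic
            + self.skipped_malformed
        )


@dataclass
class SampleTable:
    """Ordered, de-duplicated variant calls for one sample.

    Calls are kept sorted by (chromosome, position, alt allele) with
    duplicate (chrom, pos, alt) entries removed, preserving first occurrence.
    """

    sample_id: str
    calls: list[VariantCall] = field(default_factory=list)
    stats: ReadStats = field(default_factory=ReadStats)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        unique: list[VariantCall] = []
        for c in self.calls:
            key = (c.chrom, c.pos, c.alt_allele)
            if key in seen:
                continue
            seen.add(key)
            unique.append(c)
        unique.sort(key=lambda c: (chrom_sort_key(c.chrom), c.pos, c.alt_allele))
        self.calls = unique

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def subset(self, keep: Iterable[VariantCall]) -> "SampleTable":
        return SampleTable(self.sample_id, list(keep))

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.calls:
            if not out or out[-1] != c.chrom:
                if c.chrom not in out:
                    out.append(c.chrom)
        return out

    def calls_for(self, chrom: str) -> list[VariantCall]:
        norm = normalize_chrom(chrom)
        return [c for c in self.calls if normalize_chrom(c.chrom) == norm]


def compute_alt_fraction(counts: Sequence[int]) -> float | None:
    """Alt-allele read fraction from AD (ref, alt) or DP4 (rf, rr, af, ar).

    Returns ``None`` when all counts are zero (fraction undefined; such a
    site is later removed by the depth filter).
    """
    if len(counts) == 2:
        ref, alt = counts
        total = ref + alt
        alt_n = alt
    elif len(counts) == 4:
        total = sum(counts)
        alt_n = counts[2] + counts[3]
    else:
        raise ValueError(f"expected 2 (AD) or 4 (DP4) counts, got {len(counts)}")
    if total == 0:
        return None
    return alt_n / total


def _zygosity_of(gt: tuple[int, ...], allele_index: int) -> Zygosity:
    if len(gt) == 1:
        return Zygosity.HEMI
    if all(a == allele_index for a in gt):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def read_vcf(
    path: str | Path,
    sample: str | None = None,
    depth_source: str = "auto",
) -> SampleTable:
    """Parse one sample's calls out of a (plain or bgzipped) VCF.

    Parameters
    ----------
    path:
        VCF v4.x file.  The header must declare FORMAT/GT and either
        FORMAT/AD or DP4 (FORMAT or INFO).
    sample:
        Sample name to extract.  May be omitted for single-sample files;
        required (and validated) for multi-sample files.
    depth_source:
        ``"auto"`` (AD, falling back to DP4, then FORMAT/DP for depth only),
        ``"AD"``, ``"DP4"`` or ``"DP"`` to force one source.

    Raises
    ------
    UnusableVCFError
        Missing GT, neither AD nor DP4 declared, or sample not present.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise UnusableVCFError(f"cannot parse VCF {path}: {exc}") from exc

    formats = set(vcf.header.formats.keys())
    infos = set(vcf.header.info.keys())
    if "GT" not in formats:
        raise UnusableVCFError(
            f"unusable VCF {path}: FORMAT/GT is required but not declared"
        )
    has_ad = "AD" in formats
    has_dp4 = "DP4" in formats or "DP4" in infos
    if not (has_ad or has_dp4):
        raise UnusableVCFError(
            f"unusable VCF {path}: neither AD nor DP4 is declared in "
            "FORMAT or INFO; allele counts are required"
        )

    samples = list(vcf.header.samples)
    if sample is None:
        if len(samples) != 1:
            raise UnusableVCFError(
                f"multi-sample VCF {path}: choose one of {samples}"
            )
        sample = samples[0]
    elif sample not in samples:
        raise UnusableVCFError(
            f"sample {sample!r} not present in {path}; available: {samples}"
        )

    stats = ReadStats()
    calls: list[VariantCall] = []
    for rec in vcf:
        try:
            _parse_record(rec, sample, depth_source, calls, stats)
        except Exception:
            stats.skipped_malformed += 1
    vcf.close()
    table = SampleTable(sample, calls)
    table.stats = stats
    return table


def _parse_record(rec, sample: str, depth_source: str, calls, stats) -> None:
    sd = rec.samples[sample]
    gt = sd.get("GT")
    if gt is None or len(gt) == 0 or any(a is None for a in gt):
        stats.dropped_missing += 1
        return
    alt_indices = sorted({a for a in gt if a > 0})
    if not alt_indices:
        stats.dropped_hom_ref += 1
        return
    alts = rec.alts or ()

    ad = sd.get("AD") if depth_source in ("auto", "AD") else None
    if ad is not None and (len(ad) == 0 or any(v is None for v in ad)):
        ad = None
    dp4 = None
    if ad is None and depth_source in ("auto", "DP4"):
        dp4 = sd.get("DP4")
        if dp4 is None:
            dp4 = rec.info.get("DP4")
        if dp4 is not None and (len(dp4) != 4 or any(v is None for v in dp4)):
            dp4 = None

    for ai in alt_indices:
        if ai - 1 >= len(alts):
            stats.skipped_malformed += 1
            continue
        alt = alts[ai - 1]
        if alt is None or not alt or not set(alt.upper()) <= _BASES:
            stats.skipped_symbolic += 1
            continue
        if ad is not None:
            depth = int(sum(ad))
            alt_reads: int | None = int(ad[ai]) if ai < len(ad) else None
        elif dp4 is not None:
            depth = int(sum(dp4))
            alt_reads = int(dp4[2]) + int(dp4[3])
        else:
            dp = sd.get("DP")
            if dp is None:
                stats.skipped_malformed += 1
                continue
            depth = int(dp)
            alt_reads = None
        frac = (
            alt_reads / depth if depth > 0 and alt_reads is not None else None
        )
        calls.append(
            VariantCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref or "N",
                alt_allele=alt,
                zygosity=_zygosity_of(gt, ai),
                depth=depth,
                alt_reads=alt_reads,
                alt_fraction=frac,
            )
        )


_GT_OF = {
    Zygosity.HOM_ALT: "1/1",
    Zygosity.HET: "0/1",
    Zygosity.HEMI: "1",
}


def write_vcf(table: SampleTable, path: str | Path) -> None:
    """Write a SampleTable back out as a minimal single-sample VCF 4.2.

    One record per call (multiallelic sites stay decomposed); GT/AD/DP are
    reconstructed so that re-reading yields identical
    (chrom, pos, zygosity, depth) tuples.
    """
    path = Path(path)
    chroms: list[str] = []
    for c in table.calls:
        if c.chrom not in chroms:
            chroms.append(c.chrom)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in chroms:
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{table.sample_id}\n"
        )
        for c in table.calls:
            if c.alt_reads is not None:
                ref_reads = c.depth - c.alt_reads
                ad = f"{ref_reads},{c.alt_reads}"
            else:
                ad = ".,."
            gt = _GT_OF.get(c.zygosity, "./.")
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\t.\t.\t"
                f"GT:AD:DP\t{gt}:{ad}:{c.depth}\n"
            )
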