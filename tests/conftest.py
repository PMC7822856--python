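"""Shared helpers: hand-built variant tables and tiny VCF fixtures."""

from __future__ import annotations

import pytest

from rohmap import (
    GenomeAnnotation,
    IntervalSet,
    SampleTable,
    VariantCall,
    Zygosity,
)


def hom(chrom: str, pos: int, depth: int = 30) -> VariantCall:
    return VariantCall(
        chrom, pos, "A", "G", Zygosity.HOM_ALT, depth,
        alt_reads=depth, alt_fraction=1.0,
    )


def het(
    chrom: str, pos: int, depth: int = 30, alt_reads: int | None = None
) -> VariantCall:
    if alt_reads is None:
        alt_reads = depth // 2
    return VariantCall(
        chrom, pos, "A", "G", Zygosity.HET, depth,
        alt_reads=alt_reads,
        alt_fraction=alt_reads / depth if depth else None,
    )


def hemi(chrom: str, pos: int, depth: int = 30) -> VariantCall:
    return VariantCall(
        chrom, pos, "A", "G", Zygosity.HEMI, depth,
        alt_reads=depth, alt_fraction=1.0,
    )


def table_from_pattern(
    pattern: str,
    chrom: str = "chr1",
    start: int = 1_000_000,
    spacing: int = 10_000,
    sample: str = "S1",
) -> SampleTable:
    """'H' -> homozygous call, 'e' -> heterozygous, one per `spacing` bp."""
    calls = []
    for i, ch in enumerate(pattern):
        pos = start + i * spacing
        calls.append(hom(chrom, pos) if ch == "H" else het(chrom, pos))
    return SampleTable(sample, calls)


def annot_for(
    lengths: dict[str, int],
    repeats: IntervalSet | None = None,
    gaps: IntervalSet | None = None,
) -> GenomeAnnotation:
    from rohmap.vcf_io import normalize_chrom

    return GenomeAnnotation(
        repeats=repeats or IntervalSet(),
        gaps=gaps or IntervalSet(),
        chrom_lengths={normalize_chrom(c): n for c, n in lengths.items()},
    )


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=249000000>
##contig=<ID=chr2,length=243000000>
##contig=<ID=chrX,length=155000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write VCF body lines under the standard single-sample header."""

    def _write(body: str, header: str = VCF_HEADER, name: str = "x.vcf"):
        path = tmp_path / name
        path.write_text(header + body)
        return path

    return _write
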