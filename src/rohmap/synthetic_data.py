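"""Synthetic exome-like VCFs with planted autozygous segments.

Real WES cohorts with matched array genotypes cannot be redistributed, so
the test bed is simulated.  The generator reproduces the data features the
detector's behaviour actually depends on:

* **exon clustering** — variant sites fall in dense "exon" blocks separated
  by empty intergenic blocks, giving the variant-free-gap structure the
  ``maxgap`` rule handles;
* **planted autozygous segments** — inside them every site is homozygous
  except a configurable fraction of *false heterozygous* calls, the WES
  artifact the allele-balance and binomial filters target; their alt-read
  fraction is drawn from a mixture peaked away from 0.5 (default peaks at
  0.1 and 0.9), since mapping/calling artifacts are allele-skewed;
* **background heterozygosity** — outside segments sites are heterozygous
  with probability ``background_het_rate`` (default 0.66, the common-variant
  het excess seen at polymorphic exome sites);
* **read sampling** — per-site depth is gamma-Poisson (negative binomial)
  and allelic depths are binomial draws given the true allele fraction, so
  AD fields are internally consistent;
* **repeat regions and assembly gaps** — periodic repeat intervals whose
  variants are deliberately noisy (exercising the repeat filter) and a
  central centromere-like gap with no variants at all.

Everything is driven by one seeded generator: identical configs give
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .evaluation import EvalResult, evaluate, load_roh_bed
from .genome_annotation import IntervalSet
from .roh_detection import MB, ROH

__all__ = ["AltBiasModel", "SimConfig", "SimOutput", "simulate", "truth_compare"]


@dataclass
class AltBiasModel:
    """Mixture of Beta distributions for false-het alt-read fractions.

    Components have means ``means`` and a shared ``concentration`` (Beta
    parameters mean*c and (1-mean)*c); a component is picked per draw with
    probabilities ``weights``.  The default peaks at 0.1 and 0.9 — the
    allele-skewed regime of mapping/calling artifacts — with most mass on
    the high-skew side.
    """

    means: tuple[float, ...] = (0.1, 0.9)
    weights: tuple[float, ...] = (0.3, 0.7)
    concentration: float = 20.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        means = np.asarray(self.means)
        weights = np.asarray(self.weights, dtype=float)
        weights = weights / weights.sum()
        comp = rng.choice(len(means), size=size, p=weights)
        m = means[comp]
        a = m * self.concentration
        b = (1.0 - m) * self.concentration
        return rng.beta(a, b)


@dataclass
class SimConfig:
    """Study conditions for one simulated exome.

    seed:
        RNG seed; identical configs give byte-identical outputs.
    n_chromosomes, chrom_length:
        genome shape; chromosomes are named chr1..chrN.
    target_density:
        variant sites per Mb (default 20/Mb, i.e. ~60k sites on a 3-Gb
        genome — a typical single-sample WES VCF).
    planted_segments:
        autozygous (chrom, start, end) intervals, 1-based inclusive;
        must lie within their chromosomes and not overlap.
    background_het_rate:
        probability that a site outside any segment is heterozygous.
    in_roh_false_het_rate:
        fraction of in-segment sites emitted as false heterozygous calls
        (WES noise; realistic values run from a few percent to ~0.3).
    depth_mean, depth_shape:
        gamma-Poisson read depth (mean reads; smaller shape = more
        dispersed).
    noise_alt_fraction_model:
        alt-fraction distribution for false-het calls.
    exon_block_bp, intergenic_block_bp:
        alternating dense/empty block lengths.
    repeat_period_bp, repeat_length_bp, repeat_het_rate:
        one repeat interval per period; variants inside repeats are noisy
        (het with skewed allele balance at the given rate).
    centromere_mb:
        length of the central variant-free assembly gap per chromosome.
    """

    seed: int = 0
    n_chromosomes: int = 6
    chrom_length: int = 110 * MB
    target_density: float = 20.0
    planted_segments: tuple[tuple[str, int, int], ...] = ()
    background_het_rate: float = 0.66
    in_roh_false_het_rate: float = 0.10
    depth_mean: float = 50.0
    depth_shape: float = 10.0
    noise_alt_fraction_model: AltBiasModel = field(default_factory=AltBiasModel)
    exon_block_bp: int = 20_000
    intergenic_block_bp: int = 30_000
    repeat_period_bp: int = 1_000_000
    repeat_length_bp: int = 20_000
    repeat_het_rate: float = 0.5
    centromere_mb: float = 3.0
    sample_id: str = "SIM001"

    def __post_init__(self) -> None:
        for rate in (self.background_het_rate, self.in_roh_false_het_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        chroms = {f"chr{i}" for i in range(1, self.n_chromosomes + 1)}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.planted_segments:
            if chrom not in chroms:
                raise ValueError(f"planted segment on unknown chromosome {chrom}")
            if not (1 <= start <= end <= self.chrom_length):
                raise ValueError(
                    f"planted segment {chrom}:{start}-{end} outside chromosome"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError("planted segments overlap")


@dataclass
class SimOutput:
    """Paths of the files one simulation wrote."""

    vcf: Path
    truth_bed: Path
    repeat_bed: Path
    gap_bed: Path
    chrom_lengths: Path


def _chrom_names(config: SimConfig) -> list[str]:
    return [f"chr{i}" for i in range(1, config.n_chromosomes + 1)]


def _site_positions(
    config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Exon-clustered variant positions for one chromosome (1-based)."""
    period = config.exon_block_bp + config.intergenic_block_bp
    lam = config.target_density * period / MB
    positions: list[int] = []
    for block_start in range(0, config.chrom_length, period):
        n = rng.poisson(lam)
        if n == 0:
            continue
        exon_end = min(block_start + config.exon_block_bp, config.chrom_length)
        if exon_end <= block_start:
            continue
        pos = rng.integers(block_start, exon_end, size=n) + 1
        positions.extend(int(p) for p in pos)
    return np.unique(np.asarray(positions, dtype=np.int64))


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def simulate(config: SimConfig, out_dir: str | Path) -> SimOutput:
    """Generate the VCF plus truth/repeat/gap BEDs and a length table.

    Fully deterministic given ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    chroms = _chrom_names(config)

    segs_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, start, end in config.planted_segments:
        segs_by_chrom[chrom].append((start, end))
    for ivs in segs_by_chrom.values():
        ivs.sort()

    # annotation tracks (deterministic; BED = 0-based half-open)
    gap_lines: list[str] = []
    repeat_lines: list[str] = []
    gaps_by_chrom: dict[str, list[tuple[int, int]]] = {}
    repeats_by_chrom: dict[str, list[tuple[int, int]]] = {}
    cen_bp = int(config.centromere_mb * MB)
    for chrom in chroms:
        mid = config.chrom_length // 2
        g0, g1 = mid - cen_bp // 2, mid + cen_bp // 2
        gaps_by_chrom[chrom] = [(g0 + 1, g1)]  # 1-based inclusive
        gap_lines.append(f"{chrom}\t{g0}\t{g1}\n")
        reps = []
        for rstart in range(
            config.repeat_period_bp // 2,
            config.chrom_length - config.repeat_length_bp,
            config.repeat_period_bp,
        ):
            reps.append((rstart + 1, rstart + config.repeat_length_bp))
            repeat_lines.append(
                f"{chrom}\t{rstart}\t{rstart + config.repeat_length_bp}\n"
            )
        repeats_by_chrom[chrom] = reps

    noise_model = config.noise_alt_fraction_model
    bases = np.array(list("ACGT"))

    vcf_path = out_dir / "sample.vcf"
    with vcf_path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohmap-simulate\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom},length={config.chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{config.sample_id}\n"
        )
        for chrom in chroms:
            positions = _site_positions(config, rng)
            gap = gaps_by_chrom[chrom][0]
            for pos in positions:
                pos = int(pos)
                if gap[0] <= pos <= gap[1]:
                    continue  # no sequence, no calls
                in_segment = _in_any(pos, segs_by_chrom[chrom])
                in_repeat = _in_any(pos, repeats_by_chrom[chrom])
                depth = int(
                    rng.poisson(
                        rng.gamma(
                            config.depth_shape,
                            config.depth_mean / config.depth_shape,
                        )
                    )
                )
                if in_segment:
                    is_het = rng.random() < config.in_roh_false_het_rate
                    af = (
                        float(noise_model.sample(rng, 1)[0])
                        if is_het
                        else 0.98
                    )
                elif in_repeat:
                    is_het = rng.random() < config.repeat_het_rate
                    af = (
                        float(noise_model.sample(rng, 1)[0]) if is_het else 0.98
                    )
                else:
                    is_het = rng.random() < config.background_het_rate
                    af = 0.5 if is_het else 0.98
                alt_reads = int(rng.binomial(depth, af)) if depth > 0 else 0
                ref_reads = depth - alt_reads
                ref_b, alt_b = rng.choice(4, size=2, replace=False)
                gt = "0/1" if is_het else "1/1"
                fh.write(
                    f"{chrom}\t{pos}\t.\t{bases[ref_b]}\t{bases[alt_b]}\t.\t.\t.\t"
                    f"GT:AD:DP\t{gt}:{ref_reads},{alt_reads}:{depth}\n"
                )

    truth_path = out_dir / "truth.bed"
    with truth_path.open("w") as fh:
        for chrom in chroms:
            for start, end in segs_by_chrom[chrom]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")
    repeat_path = out_dir / "repeats.bed"
    repeat_path.write_text("".join(repeat_lines))
    gap_path = out_dir / "gaps.bed"
    gap_path.write_text("".join(gap_lines))
    lengths_path = out_dir / "chrom_lengths.tsv"
    lengths_path.write_text(
        "".join(f"{c}\t{config.chrom_length}\n" for c in chroms)
    )
    return SimOutput(vcf_path, truth_path, repeat_path, gap_path, lengths_path)


def truth_compare(
    detected: list[ROH],
    truth: str | Path | list[ROH],
    gaps: IntervalSet | None = None,
    min_size_mb: float = 1.0,
) -> EvalResult:
    """Evaluate detected ROHs against the planted truth set."""
    truth_rohs = truth if isinstance(truth, list) else load_roh_bed(truth)
    return evaluate(detected, truth_rohs, gaps=gaps, min_size_mb=min_size_mb)


def with_noise(config: SimConfig, rate: float) -> SimConfig:
    """Copy of a config with a different in-ROH false-het rate."""
    return replace(config, in_roh_false_het_rate=rate)
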