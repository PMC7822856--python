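"""User-facing outputs: ROH tables, genome-wide plots, gene-panel annotation."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .genome_annotation import GenomeAnnotation
from .roh_detection import ROH, DetectionParams
from .variant_filter import FilterParams
from .vcf_io import chrom_sort_key, normalize_chrom

__all__ = [
    "GenePanel",
    "load_gene_panel",
    "parameter_echo",
    "write_roh_table",
    "read_roh_table",
    "write_bed",
    "plot_rohs",
    "annotate_panel",
    "write_eval_table",
]

_COLUMNS = (
    "chrom",
    "start",
    "end",
    "size_bp",
    "n_variants",
    "n_homozygous",
    "perc_homozygosity",
)


@dataclass
class GenePanel:
    """Named genes with 1-based inclusive coordinates; symbols unique."""

    entries: list[tuple[str, str, int, int]]

    def __post_init__(self) -> None:
        symbols = [e[0] for e in self.entries]
        if len(symbols) != len(set(symbols)):
            raise ValueError("gene panel symbols must be unique")
        for gene, _, start, end in self.entries:
            if start < 1 or end < start:
                raise ValueError(f"invalid coordinates for gene {gene}")


def load_gene_panel(path: str | Path) -> GenePanel:
    """Read a panel as whitespace-separated (gene, chrom, start, end) lines."""
    entries = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, chrom, start, end = line.split()[:4]
            entries.append((gene, chrom, int(start), int(end)))
    return GenePanel(entries)


def parameter_echo(
    filter_params: FilterParams | None = None,
    det_params: DetectionParams | None = None,
) -> str:
    """One-line provenance record of every tunable parameter."""
    fp = filter_params or FilterParams()
    dp = det_params or DetectionParams()
    parts = [
        f"DP={fp.min_depth}",
        f"minpercalt={fp.min_alt_fraction:g}",
        f"maxpercalt={fp.max_alt_fraction:g}",
        f"binomial={fp.binomial_p:g}",
        f"window={dp.window}",
        f"windowthres={dp.windowthres}",
        f"maxgap={dp.maxgap:g}",
        f"extend={dp.extend:g}",
        f"minsize={dp.minsize:g}",
        f"minvar={dp.minvar}",
        f"minperc={dp.minperc:g}",
        f"chrX={dp.include_chrX}",
    ]
    return " ".join(parts)


def write_roh_table(
    rohs: Sequence[ROH],
    path: str | Path,
    params: str | Mapping[str, Any] | None = None,
    bed_path: str | Path | None = None,
) -> None:
    """Write the per-sample ROH table as TSV, plus a companion BED3.

    The header comment records every parameter value used (pass the string
    from :func:`parameter_echo` or any mapping).  Columns: chrom, start, end
    (1-based inclusive), size_bp, n_variants, n_homozygous,
    perc_homozygosity (2 decimals).
    """
    path = Path(path)
    if isinstance(params, Mapping):
        params = " ".join(f"{k}={v}" for k, v in params.items())
    with path.open("w") as fh:
        if params:
            fh.write(f"# parameters: {params}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rohs:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.size}\t{r.n_variants}\t"
                f"{r.n_homozygous}\t{r.perc_homozygous:.2f}\n"
            )
    if bed_path is None:
        bed_path = path.with_suffix(".bed")
    write_bed(rohs, bed_path)


def read_roh_table(path: str | Path) -> list[ROH]:
    """Read back a TSV written by :func:`write_roh_table`."""
    rohs: list[ROH] = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, start, end, _size, n_var, n_hom, _perc = line.split("\t")
            rohs.append(
                ROH(chrom, int(start), int(end), int(n_var), int(n_hom))
            )
    return rohs


def write_bed(rohs: Sequence[ROH], path: str | Path) -> None:
    """BED3 export (0-based half-open; start = 1-based start - 1)."""
    with Path(path).open("w") as fh:
        for r in rohs:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")


def plot_rohs(
    rohs: Sequence[ROH],
    chrom_lengths: Mapping[str, int] | GenomeAnnotation,
    path: str | Path,
    include_chrX: bool = False,
) -> dict[str, list[tuple[int, int]]]:
    """Genome-wide ideogram: one bar per chromosome, ROHs as filled spans.

    Saves a vector file (format from the extension: .pdf or .svg) and
    returns the per-chromosome span coordinates actually drawn, so callers
    can verify the plotted data independently of the binary output.
    """
    if isinstance(chrom_lengths, GenomeAnnotation):
        chrom_lengths = chrom_lengths.chrom_lengths
    skip = {"Y", "M", "MT"} | (set() if include_chrX else {"X"})
    chroms = [
        c
        for c in sorted(chrom_lengths, key=chrom_sort_key)
        if normalize_chrom(c) not in skip
    ]
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    by_norm = {normalize_chrom(c): c for c in chroms}
    for r in sorted(rohs, key=lambda r: (chrom_sort_key(r.chrom), r.start)):
        key = by_norm.get(normalize_chrom(r.chrom))
        if key is not None:
            spans[key].append((r.start, r.end))

    fig, ax = plt.subplots(figsize=(10, max(2, 0.35 * len(chroms) + 1)))
    for i, chrom in enumerate(chroms):
        y = len(chroms) - 1 - i
        length = chrom_lengths[chrom]
        ax.barh(
            y, length, height=0.6, color="0.92", edgecolor="0.4", linewidth=0.5
        )
        for start, end in spans[chrom]:
            ax.barh(
                y,
                end - start + 1,
                left=start - 1,
                height=0.6,
                color="tab:blue",
            )
    ax.set_yticks(range(len(chroms)))
    ax.set_yticklabels(list(reversed(chroms)))
    ax.set_xlabel("position (bp)")
    ax.set_title("Runs of homozygosity")
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
    return spans


def annotate_panel(
    rohs: Sequence[ROH], panel: GenePanel
) -> list[dict[str, Any]]:
    """Report, for every panel gene, the ROH it overlaps (>= 1 bp) or None."""
    out: list[dict[str, Any]] = []
    for gene, chrom, start, end in panel.entries:
        hit: ROH | None = None
        for r in rohs:
            if (
                normalize_chrom(r.chrom) == normalize_chrom(chrom)
                and start <= r.end
                and end >= r.start
            ):
                hit = r
                break
        out.append(
            {"gene": gene, "chrom": chrom, "start": start, "end": end, "roh": hit}
        )
    return out


def write_eval_table(results: Mapping[str, Any], path: str | Path) -> None:
    """TSV of per-sample evaluation metrics (sample, sens, spec, F-score)."""

    def fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.2f}"

    with Path(path).open("w") as fh:
        fh.write("sample\tsensitivity\tspecificity\tf_score\n")
        for sample, res in results.items():
            fh.write(
                f"{sample}\t{fmt(res.sensitivity)}\t{fmt(res.specificity)}\t"
                f"{fmt(res.f_score)}\n"
            )
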