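"""Write the user-facing outputs: ROH table, BED, genome plot, gene panel.

Takes a hand-built ROH list, writes the TSV (with a parameter-provenance
header) and its companion BED, draws the genome-wide ideogram, and checks a
small gene panel against the ROHs.
"""

from pathlib import Path

from rohmap import (
    MB,
    ROH,
    GenePanel,
    annotate_panel,
    parameter_echo,
    plot_rohs,
    write_roh_table,
)

out = Path("scratch/example03")
out.mkdir(parents=True, exist_ok=True)

rohs = [
    ROH("chr1", 94 * MB + 1, 99 * MB, n_variants=120, n_homozygous=118),
    ROH("chr6", 30 * MB + 1, 33 * MB, n_variants=60, n_homozygous=60),
]
lengths = {"chr1": 249 * MB, "chr6": 171 * MB}

write_roh_table(rohs, out / "sample.HomRegions.tsv", params=parameter_echo())
spans = plot_rohs(rohs, lengths, out / "sample.HomRegions.pdf")
print(f"wrote table + BED + plot under {out}/")
print("plotted spans:", spans)

panel = GenePanel([
    ("ABCA4", "chr1", 94_458_394, 94_586_688),   # inside the chr1 ROH
    ("CFTR", "chr7", 117_120_017, 117_308_718),  # chromosome without ROHs
])
for row in annotate_panel(rohs, panel):
    roh = row["roh"]
    where = f"in ROH {roh.chrom}:{roh.start}-{roh.end}" if roh else "not in any ROH"
    print(f"{row['gene']}: {where}")
# A gene counts as "in ROH" from a single bp of overlap — the clinically
# conservative choice when prioritising candidate genes.
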