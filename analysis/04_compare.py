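"""Cross-layer comparison: gene- and process-level protein-mRNA correlation
per condition, and the translation-propensity (P/T) table."""

import argparse
from pathlib import Path

import pandas as pd

import omniflux as om
from omniflux import io

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--inputs", type=Path, default=Path("results/01_simulated"))
parser.add_argument("--absolute", type=Path, default=Path("results/02_absolute"))
parser.add_argument("--fractions", type=Path, default=Path("results/03_allocation"))
parser.add_argument("--out", type=Path, default=Path("results/04_compare"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

mrna_abs = io.read_matrix_tsv(args.absolute / "mrna_absolute.tsv",
                              "mRNA", "arbitrary_absolute")
prot_abs = io.read_matrix_tsv(args.absolute / "protein_absolute.tsv",
                              "protein", "arbitrary_absolute")
prot_frac = om.ProcessFractionTable(
    io.read_frame_tsv(args.fractions / "protein_fractions.tsv").set_index("process_id"),
    mode="mass", layer="protein")
mrna_frac = om.ProcessFractionTable(
    io.read_frame_tsv(args.fractions / "mrna_fractions.tsv").set_index("process_id"),
    mode="molar", layer="mRNA")

rows = []
for sample in prot_abs.sample_ids:
    gene = om.correlate_layers(prot_abs, mrna_abs, sample, level="gene")
    proc = om.correlate_layers(prot_abs, mrna_abs, sample, level="process",
                               fractions=(prot_frac, mrna_frac))
    rows.append({"sample": sample, "gene_r2": gene.r_squared,
                 "n_pairs": gene.n_pairs, "process_r2": proc.r_squared})
    print(f"{sample}: gene-level R^2 {gene.r_squared:.2f} over {gene.n_pairs} "
          f"protein-transcript pairs; process-level R^2 {proc.r_squared:.2f}")
io.write_frame_tsv(pd.DataFrame(rows), args.out / "correlations.tsv")

pt = om.translation_propensity(prot_abs, mrna_abs)
io.write_frame_tsv(pt.rename_axis("gene_id"), args.out / "translation_propensity.tsv",
                   index=True)
print(f"P/T table: {pt.shape[0]} genes x {pt.shape[1]} samples; outputs in {args.out}")
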