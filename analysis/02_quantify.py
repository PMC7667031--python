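"""Convert both signal layers to absolute abundances.

mRNA: fit the spike-in calibration (log10 FPKM-like signal vs known
concentration) and apply it to all transcripts.  Protein: compute iBAQ for
the pooled reference, fit the UPS2-style calibration on standards with >=2
unique peptides, convert the reference to absolute values, and propagate to
every sample through the TMT ratios.
"""

import argparse
from pathlib import Path

import omniflux as om
from omniflux import io

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--inputs", type=Path, default=Path("results/01_simulated"))
parser.add_argument("--out", type=Path, default=Path("results/02_absolute"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

annotation = io.read_annotation_tsv(args.inputs / "annotation.tsv")
mrna_signal = io.read_matrix_tsv(args.inputs / "mrna_signal.tsv", "mRNA", "signal")
mrna_std = io.read_frame_tsv(args.inputs / "mrna_standards.tsv")
peptides = io.read_frame_tsv(args.inputs / "peptides.tsv")
ups2 = io.read_frame_tsv(args.inputs / "ups2_standards.tsv")
tmt = io.read_frame_tsv(args.inputs / "tmt_ratios.tsv").set_index("gene_id")

mrna_curve = om.fit_calibration(mrna_std)
mrna_abs = om.apply_calibration(mrna_curve, mrna_signal)
print(f"mRNA calibration: slope {mrna_curve.slope:.3f}, intercept "
      f"{mrna_curve.intercept:.3f}, R^2 {mrna_curve.r_squared:.3f} "
      f"({mrna_curve.n_points} standards)")

ibaq = om.compute_ibaq(peptides, annotation)
kept = om.filter_standards(ups2, min_unique_peptides=2)
prot_curve = om.fit_calibration(kept)
ref_abs = om.apply_calibration(prot_curve, ibaq)
prot_abs = om.propagate_tmt(ref_abs, tmt)
print(f"UPS2-style standards retained: {len(kept)}/{len(ups2)}")
print(f"protein calibration: slope {prot_curve.slope:.3f}, intercept "
      f"{prot_curve.intercept:.3f}, R^2 {prot_curve.r_squared:.3f}")
print(f"absolute layers: {mrna_abs.data.shape[0]} transcripts, "
      f"{prot_abs.data.shape[0]} proteins across {prot_abs.data.shape[1]} samples")

io.write_matrix_tsv(mrna_abs, args.out / "mrna_absolute.tsv")
io.write_matrix_tsv(prot_abs, args.out / "protein_absolute.tsv")
print(f"outputs in {args.out}")
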