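"""Generate the synthetic chemostat study: 3 strains x 2 dilution rates x
biological duplicates, ~2,800 protein-transcript pairs over 99 bioprocesses,
spike-in standards for both omics layers, steady-state chemostat records and
a toy enzyme-constrained network with recorded truth.

Writes every downstream input under results/01_simulated/.
"""

import argparse
from pathlib import Path

import omniflux as om
from omniflux import io

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/01_simulated"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

design = om.ExperimentDesign(seed=args.seed)
annotation, ontology = om.generate_annotation(2800, 99, seed=args.seed)
truth = om.generate_truth(design, annotation)
mrna_signal, mrna_std = om.simulate_mrna_assay(truth, seed=args.seed + 1)
peptides, ups2, tmt = om.simulate_protein_assay(truth, annotation, seed=args.seed + 2)
toy = om.generate_toy_ecmodel(seed=args.seed + 3, design=design)

io.write_annotation_tsv(annotation, args.out / "annotation.tsv")
io.write_matrix_tsv(mrna_signal, args.out / "mrna_signal.tsv")
io.write_frame_tsv(mrna_std, args.out / "mrna_standards.tsv")
io.write_frame_tsv(peptides, args.out / "peptides.tsv")
io.write_frame_tsv(ups2, args.out / "ups2_standards.tsv")
io.write_frame_tsv(tmt.rename_axis("gene_id"), args.out / "tmt_ratios.tsv", index=True)
io.write_matrix_tsv(truth.true_mrna, args.out / "truth_mrna.tsv")
io.write_matrix_tsv(truth.true_protein, args.out / "truth_protein.tsv")
io.write_network_json(toy.network, args.out / "network.json")
io.write_chemostat_csv([c.chemostat for c in toy.conditions.values()],
                       args.out / "chemostat.csv")
io.write_frame_tsv(
    om.enzyme_abundance_matrix(toy).data.rename_axis("enzyme_id"),
    args.out / "enzyme_abundance.tsv", index=True)
for (strain, d), cond in toy.conditions.items():
    io.write_frame_tsv(cond.measured_rates,
                       args.out / f"measured_rates_{strain}_{d:g}.tsv")

n_samples = len(design.sample_ids())
print(f"simulated {len(annotation)} genes x {n_samples} samples "
      f"({len(design.strains)} strains x {len(design.dilution_rates)} rates "
      f"x {design.n_replicates} replicates)")
print(f"mRNA spike-in standards: {len(mrna_std)}; UPS2-like standards: {len(ups2)} "
      f"(of which <2 unique peptides: {(ups2['n_unique_peptides'] < 2).sum()})")
print(f"toy network: {len(toy.network.reactions)} reactions, "
      f"{len(toy.network.enzymes)} enzymes; true NGAM range "
      f"{min(c.ngam for c in toy.conditions.values()):.2f}-"
      f"{max(c.ngam for c in toy.conditions.values()):.2f} mmol ATP/gDCW/h")
print(f"outputs in {args.out}")
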