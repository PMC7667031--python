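# omniflux

Multi-omics resource-allocation analysis for recombinant-protein-producing
yeast grown in chemostats: spike-in-calibrated absolute transcriptomics and
proteomics, allocation of both layers to biological processes, differential
testing between strains, translation propensity, steady-state physiology,
and enzyme-constrained flux balance analysis (FBA) with the non-growth-
associated maintenance energy (NGAM) as the objective.

The package is built for systems biologists who want to run — and, on
synthetic data with recorded ground truth, *validate* — the full chain from
raw signal tables (FPKM, peptide intensities, TMT ratios) to a per-strain
maintenance-energy estimate. A first-class generator emulates the structure
of such a study (3 strains × 2 dilution rates × biological duplicates,
~2,800 protein–transcript pairs, 99 processes, calibration standards
spanning the dynamic range), so every stage can be tested for parameter
recovery without any external download.

## The methods in brief

**Absolute quantification.** For each layer, standards of known
concentration are regressed in log space against their measured signal,

&nbsp;&nbsp;&nbsp;&nbsp;log₁₀ c = a·log₁₀ s + b,

and the fitted (a, b) convert all signals to absolute values. The protein
signal is iBAQ — summed peptide intensity divided by the number of
theoretically observable peptides — of a pooled reference spiked with a
UPS2-style dynamic-range standard; only standards with ≥ 2 unique peptides
enter the fit. Per-sample protein abundances follow by multiplying the
reference's absolute values with each sample's TMT ratio.

**Allocation and testing.** A process's fraction in a sample is the summed
abundance of its member genes over the total of all quantified genes —
molar (mol/mol) or mass-weighted (g/g). Strains are compared at matched
dilution rates with a two-tailed pooled-variance Student's *t* test per
process, log₂FC against the reference strain.

**Cross-layer comparison.** Gene-level Pearson R² of log₁₀ absolute protein
vs mRNA over the quantified pairs; process-level R² on fraction values;
translation propensity P/T = protein / mRNA per gene.

**Chemostat physiology.** At steady state μ = D, so specific rates are
arithmetic: uptake q = D·(c_feed − c_residual)/X, secretion q = D·c/X,
yield = titer/X, productivity = yield·D.

**Enzyme-constrained FBA.** A GECKO-form LP: fluxes v with S·v = 0, enzyme
usages e with v ≤ k_cat·e, measured abundances as upper bounds on e, a pool
constraint Σ MWᵢ·eᵢ ≤ P_total·f·σ (f = 0.5, σ = 0.5), measured exchange
fluxes windowed by a flexibility factor (1.03), growth fixed to D, and NGAM
(ATP hydrolysis) maximised — reading out the energy spent beyond growth.

## Worked example

Run the numbered analysis scripts from the repository root (each is a thin
driver over the library; outputs land under `results/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_quantify.py
python analysis/03_allocate.py
python analysis/04_compare.py
python analysis/05_chemostat.py
python analysis/06_ngam.py
```

Selected output of the chain:

```
mRNA calibration: slope 0.913, intercept 2.006, R^2 0.964 (36 standards)
UPS2-style standards retained: 43/48
protein  MH34 vs AAC at D=0.1/h: 14 differential processes (P<0.05), log2FC range [-0.69, 0.92]
AAC_0.1_r1: gene-level R^2 0.46 over 2800 protein-transcript pairs; process-level R^2 0.26
B184 D=0.1/h: glucose uptake 0.871, amino-acid uptake 0.252 mmol/gDCW/h; yield 59.8 mg/gDCW, productivity 5.98 mg/gDCW/h
AAC  D=0.1/h: NGAM 3.703 mmol ATP/gDCW/h (optimal)
MH34 D=0.1/h: NGAM 4.272 mmol ATP/gDCW/h (optimal)
B184 D=0.1/h: NGAM 3.145 mmol ATP/gDCW/h (optimal)
D=0.1/h NGAM ordering (lowest first): B184 < AAC < MH34
```

Reading it: the calibration recovers the generator's configured law (slope
0.9, intercept 2.0) from 36 noisy standards; 43 of the 48 protein standards
survive the unique-peptide filter and anchor the iBAQ calibration;
process-level differential tests flag the planted strain effects (the
ER-folding process is up in both evolved strains); gene-level protein–mRNA
R² sits near 0.46 (the generator's coupling target of 0.5, attenuated by
assay noise); and the enzyme-constrained model assigns the lowest
maintenance energy to the strain whose ground truth wastes the least ATP
per unit of secreted product — at both dilution rates.

The same chain is available as one call:

```python
from omniflux import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(out_dir="results/pipeline", seed=1))
print(report.summary["ngam"])
```

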