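# Methods

This note documents the models and procedures implemented in `omniflux`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the design choices made where the design was genuinely
open. Empirical claims here are limited to properties the test suite and
`scripts/acceptance.py` themselves compute.

## Scope and data flow

The pipeline starts where read mapping and database search end: from an
FPKM-like mRNA signal matrix, a peptide-intensity table for a pooled
reference sample, a TMT ratio matrix, spike-in standard tables, chemostat
measurements, and a small metabolic network with kcats. Stages:

1. **simulate** — generate all of the above with recorded ground truth;
2. **quantify** — signal → absolute conversion for both layers;
3. **allocate** — process fractions and differential testing;
4. **compare** — protein–mRNA correlation and translation propensity;
5. **chemostat** — specific rates, yield, productivity;
6. **ngam** — enzyme-constrained FBA maximising maintenance ATP hydrolysis.

Missing observations are NaN throughout, never zero: log-space calibration
is undefined at zero, and an undetected species must never acquire an
invented absolute value.

## Absolute quantification

Calibration is ordinary least squares of log₁₀(known concentration) on
log₁₀(measured signal). The log–log choice is a design decision: both
signal and concentration span orders of magnitude, and a linear-space fit
would be dominated by the few largest standards. Concentration units are
treated as opaque "absolute units" fixed by the standards table — the
pipeline never needs to know whether the standards were molar or mass.

iBAQ is the summed intensity of a protein's detected peptides divided by
its count of theoretically observable peptides. Technical (injection)
replicates, when present in the peptide table, are averaged *before* iBAQ.
Standards enter the protein calibration only with ≥ 2 unique peptides
(`min_unique_peptides`, default 2). Per-sample protein abundances are the
pooled reference's absolute values times the sample/reference TMT ratio;
no additional between-channel normalisation is applied (upstream software
normalisation is out of scope, and the generator emits ratios directly).

## Allocation and differential testing

Molar fraction of process p in sample s: Σ_{g∈p} a(g,s) / Σ_{all g} a(g,s);
mass fractions weight each gene by its molecular weight (kDa). Membership
is many-to-many: a gene in several processes counts fully in each, while
the denominator is always the total over all quantified genes — so
fractions sum to exactly 1 per sample only on a partition ontology
(asserted to 1e-9 in tests), and may sum above 1 otherwise. Genes with no
membership contribute to denominators only.

Differential testing is a two-tailed pooled-variance Student's *t* test on
per-replicate values, reference strain as group A, log₂FC = log₂(mean_B /
mean_A) (missing when either mean is non-positive). Raw p-values are
compared to α = 0.05 by default, matching the practice of reporting
uncorrected P < 0.05 for process panels; Benjamini–Hochberg adjustment is
available behind the `fdr` flag. Tests run on fractions (the quantity the
figures plot); running them on absolute sums instead is a one-line change
for the caller since `diff_units` accepts any unit × sample table.

## Cross-layer comparison

Gene-level correlation is Pearson R² of log₁₀ absolute values over genes
positive in both layers of one sample. The log transform is a documented
decision: R² values in the 0.3–0.5 range for abundances spanning four
orders of magnitude are only meaningful in log space. Process-level
correlation uses untransformed fractions, which are already commensurate.
Translation propensity P/T is the elementwise protein/mRNA ratio; the
identity P/T × mRNA = protein holds exactly wherever all three are defined.

## Chemostat arithmetic

Steady state (μ = D) is assumed; dilution of intracellular product and
evaporation are ignored. Uptake q = D·(c_feed − c_residual)/X and secretion
q = D·c_residual/X in mmol/gDCW/h feed directly into the model's flux
units; yield = titer/X (mg/gDCW) and productivity = yield·D. A residual
above feed for a declared uptake is a data error, not a warning.

## Enzyme-constrained FBA and the NGAM objective

The LP has one variable per directional flux plus one usage variable per
enzyme. Constraints: S·v = 0 on internal metabolites; v_j ≤ kcat_ij·e_i for
every catalysed direction (reversible enzymatic reactions are split, both
halves coupled to the same enzyme; isoenzymes and complexes are out of
scope — one enzyme per reaction); the pool Σ MWᵢ·eᵢ ≤ P_total·f·σ; and
finite box bounds everywhere, so the feasible region is a polytope.
Defaults: P_total = 0.5 g protein/gDCW, f = 0.5 (mass fraction of protein
that is metabolic enzyme), σ = 0.5 (mean saturation). MW in kDa equals
g/mmol, so usages carry mmol/gDCW with no further conversion; proteomic
bounds given in molecules/cell are converted via Avogadro's number and a
cells-per-gDCW constant (default 5 × 10¹⁰, ≈ 20 pg dry mass per cell).

Measured exchange fluxes are bounded two-sidedly in [m/flex, m·flex] with
flex = 1.03, so measurement error cannot render the LP infeasible. Growth
is fixed *equal* to the dilution rate (chemostat steady state), and the LP
**maximises** the NGAM (ATP hydrolysis) flux. The optimisation sense is a
design decision: with growth fixed and all exchanges measured, surplus
catabolic capacity has nowhere to go but maintenance, so the maximised
NGAM reads out the energy spent beyond growth. Solver: HiGHS through
`scipy.optimize.linprog`; feasibility is asserted to 1e-8 and only the
objective value is contract-bearing (flux vectors may be degenerate).

### Independent verification

Because every bound is finite, the optimum lies at a vertex. On small
networks `omniflux.verify` enumerates all basic solutions of the
standard-form LP outright (pin n − rank(A) variables at a bound, solve for
the rest) — an oracle with no simplex code in common with the solver. The
test suite compares both `fba` and `solve_ngam` against it on 50 seeded
random networks (1e-7 agreement), and additionally rebuilds the toy
ec-model in cobrapy with GECKO-style enzyme draw reactions as a second,
external cross-check.

## The synthetic generator

The generator emulates the *structure* of a chemostat multi-omics study of
three related α-amylase-producing strains — a reference producer and two
evolved isolates — at D = 0.1 and 0.2 h⁻¹ in biological duplicate.

Truth layers: per-gene base mRNA is log-normal (log₁₀ mean 1.0, SD 0.5 —
about two orders of magnitude for the bulk of quantified transcripts, with
a median of ~10 molecules/cell); protein = mRNA × gene-specific translation
propensity × strain effects × replicate noise. The propensity spread is
solved in closed form so that the within-sample log-protein/log-mRNA R²
hits a configured target (default 0.5, the midpoint of typical gene-level
couplings); replicate noise is log-normal with log₁₀ SD 0.05 (~12% CV,
typical of steady-state chemostat duplicates, which are much tighter than
batch cultures). Shipped strain effects: the ER-folding process up 1.8× /
2.0× in the two evolved strains, glycosylation and amino-acid transport
trimmed in the first — the contrasts the differential report should
recover. Spike-in standards are chosen by stratified quantiles of the
pooled dynamic range (36 for mRNA; 48 UPS2-like with 5 deliberately under
the 2-peptide threshold). Assay noise (log₁₀ SD 0.1 on signals) and TMT
ratio noise (log₁₀ SD 0.05) are simulator conventions, not inferences
about any instrument.

The toy metabolic network (14 reactions, 6 enzymes) has glucose uptake,
glycolysis, fermentation/respiration branches with a crabtree-like shift
toward fermentation at higher D, amino-acid uptake and synthesis, protein
synthesis and product secretion, a biomass drain and the NGAM reaction.
Per condition the generator constructs a flux vector satisfying S·v = 0
exactly, with true NGAM = base maintenance × a strain waste factor
(highest in the high-misfolding evolved strain, lowest in the efficient
one) and enzyme abundances e = v/(kcat·σ). Chemostat records (feed,
residual, biomass, titer) are built to reproduce those rates under the
steady-state balance, so the chemostat stage's recomputed rates equal the
truth exactly.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read- or spectrum-level noise and missingness
mechanisms (values are missing only where signals are zero), compositional
TMT artefacts and channel interference, correlated process-level
co-regulation beyond the planted effects (so the process-level
protein–mRNA R² of the defaults is lower than in real proteomes),
isoenzymes, enzyme complexes and genome-scale network redundancy.

## Replicates and test power

The shipped experimental design uses biological duplicates, matching the
structure such studies typically have. A pooled t test between two
duplicate groups has 2 degrees of freedom (critical |t| ≈ 4.30), which
caps its power: a planted 1.5× process effect at the default noise is
directionally recovered essentially always, but its p-value can miss 0.05
in a noticeable fraction of seeds. Two consequences in this package: the
planted-effect *recovery benchmark* runs with triplicates (df = 4), where
all five planted effects are recovered at α = 0.05 in ≥ 95% of seeds; and
the default-scenario differential report follows the figure convention of
listing a process when it is significant in *any* strain × rate condition,
rather than demanding significance in every contrast.

## Numerical choices

LP feasibility tolerance 1e-8, oracle comparison 1e-7; calibration and
t-test oracle agreement 1e-10; fraction-sum conservation 1e-9; noise-free
round-trip recovery 1e-9 relative. Floats are written with a fixed
`%.12g` format and the pipeline log carries no wall-clock timestamps, so a
rerun with identical config and seed is byte-identical; completed stage
outputs are rewritten only when their bytes would change. Degenerate
inputs fail loudly: all-zero samples, empty filtered standard sets,
zero-variance calibrations and missing annotation entries raise typed
errors rather than propagating NaN.

## Problem sizes

Default analyses run at the study's scale (2,800 genes, 99 processes, 12
samples); oracle-heavy checks use deliberately small instances — 5-reaction
random networks for exhaustive vertex enumeration, 800-gene designs for
the 40-seed recovery benchmark — chosen so exhaustive verification stays
exact and the whole validation suite runs in seconds on one CPU.
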