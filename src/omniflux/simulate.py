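"""Synthetic multi-omics experiment generator with recorded ground truth.

Emulates the structure of a chemostat study of recombinant-protein-producing
yeast: three strains (a reference producer and two evolved isolates) grown at
two dilution rates in biological duplicate, with

* absolute mRNA truth (molecules/cell) and an FPKM-like signal assay anchored
  by 36 spike-in standards spanning the dynamic range,
* absolute protein truth, a pooled-reference peptide-intensity table suitable
  for iBAQ plus a UPS2-style dynamic-range standard, and TMT-style
  sample/pooled-reference ratio matrices,
* steady-state chemostat measurements (feed/residual concentrations, biomass,
  product titer), and
* a toy enzyme-constrained metabolic network whose per-condition reference
  flux vector, maintenance energy (NGAM) and enzyme abundances are recorded.

Every generator is deterministic under its seed, and every statistical target
(process effects, protein-mRNA coupling R-squared, NGAM) is recoverable from
the recorded truth, so downstream stages can be tested for parameter
recovery rather than against opaque fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemostat import ChemostatRecord
from .containers import AbundanceMatrix, ExperimentDesign, GeneRecord, Ontology
from .ecfba import EnzymeInfo, MetabolicNetwork, Reaction
from .errors import ArgumentError

# A few leading processes get meaningful names so that shipped default effects
# (folding up in the evolved strains, etc.) read naturally in reports.
_NAMED_PROCESSES = (
    "protein_folding_ER",
    "protein_glycosylation",
    "amino_acid_transport",
    "energy_metabolism",
    "translation",
    "protein_phosphorylation",
    "vitamin_metabolism",
    "trehalose_metabolism",
)


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def generate_annotation(n_genes: int, ontology_size: int, seed: int,
                        membership_rate: float = 1.5,
                        ) -> tuple[list[GeneRecord], Ontology]:
    """Generate per-gene annotation over a GO-Slim-like process vocabulary.

    Each gene joins ``Poisson(membership_rate)`` processes (many-to-many, may
    be none), molecular weights are log-uniform in [10, 200] kDa, and
    theoretical peptide counts scale roughly with protein size.
    """
    if n_genes < 1 or ontology_size < 1:
        raise ArgumentError("n_genes and ontology_size must be >= 1")
    rng = np.random.default_rng(seed)
    pids = [
        _NAMED_PROCESSES[i] if i < len(_NAMED_PROCESSES) else f"proc_{i + 1:03d}"
        for i in range(ontology_size)
    ]
    ontology = Ontology(process_ids=tuple(pids))
    records = []
    for g in range(n_genes):
        mw = float(10 ** rng.uniform(np.log10(10), np.log10(200)))
        # ~1 observable tryptic peptide per 3 kDa, at least one
        n_pep = max(1, int(rng.poisson(mw / 3.0)))
        k = min(ontology_size, rng.poisson(membership_rate))
        procs = frozenset(rng.choice(pids, size=k, replace=False)) if k else frozenset()
        records.append(GeneRecord(f"gene_{g + 1:05d}", mw, n_pep, procs))
    return records, ontology


# --------------------------------------------------------------------------
# abundance truth
# --------------------------------------------------------------------------

@dataclass
class EffectConfig:
    """Strain effects and statistical targets for the truth layers.

    ``process_effects[strain][process]`` multiplies the protein abundance of
    every member gene in that strain; ``gene_propensity_effects`` does the
    same per gene (posttranscriptional regulation of individual genes).
    ``coupling_r2`` is the target squared Pearson correlation between
    log-protein and log-mRNA within a sample; ``replicate_noise_sd`` is the
    biological replicate SD on the log10 scale, applied independently to both
    layers.
    """

    process_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_propensity_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    coupling_r2: float = 0.5
    replicate_noise_sd: float = 0.05
    mrna_log10_mean: float = 1.0
    mrna_log10_sd: float = 0.5
    propensity_log10_mean: float = 3.0


def default_effect_config() -> EffectConfig:
    """Shipped defaults mimicking the study contrasts qualitatively.

    Both evolved strains upregulate ER folding at the proteome level; the
    first evolved strain (MH34-like) trims glycosylation and amino-acid
    transport, the second (B184-like) keeps glycosylation up — the pattern
    that downstream differential-process reports should recover.
    """
    return EffectConfig(
        process_effects={
            "MH34": {"protein_folding_ER": 1.8, "protein_glycosylation": 0.7,
                     "amino_acid_transport": 0.7},
            "B184": {"protein_folding_ER": 2.0, "protein_glycosylation": 1.3,
                     "amino_acid_transport": 0.75},
        },
    )


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated experiment."""

    design: ExperimentDesign
    true_mrna: AbundanceMatrix  # molecules/cell
    true_protein: AbundanceMatrix  # molecules/cell
    propensity: pd.Series  # per-gene base protein/mRNA ratio
    generator_params: dict


def _propensity_log10_sd(cfg: EffectConfig) -> float:
    """Solve the propensity spread that hits the target coupling R².

    Within a sample, log10 protein = log10 mRNA(base) + log10 propensity +
    replicate noise, and log10 mRNA(observed) = base + replicate noise, so

        R² = Vb² / ((Vb + Vr) (Vb + Vp + Vr))

    with Vb the base mRNA variance, Vr the replicate-noise variance and Vp the
    propensity variance.  Solving for Vp gives the generator parameter.
    """
    vb = cfg.mrna_log10_sd ** 2
    vr = cfg.replicate_noise_sd ** 2
    if not (0 < cfg.coupling_r2 <= 1):
        raise ArgumentError("coupling_r2 must be in (0, 1]")
    vp = vb ** 2 / (cfg.coupling_r2 * (vb + vr)) - vb - vr
    if vp < -1e-12:
        raise ArgumentError(
            f"coupling_r2={cfg.coupling_r2} unreachable with replicate noise "
            f"sd={cfg.replicate_noise_sd}")
    return float(np.sqrt(max(vp, 0.0)))


def generate_truth(design: ExperimentDesign, annotation: list[GeneRecord],
                   effect_config: EffectConfig | None = None) -> SyntheticTruth:
    """Draw true mRNA and protein abundance layers for the whole design.

    Per gene, base mRNA is log-normal; protein is mRNA times a gene-specific
    translation propensity, times strain effects on configured processes,
    times replicate noise.  All strain/process effects present in the truth
    are recoverable by direct computation on the emitted matrices.
    """
    cfg = effect_config or default_effect_config()
    known_processes = set().union(*(r.processes for r in annotation)) if annotation else set()
    for strain, effects in cfg.process_effects.items():
        if strain not in design.strains:
            raise ArgumentError(f"effect for unknown strain {strain!r}")
        for pid in effects:
            if pid not in known_processes:
                raise ArgumentError(f"effect on unknown process id {pid!r}")
    gene_ids = [r.gene_id for r in annotation]
    for strain, effects in cfg.gene_propensity_effects.items():
        for gid in effects:
            if gid not in set(gene_ids):
                raise ArgumentError(f"propensity effect on unknown gene {gid!r}")

    rng = np.random.default_rng(design.seed)
    n = len(gene_ids)
    base_log_mrna = rng.normal(cfg.mrna_log10_mean, cfg.mrna_log10_sd, size=n)
    sd_p = _propensity_log10_sd(cfg)
    log_prop = rng.normal(cfg.propensity_log10_mean, sd_p, size=n)
    propensity = pd.Series(10.0 ** log_prop, index=gene_ids)

    samples = design.sample_ids()
    log_effect = np.zeros((n, len(samples)))
    for j, sid in enumerate(samples):
        strain = sid.split("_")[0]
        effects = cfg.process_effects.get(strain, {})
        gene_eff = cfg.gene_propensity_effects.get(strain, {})
        for i, rec in enumerate(annotation):
            f = 1.0
            for pid, mult in effects.items():
                if pid in rec.processes:
                    f *= mult
            f *= gene_eff.get(rec.gene_id, 1.0)
            log_effect[i, j] = np.log10(f)

    sd_r = cfg.replicate_noise_sd
    noise_t = rng.normal(0.0, sd_r, size=(n, len(samples))) if sd_r > 0 else np.zeros((n, len(samples)))
    noise_p = rng.normal(0.0, sd_r, size=(n, len(samples))) if sd_r > 0 else np.zeros((n, len(samples)))

    log_mrna = base_log_mrna[:, None] + noise_t
    log_protein = base_log_mrna[:, None] + log_prop[:, None] + log_effect + noise_p
    mrna = pd.DataFrame(10.0 ** log_mrna, index=gene_ids, columns=samples)
    protein = pd.DataFrame(10.0 ** log_protein, index=gene_ids, columns=samples)
    params = {
        "coupling_r2": cfg.coupling_r2,
        "replicate_noise_sd": sd_r,
        "propensity_log10_sd": sd_p,
        "mrna_log10_mean": cfg.mrna_log10_mean,
        "mrna_log10_sd": cfg.mrna_log10_sd,
        "seed": design.seed,
        "process_effects": cfg.process_effects,
        "gene_propensity_effects": cfg.gene_propensity_effects,
    }
    return SyntheticTruth(
        design=design,
        true_mrna=AbundanceMatrix(mrna, layer="mRNA", units="molecules_per_cell"),
        true_protein=AbundanceMatrix(protein, layer="protein", units="molecules_per_cell"),
        propensity=propensity,
        generator_params=params,
    )


# --------------------------------------------------------------------------
# mRNA assay
# --------------------------------------------------------------------------

@dataclass
class CalibConfig:
    """True log-linear calibration law and assay noise for one signal layer.

    The law maps measured signal to absolute concentration:
    ``log10(conc) = slope * log10(signal) + intercept``; the generator applies
    its inverse to the truth and adds log-normal measurement noise
    (``noise_sd`` on log10 signal).
    """

    slope: float = 0.9
    intercept: float = 2.0
    noise_sd: float = 0.1
    n_standards: int = 36


def _inverse_law(conc: np.ndarray, cfg: CalibConfig) -> np.ndarray:
    return (np.log10(conc) - cfg.intercept) / cfg.slope


def simulate_mrna_assay(truth: SyntheticTruth, calib_config: CalibConfig | None = None,
                        seed: int = 0) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Produce an FPKM-like signal matrix plus a spike-in standards table.

    Standards are picked by stratified quantiles of the pooled dynamic range
    so they cover it end to end; each row carries the known concentration and
    one noisy measured signal.
    """
    cfg = calib_config or CalibConfig()
    truth_df = truth.true_mrna.data
    if cfg.n_standards > len(truth_df):
        raise ArgumentError("fewer genes than requested spike-in standards")
    rng = np.random.default_rng(seed)
    log_sig = _inverse_law(truth_df.to_numpy(), cfg)
    if cfg.noise_sd > 0:
        log_sig = log_sig + rng.normal(0.0, cfg.noise_sd, size=log_sig.shape)
    signal = truth.true_mrna.with_data(
        pd.DataFrame(10.0 ** log_sig, index=truth_df.index, columns=truth_df.columns),
        units="signal")

    pooled = truth_df.mean(axis=1).sort_values()
    qidx = np.floor((np.arange(cfg.n_standards) + 0.5) / cfg.n_standards * len(pooled)).astype(int)
    std_genes = pooled.index[qidx]
    known = pooled.loc[std_genes].to_numpy()
    meas_log = _inverse_law(known, cfg)
    if cfg.noise_sd > 0:
        meas_log = meas_log + rng.normal(0.0, cfg.noise_sd, size=meas_log.shape)
    spike = pd.DataFrame({
        "standard_id": list(std_genes),
        "known_concentration": known,
        "measured_signal": 10.0 ** meas_log,
    })
    return signal, spike


# --------------------------------------------------------------------------
# protein assay
# --------------------------------------------------------------------------

@dataclass
class UPS2Config:
    """UPS2-like dynamic-range standard: known amounts plus peptide evidence.

    ``n_below_threshold`` of the ``n_standards`` proteins are emitted with
    fewer than two unique peptides, to exercise the downstream filter.  The
    calibration law plays the same role as in :class:`CalibConfig` but for the
    iBAQ signal of the pooled reference.
    """

    n_standards: int = 48
    n_below_threshold: int = 5
    slope: float = 0.95
    intercept: float = 1.5
    noise_sd: float = 0.1
    amount_log10_range: tuple[float, float] = (-0.5, 3.5)


@dataclass
class TMTConfig:
    """Noise on TMT-style sample/pooled-reference ratios (log10 SD)."""

    noise_sd: float = 0.05


def simulate_protein_assay(truth: SyntheticTruth, annotation: list[GeneRecord],
                           ups2_config: UPS2Config | None = None,
                           tmt_config: TMTConfig | None = None,
                           seed: int = 0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit (peptide intensity table, UPS2-like table, TMT ratio matrix).

    The peptide table covers the pooled reference sample (mean of the true
    protein layer); summed intensities divided by theoretical peptide counts
    reproduce the iBAQ signal the calibration law expects.  TMT ratios are
    sample/pooled-reference true ratios with log-normal noise.
    """
    ups2 = ups2_config or UPS2Config()
    tmt = tmt_config or TMTConfig()
    if ups2.n_standards < 1:
        raise ArgumentError("UPS2 config must list at least one standard")
    if ups2.n_below_threshold > ups2.n_standards:
        raise ArgumentError("more sub-threshold standards than standards")
    rng = np.random.default_rng(seed)
    prot = truth.true_protein.data
    pooled = prot.mean(axis=1)

    law = CalibConfig(slope=ups2.slope, intercept=ups2.intercept, noise_sd=ups2.noise_sd)
    log_ibaq = _inverse_law(pooled.to_numpy(), law)
    if ups2.noise_sd > 0:
        log_ibaq = log_ibaq + rng.normal(0.0, ups2.noise_sd, size=log_ibaq.shape)
    ibaq_signal = 10.0 ** log_ibaq

    ann = {r.gene_id: r for r in annotation}
    rows = []
    for gid, sig in zip(pooled.index, ibaq_signal):
        n_theor = ann[gid].n_theoretical_peptides
        n_det = int(min(n_theor, 1 + rng.poisson(3)))
        total = sig * n_theor
        weights = rng.dirichlet(np.ones(n_det)) if n_det > 1 else np.array([1.0])
        for k in range(n_det):
            rows.append((gid, f"{gid}_pep{k + 1}", total * weights[k]))
    peptides = pd.DataFrame(rows, columns=["protein_id", "peptide_id", "intensity"])

    known = 10.0 ** rng.uniform(*ups2.amount_log10_range, size=ups2.n_standards)
    meas_log = _inverse_law(known, law)
    if ups2.noise_sd > 0:
        meas_log = meas_log + rng.normal(0.0, ups2.noise_sd, size=meas_log.shape)
    n_pep = rng.integers(2, 21, size=ups2.n_standards)
    low = rng.choice(ups2.n_standards, size=ups2.n_below_threshold, replace=False)
    n_pep[low] = rng.integers(0, 2, size=ups2.n_below_threshold)
    ups2_table = pd.DataFrame({
        "standard_id": [f"UPS2_{i + 1:02d}" for i in range(ups2.n_standards)],
        "known_concentration": known,
        "measured_signal": 10.0 ** meas_log,
        "n_unique_peptides": n_pep,
    })

    ratios = prot.div(pooled, axis=0)
    if tmt.noise_sd > 0:
        ratios = ratios * 10.0 ** rng.normal(0.0, tmt.noise_sd, size=ratios.shape)
    return peptides, ups2_table, ratios


# --------------------------------------------------------------------------
# toy enzyme-constrained network
# --------------------------------------------------------------------------

@dataclass
class ToyModelConfig:
    """Parameters of the toy metabolism and of per-strain physiology.

    ATP yields are per mmol of substrate through each pathway branch; the
    strain dictionaries set the truth fluxes: product secretion scales with
    the dilution rate and a strain productivity factor, amino-acid uptake
    covers a strain-specific fraction of demand (the reference strain takes
    up the most, as a less efficient metabolism would), and true NGAM is a
    base maintenance times a strain waste factor — highest in the
    high-misfolding evolved strain, lowest in the efficient one.
    """

    atp_per_glycolysis: float = 2.0
    atp_per_respiration: float = 12.0
    o2_per_respiration: float = 2.0
    atp_per_aa_synthesis: float = 2.0
    atp_per_protein: float = 4.0
    atp_per_secretion: float = 1.0
    biomass_glc: float = 5.0
    biomass_aa: float = 2.0
    biomass_atp: float = 30.0
    product_rate_factor: dict[str, float] = field(
        default_factory=lambda: {"AAC": 1.0, "MH34": 2.0, "B184": 2.2})
    product_rate_per_d: float = 0.5  # mmol product per gDCW per unit D
    aa_uptake_fraction: dict[str, float] = field(
        default_factory=lambda: {"AAC": 0.8, "MH34": 0.55, "B184": 0.6})
    ngam_base: float = 2.0  # mmol ATP/gDCW/h
    ngam_waste: dict[str, float] = field(
        default_factory=lambda: {"AAC": 1.3, "MH34": 1.5, "B184": 1.0})
    include_ngam: bool = True
    p_total: float = 0.5  # g protein/gDCW
    sigma_true: float = 0.5  # true saturation behind recorded enzyme abundances
    biomass_gdcw_per_l: float = 2.0
    product_mw_kda: float = 54.4  # alpha-amylase-like
    residual_mmol_per_l: float = 0.1


@dataclass
class ConditionTruth:
    """Reference state of one strain x dilution-rate condition."""

    strain: str
    dilution_rate: float
    fluxes: pd.Series  # mmol/gDCW/h, steady-state consistent
    ngam: float
    enzyme_abundance: pd.Series  # mmol/gDCW
    measured_rates: pd.DataFrame  # reaction_id, rate, direction
    chemostat: ChemostatRecord


@dataclass
class ToyEcResult:
    network: MetabolicNetwork
    kcats: dict[str, float]  # reaction id -> kcat (/h)
    conditions: dict[tuple[str, float], ConditionTruth]
    config: ToyModelConfig


def _toy_network(cfg: ToyModelConfig, rng: np.random.Generator) -> MetabolicNetwork:
    mets = {m: True for m in
            ("glc", "pyr", "atp", "etoh", "o2", "co2", "aa", "prot", "amy")}
    r = cfg
    reactions = [
        Reaction("EX_glc", {"glc": 1.0}, 0, 10, role="exchange"),
        Reaction("EX_o2", {"o2": 1.0}, 0, 50, role="exchange"),
        Reaction("EX_aa", {"aa": 1.0}, 0, 10, role="exchange"),
        Reaction("GLY", {"glc": -1.0, "pyr": 2.0, "atp": r.atp_per_glycolysis}),
        Reaction("FERM", {"pyr": -1.0, "etoh": 1.0, "co2": 1.0}),
        Reaction("RESP", {"pyr": -1.0, "o2": -r.o2_per_respiration,
                          "co2": 3.0, "atp": r.atp_per_respiration}),
        Reaction("AAS", {"glc": -0.5, "atp": -r.atp_per_aa_synthesis, "aa": 1.0}),
        Reaction("PROT", {"aa": -2.0, "atp": -r.atp_per_protein, "prot": 1.0}),
        Reaction("SEC", {"prot": -1.0, "atp": -r.atp_per_secretion, "amy": 1.0},
                 role="product_secretion"),
        Reaction("EX_amy", {"amy": -1.0}, 0, 10, role="exchange"),
        Reaction("EX_etoh", {"etoh": -1.0}, 0, 50, role="exchange"),
        Reaction("EX_co2", {"co2": -1.0}, 0, 100, role="exchange"),
        Reaction("BIOMASS", {"glc": -r.biomass_glc, "aa": -r.biomass_aa,
                             "atp": -r.biomass_atp}, 0, 2, role="biomass"),
    ]
    if cfg.include_ngam:
        reactions.append(Reaction("NGAM", {"atp": -1.0}, 0, 100, role="ngam"))
    else:
        raise ArgumentError("toy model config must include an ATP-hydrolysis "
                            "(NGAM) reaction: the NGAM objective is undefined without it")
    enzymes = {}
    for rid in ("GLY", "FERM", "RESP", "AAS", "PROT", "SEC"):
        kcat = float(10 ** rng.uniform(4, 5))  # /h
        mw = float(10 ** rng.uniform(np.log10(30), np.log10(150)))  # kDa
        enzymes[rid] = EnzymeInfo(f"E_{rid}", kcat, mw)
    return MetabolicNetwork(mets, reactions, enzymes)


def _fermentation_fraction(d: float) -> float:
    """Crabtree-like shift toward fermentation at higher dilution rates."""
    return float(np.clip(2.5 * d - 0.05, 0.05, 0.8))


def _condition_fluxes(cfg: ToyModelConfig, strain: str, d: float) -> tuple[pd.Series, float]:
    q_amy = cfg.product_rate_per_d * d * cfg.product_rate_factor[strain]
    v_sec = v_prot = q_amy
    aa_demand = 2.0 * v_prot + cfg.biomass_aa * d
    q_aa = cfg.aa_uptake_fraction[strain] * aa_demand
    v_aas = aa_demand - q_aa
    ngam = cfg.ngam_base * cfg.ngam_waste[strain] * (1.0 + d)
    atp_needed = (cfg.biomass_atp * d + cfg.atp_per_aa_synthesis * v_aas
                  + cfg.atp_per_protein * v_prot + cfg.atp_per_secretion * v_sec + ngam)
    phi = _fermentation_fraction(d)
    v_gly = atp_needed / (cfg.atp_per_glycolysis + 2.0 * (1.0 - phi) * cfg.atp_per_respiration)
    v_ferm = phi * 2.0 * v_gly
    v_resp = (1.0 - phi) * 2.0 * v_gly
    q_glc = v_gly + 0.5 * v_aas + cfg.biomass_glc * d
    fluxes = pd.Series({
        "EX_glc": q_glc, "EX_o2": cfg.o2_per_respiration * v_resp, "EX_aa": q_aa,
        "GLY": v_gly, "FERM": v_ferm, "RESP": v_resp, "AAS": v_aas,
        "PROT": v_prot, "SEC": v_sec, "EX_amy": q_amy, "EX_etoh": v_ferm,
        "EX_co2": v_ferm + 3.0 * v_resp, "BIOMASS": d, "NGAM": ngam,
    })
    return fluxes, ngam


def generate_toy_ecmodel(config: ToyModelConfig | None = None, seed: int = 0,
                         design: ExperimentDesign | None = None) -> ToyEcResult:
    """Build the toy ec-network and the per-condition reference truth.

    For every strain x dilution rate the returned truth holds a flux vector
    satisfying steady state exactly, the NGAM it implies, enzyme abundances
    ``e = v / (kcat * sigma_true)`` (the "measured proteome" for recovery
    tests), the measured exchange-rate table, and a consistent chemostat
    record (feed/residual/biomass/titer reproducing the rates under the
    steady-state mass balance).
    """
    cfg = config or ToyModelConfig()
    des = design or ExperimentDesign()
    rng = np.random.default_rng(seed)
    network = _toy_network(cfg, rng)
    kcats = {rid: info.kcat for rid, info in network.enzymes.items()}

    s_mat, rxn_ids = stoichiometric_matrix(network)
    conditions: dict[tuple[str, float], ConditionTruth] = {}
    for strain in des.strains:
        if strain not in cfg.product_rate_factor:
            raise ArgumentError(f"no toy physiology configured for strain {strain!r}")
        for d in des.dilution_rates:
            fluxes, ngam = _condition_fluxes(cfg, strain, d)
            v = fluxes.loc[rxn_ids].to_numpy()
            resid = np.abs(s_mat @ v).max()
            if resid > 1e-9:  # pragma: no cover - construction guard
                raise RuntimeError(f"toy truth violates steady state (|Sv|={resid:g})")
            enz = pd.Series({
                network.enzymes[rid].enzyme_id: fluxes[rid] / (kcats[rid] * cfg.sigma_true)
                for rid in kcats})
            measured = pd.DataFrame({
                "reaction_id": ["EX_glc", "EX_aa", "EX_etoh", "EX_amy"],
                "rate": [fluxes["EX_glc"], fluxes["EX_aa"],
                         fluxes["EX_etoh"], fluxes["EX_amy"]],
                "direction": ["uptake", "uptake", "secretion", "secretion"],
            })
            x = cfg.biomass_gdcw_per_l
            res = cfg.residual_mmol_per_l
            feed = {c: res + fluxes[r] * x / d
                    for c, r in (("glucose", "EX_glc"), ("amino_acids", "EX_aa"))}
            residual = {"glucose": res, "amino_acids": res,
                        "ethanol": fluxes["EX_etoh"] * x / d}
            titer = fluxes["EX_amy"] * x / d * cfg.product_mw_kda  # mmol/L * g/mol -> mg/L
            record = ChemostatRecord(
                strain=strain, dilution_rate=d, biomass=x,
                feed_concentrations=feed, residual_concentrations=residual,
                product_titer=titer)
            conditions[(strain, d)] = ConditionTruth(
                strain=strain, dilution_rate=d, fluxes=fluxes, ngam=ngam,
                enzyme_abundance=enz, measured_rates=measured, chemostat=record)
    return ToyEcResult(network=network, kcats=kcats, conditions=conditions, config=cfg)


def stoichiometric_matrix(network: MetabolicNetwork) -> tuple[np.ndarray, list[str]]:
    """Dense S over internal metabolites; columns in reaction order."""
    mets = network.internal_metabolites
    rxn_ids = [r.id for r in network.reactions]
    s = np.zeros((len(mets), len(rxn_ids)))
    row = {m: i for i, m in enumerate(mets)}
    for j, r in enumerate(network.reactions):
        for met, coef in r.stoichiometry.items():
            if met in row:
                s[row[met], j] = coef
    return s, rxn_ids


def enzyme_abundance_matrix(toy: ToyEcResult) -> AbundanceMatrix:
    """Truth enzyme abundances as a protein AbundanceMatrix (mmol/gDCW)."""
    cols = {f"{c.strain}_{c.dilution_rate:g}": c.enzyme_abundance
            for c in toy.conditions.values()}
    return AbundanceMatrix(pd.DataFrame(cols), layer="protein", units="mmol_per_gDCW")


# --------------------------------------------------------------------------
# random small ec-networks (for exhaustive LP cross-checks)
# --------------------------------------------------------------------------

def random_small_network(seed: int, n_internal_reactions: int = 3,
                         n_metabolites: int = 2, n_enzymatic: int = 1,
                         ) -> tuple[MetabolicNetwork, float]:
    """A random bounded ec-network small enough to enumerate exhaustively.

    Structure: one uptake exchange per metabolite, ``n_internal_reactions``
    random internal conversions (one of which hydrolyses a virtual ATP pool —
    the NGAM reaction), a trivial biomass drain on the first metabolite, and
    ``n_enzymatic`` reactions coupled to enzymes with random kcats.  All
    bounds are finite and the zero flux vector is feasible, so the LP always
    has an optimum at a vertex.  Returns (network, pool_cap).
    """
    rng = np.random.default_rng(seed)
    mets = {f"m{i}": True for i in range(n_metabolites)}
    mets["atp"] = True
    reactions = [
        Reaction(f"EX_m{i}", {f"m{i}": 1.0}, 0, float(rng.uniform(1, 10)), role="exchange")
        for i in range(n_metabolites)
    ]
    met_ids = [f"m{i}" for i in range(n_metabolites)]
    for k in range(n_internal_reactions):
        sub, prod = rng.choice(met_ids, size=2, replace=False)
        stoich = {sub: -float(rng.integers(1, 3)), prod: float(rng.integers(1, 3)),
                  "atp": float(rng.integers(1, 4))}
        reactions.append(Reaction(f"R{k}", stoich, 0, float(rng.uniform(1, 10))))
    reactions.append(Reaction("NGAM", {"atp": -1.0}, 0, float(rng.uniform(5, 50)), role="ngam"))
    reactions.append(Reaction("BIOMASS", {met_ids[0]: -1.0, "atp": -float(rng.integers(1, 5))},
                              0, 1.0, role="biomass"))
    enzymes = {}
    candidates = [r.id for r in reactions if r.role == "internal"]
    rng.shuffle(candidates)
    for rid in candidates[:n_enzymatic]:
        enzymes[rid] = EnzymeInfo(f"E_{rid}", float(rng.uniform(5, 50)),
                                  float(rng.uniform(20, 100)))
    pool_cap = float(rng.uniform(5, 20))
    return MetabolicNetwork(mets, reactions, enzymes), pool_cap
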