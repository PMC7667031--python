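"""End-to-end orchestration: simulate → quantify → allocate → compare →
chemostat → NGAM, as one configured, logged, resumable run.

Everything downstream of the generator is pure computation over in-memory
objects, so a run is cheap to recompute; resumability is therefore handled
at the file level: each stage's outputs are written only when their bytes
would change, and the manifest records a hash per file plus the config hash.
Rerunning with the same config and seed touches nothing and produces a
byte-identical report bundle (the JSONL log carries no wall-clock
timestamps for the same reason).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .allocation import allocate, count_differential, diff_units
from .chemostat import product_yield_and_productivity, rates_table
from .compare import correlate_layers, translation_propensity
from .containers import ExperimentDesign
from .ecfba import apply_exchange_constraints, apply_proteomics, build_ec_model, solve_ngam
from .errors import ArgumentError
from .quant import (apply_calibration, compute_ibaq, filter_standards,
                    fit_calibration, propagate_tmt)
from .simulate import (CalibConfig, EffectConfig, TMTConfig, ToyModelConfig,
                       UPS2Config, default_effect_config, enzyme_abundance_matrix,
                       generate_annotation, generate_toy_ecmodel, generate_truth,
                       simulate_mrna_assay, simulate_protein_assay)

SCHEMA_VERSION = 1
_SEED_MOD = 2**31 - 1


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run, with study-condition defaults."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_genes: int = 2800
    ontology_size: int = 99
    strains: tuple[str, ...] = ("AAC", "MH34", "B184")
    dilution_rates: tuple[float, ...] = (0.1, 0.2)
    n_replicates: int = 2
    reference_strain: str = "AAC"
    alpha: float = 0.05
    f: float = 0.5
    sigma: float = 0.5
    flex: float = 1.03
    min_unique_peptides: int = 2
    calib: CalibConfig = field(default_factory=CalibConfig)
    ups2: UPS2Config = field(default_factory=UPS2Config)
    tmt: TMTConfig = field(default_factory=TMTConfig)
    toy: ToyModelConfig = field(default_factory=ToyModelConfig)
    effects: EffectConfig = field(default_factory=default_effect_config)

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ArgumentError("alpha must be in (0, 1]")
        if not (0 <= self.f <= 1) or not (0 <= self.sigma <= 1):
            raise ArgumentError("f and sigma must be in [0, 1]")
        if self.flex < 1:
            raise ArgumentError("flex must be >= 1")
        if self.reference_strain not in self.strains:
            raise ArgumentError("reference strain not in strain list")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (("calib", CalibConfig), ("ups2", UPS2Config),
                         ("tmt", TMTConfig), ("toy", ToyModelConfig),
                         ("effects", EffectConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("strains", "dilution_rates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineReport:
    out_dir: Path
    files: dict[str, str]  # logical name -> path
    summary: dict


class _Run:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.files: dict[str, str] = {}
        self.hashes: dict[str, str] = {}
        self.log_lines: list[dict] = []

    def log(self, stage: str, event: str, **detail) -> None:
        self.log_lines.append({"stage": stage, "event": event, **detail})

    def emit(self, name: str, filename: str, writer) -> Path:
        """Write through a callback only when the bytes would change."""
        path = self.out / filename
        tmp = self.out / (filename + ".tmp")
        writer(tmp)
        new = tmp.read_bytes()
        if path.exists() and path.read_bytes() == new:
            tmp.unlink()
            self.log("io", "unchanged", file=filename)
        else:
            tmp.replace(path)
            self.log("io", "written", file=filename)
        self.files[name] = str(path)
        self.hashes[str(path.name)] = hashlib.sha256(new).hexdigest()
        return path


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage and return the report bundle.

    Identical config + seed gives a byte-identical output directory.  Any
    stage failure propagates with the stage name prefixed; files already
    written stay on disk and are marked stale in the manifest.
    """
    run = _Run(config)
    summary: dict = {"schema_version": SCHEMA_VERSION, "config_hash": config.config_hash()}
    stage = "simulate"
    try:
        design = ExperimentDesign(config.strains, config.dilution_rates,
                                  config.n_replicates, seed=config.seed)
        annotation, ontology = generate_annotation(
            config.n_genes, config.ontology_size, seed=config.seed)
        truth = generate_truth(design, annotation, config.effects)
        mrna_signal, mrna_std = simulate_mrna_assay(
            truth, config.calib, seed=(config.seed + 1000003) % _SEED_MOD)
        peptides, ups2_table, tmt_ratios = simulate_protein_assay(
            truth, annotation, config.ups2, config.tmt,
            seed=(config.seed + 2000003) % _SEED_MOD)
        toy = generate_toy_ecmodel(config.toy, seed=(config.seed + 3000003) % _SEED_MOD,
                                   design=design)
        run.emit("annotation", "annotation.tsv",
                 lambda p: io.write_annotation_tsv(annotation, p))
        run.emit("mrna_signal", "mrna_signal.tsv",
                 lambda p: io.write_matrix_tsv(mrna_signal, p))
        run.emit("mrna_standards", "mrna_standards.tsv",
                 lambda p: io.write_frame_tsv(mrna_std, p))
        run.emit("peptides", "peptides.tsv", lambda p: io.write_frame_tsv(peptides, p))
        run.emit("ups2", "ups2_standards.tsv",
                 lambda p: io.write_frame_tsv(ups2_table, p))
        run.emit("tmt_ratios", "tmt_ratios.tsv",
                 lambda p: io.write_frame_tsv(tmt_ratios.rename_axis("gene_id"), p, index=True))
        run.emit("network", "network.json",
                 lambda p: io.write_network_json(toy.network, p))
        run.emit("chemostat", "chemostat.csv", lambda p: io.write_chemostat_csv(
            [c.chemostat for c in toy.conditions.values()], p))
        run.log(stage, "done", n_genes=config.n_genes, n_samples=len(design.sample_ids()))

        stage = "quantify"
        mrna_curve = fit_calibration(mrna_std)
        mrna_abs = apply_calibration(mrna_curve, mrna_signal)
        ibaq = compute_ibaq(peptides, annotation)
        kept = filter_standards(ups2_table, config.min_unique_peptides)
        prot_curve = fit_calibration(kept)
        ref_abs = apply_calibration(prot_curve, ibaq)
        prot_abs = propagate_tmt(ref_abs, tmt_ratios)
        run.emit("mrna_absolute", "mrna_absolute.tsv",
                 lambda p: io.write_matrix_tsv(mrna_abs, p))
        run.emit("protein_absolute", "protein_absolute.tsv",
                 lambda p: io.write_matrix_tsv(prot_abs, p))
        summary["calibration"] = {
            "mrna": asdict(mrna_curve), "protein": asdict(prot_curve),
            "ups2_retained": int(len(kept)),
        }
        run.log(stage, "done", mrna_r2=mrna_curve.r_squared, protein_r2=prot_curve.r_squared)

        stage = "allocate"
        prot_frac = allocate(prot_abs, annotation, ontology, mode="mass")
        mrna_frac = allocate(mrna_abs, annotation, ontology, mode="molar")
        run.emit("protein_fractions", "protein_fractions.tsv",
                 lambda p: io.write_frame_tsv(prot_frac.data.rename_axis("process_id"),
                                              p, index=True))
        run.emit("mrna_fractions", "mrna_fractions.tsv",
                 lambda p: io.write_frame_tsv(mrna_frac.data.rename_axis("process_id"),
                                              p, index=True))
        diff_summary = {}
        for strain in config.strains:
            if strain == config.reference_strain:
                continue
            for rate in config.dilution_rates:
                ref = design.condition_samples(config.reference_strain, rate)
                grp = design.condition_samples(strain, rate)
                diff = diff_units(prot_frac, ref, grp, alpha=config.alpha)
                name = f"diff_protein_{strain}_{rate:g}"
                run.emit(name, name + ".tsv",
                         lambda p, d=diff: io.write_frame_tsv(d, p))
                n_sig, lo, hi = count_differential(diff)
                diff_summary[name] = {"n_significant": n_sig,
                                      "log2fc_min": lo, "log2fc_max": hi}
        summary["differential"] = diff_summary
        run.log(stage, "done", contrasts=len(diff_summary))

        stage = "compare"
        corr_rows = []
        for sample in design.sample_ids():
            gene = correlate_layers(prot_abs, mrna_abs, sample, level="gene")
            proc = correlate_layers(prot_abs, mrna_abs, sample, level="process",
                                    fractions=(prot_frac, mrna_frac))
            corr_rows += [
                {"sample": sample, "level": "gene", "n_pairs": gene.n_pairs,
                 "r_squared": gene.r_squared},
                {"sample": sample, "level": "process", "n_pairs": proc.n_pairs,
                 "r_squared": proc.r_squared},
            ]
        corr = pd.DataFrame(corr_rows)
        pt = translation_propensity(prot_abs, mrna_abs)
        run.emit("correlations", "correlations.tsv", lambda p: io.write_frame_tsv(corr, p))
        run.emit("propensity", "translation_propensity.tsv",
                 lambda p: io.write_frame_tsv(pt.rename_axis("gene_id"), p, index=True))
        summary["correlation_gene_r2"] = {
            r["sample"]: r["r_squared"] for r in corr_rows if r["level"] == "gene"}
        run.log(stage, "done")

        stage = "chemostat"
        rate_rows = []
        derived_rates: dict[tuple[str, float], pd.DataFrame] = {}
        for (strain, d), cond in toy.conditions.items():
            rec = cond.chemostat
            y, prod = product_yield_and_productivity(rec)
            rates = rates_table(rec, {
                "glucose": ("EX_glc", "uptake"),
                "amino_acids": ("EX_aa", "uptake"),
                "ethanol": ("EX_etoh", "secretion"),
            })
            q_amy = prod / config.toy.product_mw_kda  # mg -> mmol via kDa==g/mmol
            rates = pd.concat([rates, pd.DataFrame([
                {"reaction_id": "EX_amy", "rate": q_amy, "direction": "secretion"}])],
                ignore_index=True)
            for _, row in rates.iterrows():
                rate_rows.append({"strain": strain, "dilution_rate": d, **row})
            derived_rates[(strain, d)] = rates
            rate_rows.append({"strain": strain, "dilution_rate": d,
                              "reaction_id": "yield_mg_per_gdcw", "rate": y,
                              "direction": "derived"})
        rates_frame = pd.DataFrame(rate_rows)
        run.emit("rates", "rates.tsv", lambda p: io.write_frame_tsv(rates_frame, p))
        run.log(stage, "done")

        stage = "ngam"
        base = build_ec_model(toy.network, p_total=config.toy.p_total,
                              f=config.f, sigma=config.sigma)
        proteome = enzyme_abundance_matrix(toy)
        ngam_rows = []
        for (strain, d), cond in toy.conditions.items():
            model = apply_proteomics(base, proteome, f"{strain}_{d:g}")
            model = apply_exchange_constraints(model, derived_rates[(strain, d)],
                                               flex=config.flex)
            sol = solve_ngam(model, d)
            ngam_rows.append({"strain": strain, "dilution_rate": d,
                              "status": sol.status, "ngam": sol.objective_value,
                              "true_ngam": cond.ngam})
        ngam_frame = pd.DataFrame(ngam_rows)
        run.emit("ngam", "ngam_summary.tsv", lambda p: io.write_frame_tsv(ngam_frame, p))
        summary["ngam"] = {
            f"{r['strain']}_{r['dilution_rate']:g}": r["ngam"] for r in ngam_rows}
        run.log(stage, "done")
    except Exception as err:
        run.log(stage, "failed", error=str(err))
        _write_manifest(run, summary, stale=True)
        raise type(err)(f"[stage {stage}] {err}") from err

    _write_manifest(run, summary, stale=False)
    return PipelineReport(out_dir=run.out, files=run.files, summary=summary)


def _write_manifest(run: _Run, summary: dict, stale: bool) -> None:
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": run.config.config_hash(),
        "stale": stale,
        "files": run.hashes,
    }
    (run.out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    (run.out / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    with open(run.out / "log.jsonl", "w") as fh:
        for line in run.log_lines:
            fh.write(json.dumps(line, sort_keys=True) + "\n")
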