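"""Signal-space to absolute-space conversion for both omics layers.

The absolute quantification chain is the same for mRNA and protein: a small
set of standards of known concentration is measured alongside the samples,
an ordinary least-squares line is fitted in log10-log10 space between known
concentration and measured signal, and the fitted law converts every signal
to an absolute value.  For protein, the signal is iBAQ (summed peptide
intensity over the number of theoretically observable peptides) of a pooled
reference sample, and per-sample absolutes follow by multiplying the pooled
reference's absolute value with each sample's TMT ratio against it.

Zero or missing signals are missing data throughout — log-space calibration
is undefined at zero, and an undetected protein must never acquire an
invented absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, GeneRecord, annotation_index
from .errors import CalibrationError, DataError, UnitsError

SPIKE_COLUMNS = ("standard_id", "known_concentration", "measured_signal")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted log10-log10 law: log10(conc) = slope*log10(signal) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    space: str = "log10-log10"

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise CalibrationError("a calibration needs at least 2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError("r_squared must lie in [0, 1]")


def _check_spike(spike: pd.DataFrame) -> None:
    missing = [c for c in SPIKE_COLUMNS if c not in spike.columns]
    if missing:
        raise DataError(f"spike-in table lacks columns {missing}")
    if (spike["known_concentration"] <= 0).any():
        raise DataError("known concentrations must be > 0")
    if (spike["measured_signal"] < 0).any():
        raise DataError("measured signals must be >= 0")


def compute_ibaq(peptides: pd.DataFrame, annotation: list[GeneRecord],
                 sample_id: str = "pooled_reference") -> AbundanceMatrix:
    """iBAQ per protein: summed detected-peptide intensity / theoretical peptides.

    If the peptide table has a ``replicate`` column, per-replicate sums are
    averaged first (technical injection replicates).  Proteins with no
    detected peptides are simply absent from the output.
    """
    for col in ("protein_id", "intensity"):
        if col not in peptides.columns:
            raise DataError(f"peptide table lacks column {col!r}")
    ann = annotation_index(annotation)
    unknown = sorted(set(peptides["protein_id"]) - set(ann))
    if unknown:
        raise DataError(f"proteins missing from annotation: {unknown[:5]}"
                        + ("..." if len(unknown) > 5 else ""))
    if "replicate" in peptides.columns:
        sums = (peptides.groupby(["protein_id", "replicate"])["intensity"].sum()
                .groupby("protein_id").mean())
    else:
        sums = peptides.groupby("protein_id")["intensity"].sum()
    ibaq = sums / pd.Series({p: ann[p].n_theoretical_peptides for p in sums.index})
    frame = ibaq.rename(sample_id).to_frame()
    return AbundanceMatrix(frame, layer="protein", units="signal")


def filter_standards(spike: pd.DataFrame, min_unique_peptides: int = 2) -> pd.DataFrame:
    """Keep standards with enough unique-peptide evidence and positive signal.

    Mirrors the UPS2 practice of trusting only standards identified with two
    or more unique peptides for the calibration fit.
    """
    _check_spike(spike)
    if "n_unique_peptides" not in spike.columns:
        raise DataError("spike-in table lacks column 'n_unique_peptides'")
    keep = (spike["n_unique_peptides"] >= min_unique_peptides) & (spike["measured_signal"] > 0)
    out = spike.loc[keep].copy()
    if out.empty:
        raise CalibrationError("all spike-in standards filtered out; calibration impossible")
    return out


def fit_calibration(spike: pd.DataFrame) -> CalibrationCurve:
    """OLS of log10(known concentration) on log10(measured signal)."""
    _check_spike(spike)
    usable = spike.loc[spike["measured_signal"] > 0]
    if len(usable) < 2:
        raise CalibrationError("need at least 2 standards with positive signal")
    x = np.log10(usable["measured_signal"].to_numpy(dtype=float))
    y = np.log10(usable["known_concentration"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise CalibrationError("degenerate fit: zero variance in measured signal")
    fit = stats.linregress(x, y)
    return CalibrationCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=min(float(fit.rvalue**2), 1.0), n_points=len(usable))


def apply_calibration(curve: CalibrationCurve, signals: AbundanceMatrix) -> AbundanceMatrix:
    """Convert a signal matrix to absolute units with a fitted curve.

    absolute = 10**(slope*log10(signal) + intercept); zero signal becomes
    missing (NaN), never infinity or a negative value.
    """
    if signals.units != "signal":
        raise UnitsError(f"expected signal-space matrix, got units {signals.units!r}")
    vals = signals.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logv = np.log10(np.where(vals > 0, vals, np.nan))
    absolute = 10.0 ** (curve.slope * logv + curve.intercept)
    frame = pd.DataFrame(absolute, index=signals.data.index, columns=signals.data.columns)
    return signals.with_data(frame, units="arbitrary_absolute")


def propagate_tmt(reference_absolute: AbundanceMatrix, tmt_ratios: pd.DataFrame,
                  ) -> AbundanceMatrix:
    """Per-sample absolutes = pooled-reference absolute x TMT ratio.

    Rows of the ratio matrix must cover every protein quantified in the
    reference; proteins absent from the reference are dropped from the
    output rather than invented.
    """
    if reference_absolute.data.shape[1] != 1:
        raise DataError("reference must be a single-column (pooled) matrix")
    if (tmt_ratios.to_numpy(dtype=float) < 0).any():
        raise DataError("TMT ratios must be >= 0")
    ref = reference_absolute.data.iloc[:, 0].dropna()
    missing = sorted(set(ref.index) - set(tmt_ratios.index))
    if missing:
        raise DataError(f"proteins lack TMT ratios: {missing[:5]}"
                        + ("..." if len(missing) > 5 else ""))
    ratios = tmt_ratios.loc[ref.index]
    frame = ratios.mul(ref, axis=0)
    return AbundanceMatrix(frame, layer="protein", units=reference_absolute.units)
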