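"""Cross-layer protein-mRNA comparisons: correlation and translation propensity.

Gene-level correlation is Pearson R-squared of log10 absolute abundances over
the genes quantified in both layers of one sample ("protein-transcript
pairs"); abundances span orders of magnitude, so log space is the scale on
which a squared correlation is meaningful.  Process-level correlation works
on untransformed process fractions, which are already commensurate.

Translation propensity P/T is absolute protein over absolute mRNA per gene
and sample — a readout of posttranscriptional regulation.  Wherever mRNA is
missing or zero, P/T is missing, never infinite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allocation import ProcessFractionTable
from .containers import AbundanceMatrix
from .errors import ArgumentError, DataError


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    n_pairs: int
    level: str  # gene | process
    transform: str  # log10 | none


def correlate_layers(protein: AbundanceMatrix, mrna: AbundanceMatrix, sample: str,
                     level: str = "gene",
                     fractions: tuple[ProcessFractionTable, ProcessFractionTable] | None = None,
                     ) -> CorrelationResult:
    """Protein-mRNA R² for one sample, at gene or process level.

    At process level pass ``fractions=(protein_fractions, mrna_fractions)``;
    the correlation then runs across the processes shared by both tables.
    """
    if level == "gene":
        if sample not in protein.sample_ids or sample not in mrna.sample_ids:
            raise DataError(f"sample {sample!r} missing from a layer")
        p = protein.data[sample]
        t = mrna.data[sample]
        common = p.index.intersection(t.index)
        pv, tv = p.loc[common], t.loc[common]
        mask = (pv > 0) & (tv > 0) & pv.notna() & tv.notna()
        x, y = np.log10(tv[mask].to_numpy()), np.log10(pv[mask].to_numpy())
        transform = "log10"
    elif level == "process":
        if fractions is None:
            raise ArgumentError("process-level correlation needs fraction tables")
        fp, ft = fractions
        common = fp.data.index.intersection(ft.data.index)
        x = ft.data.loc[common, sample].to_numpy(dtype=float)
        y = fp.data.loc[common, sample].to_numpy(dtype=float)
        transform = "none"
    else:
        raise ArgumentError("level must be 'gene' or 'process'")
    if len(x) < 3:
        raise DataError(f"only {len(x)} common pairs; need >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance in one layer; correlation degenerate")
    r = stats.pearsonr(x, y).statistic
    return CorrelationResult(r_squared=float(r * r), n_pairs=int(len(x)),
                             level=level, transform=transform)


def translation_propensity(protein: AbundanceMatrix, mrna: AbundanceMatrix) -> pd.DataFrame:
    """P/T matrix over the genes and samples shared by both layers."""
    genes = protein.data.index.intersection(mrna.data.index)
    samples = protein.data.columns.intersection(mrna.data.columns)
    if len(genes) == 0:
        raise DataError("protein and mRNA layers share no genes")
    if len(samples) == 0:
        raise DataError("protein and mRNA layers share no samples")
    p = protein.data.loc[genes, samples]
    t = mrna.data.loc[genes, samples].where(lambda v: v > 0)
    return p / t


def compare_propensity(prop: pd.DataFrame, gene: str, strain_pair: tuple[str, str],
                       rate: float) -> float:
    """Percent change of a gene's mean P/T from strain A to strain B at one rate.

    Sample columns must follow the ``strain_rate_replicate`` convention; the
    mean runs over biological replicates.
    """
    if gene not in prop.index:
        raise DataError(f"gene {gene!r} absent from propensity table")
    means = []
    for strain in strain_pair:
        prefix = f"{strain}_{rate:g}_"
        cols = [c for c in prop.columns if c.startswith(prefix)]
        if not cols:
            raise DataError(f"no samples for {strain} at rate {rate:g}")
        m = prop.loc[gene, cols].mean()
        if not np.isfinite(m) or m <= 0:
            raise DataError(f"P/T undefined for {gene} in {strain} at {rate:g}")
        means.append(m)
    return 100.0 * (means[1] - means[0]) / means[0]
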