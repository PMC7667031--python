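"""Resource allocation of absolute omics layers to bioprocess gene sets.

A process's molar fraction in a sample is the summed absolute abundance of
its member genes over the total of all quantified genes (mol/mol); the mass
fraction weighs each gene by its molecular weight first (g/g).  Genes
belonging to several processes count fully in each (the GO-Slim mapping is
many-to-many), while the denominator is always the total over all quantified
genes — so fractions across a many-to-many ontology may sum above one, but
on a partition they sum exactly to one.

Differential testing between strains at matched dilution rates uses a
two-tailed pooled-variance Student's t test on per-replicate values with the
reference strain as group A, reporting raw p-values (no multiple-testing
correction by default, optional Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, GeneRecord, Ontology, annotation_index
from .errors import ArgumentError, DataError

MODES = ("molar", "mass")


@dataclass
class ProcessFractionTable:
    """Process x sample fractions with mode (molar mol/mol or mass g/g) tag."""

    data: pd.DataFrame
    mode: str
    layer: str


def allocate(abundances: AbundanceMatrix, annotation: list[GeneRecord],
             ontology: Ontology, mode: str = "molar") -> ProcessFractionTable:
    """Allocate an absolute layer to processes as fractions of the total."""
    if mode not in MODES:
        raise ArgumentError(f"mode must be one of {MODES}")
    ann = annotation_index(annotation)
    missing = sorted(set(abundances.gene_ids) - set(ann))
    if missing:
        raise DataError(f"genes missing from annotation: {missing[:5]}"
                        + ("..." if len(missing) > 5 else ""))
    genes = abundances.gene_ids
    values = np.nan_to_num(abundances.values, nan=0.0)
    if mode == "mass":
        weights = np.array([ann[g].mol_weight for g in genes])
        values = values * weights[:, None]
    totals = values.sum(axis=0)
    dead = [s for s, t in zip(abundances.sample_ids, totals) if t <= 0]
    if dead:
        raise DataError(f"all-zero samples make fractions undefined: {dead}")
    membership = np.zeros((ontology.n_processes, len(genes)))
    for j, g in enumerate(genes):
        for pid in ann[g].processes:
            if pid in ontology:
                membership[ontology.process_ids.index(pid), j] = 1.0
    fractions = membership @ values / totals
    frame = pd.DataFrame(fractions, index=list(ontology.process_ids),
                         columns=abundances.sample_ids)
    return ProcessFractionTable(frame, mode=mode, layer=abundances.layer)


def diff_units(values: pd.DataFrame | ProcessFractionTable, group_a: list[str],
               group_b: list[str], alpha: float = 0.05,
               fdr: bool = False) -> pd.DataFrame:
    """Two-tailed Student's t test per unit (process or gene) between groups.

    ``group_a`` is the reference (e.g. the original strain at the same
    dilution rate); log2 fold change is log2(mean_b / mean_a), flagged
    missing when either mean is non-positive.  With ``fdr=True``,
    significance uses Benjamini-Hochberg-adjusted p-values instead of raw
    ones.
    """
    data = values.data if isinstance(values, ProcessFractionTable) else values
    if len(group_a) < 2 or len(group_b) < 2:
        raise ArgumentError("need >= 2 replicates per group")
    if set(group_a) & set(group_b):
        raise ArgumentError("groups must be disjoint")
    for col in [*group_a, *group_b]:
        if col not in data.columns:
            raise DataError(f"sample {col!r} not in table")
    a = data[group_a].to_numpy(dtype=float)
    b = data[group_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(b, a, axis=1, equal_var=True)
        mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
        ok = (mean_a > 0) & (mean_b > 0)
        log2fc = np.full_like(mean_a, np.nan)
        log2fc[ok] = np.log2(mean_b[ok] / mean_a[ok])
    pseries = pd.Series(pval, index=data.index)
    effective = _bh_adjust(pseries) if fdr else pseries
    significant = (effective < alpha).fillna(False)
    return pd.DataFrame({
        "unit_id": data.index,
        "log2_fold_change": log2fc,
        "t_statistic": tstat,
        "p_value": pval,
        "significant": significant.to_numpy(),
    }).set_index("unit_id", drop=False)


def _bh_adjust(p: pd.Series) -> pd.Series:
    mask = p.notna()
    q = pd.Series(np.nan, index=p.index)
    if mask.sum():
        q.loc[mask] = stats.false_discovery_control(p[mask].to_numpy(), method="bh")
    return q


def count_differential(diff: pd.DataFrame) -> tuple[int, float, float]:
    """(n significant, min log2FC, max log2FC) over significant units only."""
    if diff.empty:
        raise ArgumentError("differential table is empty")
    sig = diff.loc[diff["significant"].astype(bool), "log2_fold_change"].dropna()
    if sig.empty:
        return 0, float("nan"), float("nan")
    return int(diff["significant"].sum()), float(sig.min()), float(sig.max())
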