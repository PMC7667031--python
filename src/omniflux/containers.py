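"""Core in-memory containers shared by every pipeline stage.

Quantitative layers live in :class:`AbundanceMatrix`, a thin wrapper around a
pandas DataFrame (genes x samples) that carries the layer tag (``mRNA`` or
``protein``) and a units tag, so that signal-space and absolute-space matrices
cannot be confused silently.  Missing observations are NaN, never zero: a
transcript or protein that was not detected has no value, and log-space
calibration is undefined at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError

LAYERS = ("mRNA", "protein")

#: Units tags understood by the pipeline.  ``signal`` marks uncalibrated
#: instrument space (FPKM, iBAQ intensity); the others are absolute scales.
UNITS = ("signal", "molecules_per_cell", "fmol", "arbitrary_absolute", "mmol_per_gDCW")


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene annotation used across quantification and allocation.

    Parameters
    ----------
    gene_id:
        Stable identifier, shared between the mRNA and protein layers.
    mol_weight:
        Molecular weight of the gene product in kDa; must be positive.  Used
        for gram/gram proteome fractions and for converting enzyme usage
        bounds between molar and mass units.
    n_theoretical_peptides:
        Number of theoretically observable tryptic peptides, the iBAQ
        normaliser; at least 1.
    processes:
        Bioprocess memberships (GO-Slim-style); may be empty, may be several.
    """

    gene_id: str
    mol_weight: float
    n_theoretical_peptides: int
    processes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.mol_weight <= 0:
            raise ArgumentError(f"{self.gene_id}: mol_weight must be > 0")
        if self.n_theoretical_peptides < 1:
            raise ArgumentError(f"{self.gene_id}: n_theoretical_peptides must be >= 1")
        object.__setattr__(self, "processes", frozenset(self.processes))


@dataclass(frozen=True)
class Ontology:
    """A flat process vocabulary plus optional named gene-set collections.

    ``process_ids`` plays the role of the 99-term yeast GO-Slim bioprocess
    vocabulary; ``collections`` holds custom gene sets such as a handful of
    secretory-pathway subsystems, keyed by collection name then set id.
    """

    process_ids: tuple[str, ...]
    collections: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.process_ids)) != len(self.process_ids):
            raise ArgumentError("process identifiers must be unique")

    def __contains__(self, pid: str) -> bool:
        return pid in set(self.process_ids)

    @property
    def n_processes(self) -> int:
        return len(self.process_ids)


@dataclass(frozen=True)
class ExperimentDesign:
    """Strains x dilution rates x biological replicates factorial design."""

    strains: tuple[str, ...] = ("AAC", "MH34", "B184")
    dilution_rates: tuple[float, ...] = (0.1, 0.2)
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dilution_rates):
            raise ArgumentError("dilution rates must be positive")
        if self.n_replicates < 2:
            raise ArgumentError("need >= 2 replicates per condition for t-tests")

    def sample_ids(self) -> list[str]:
        """Sample columns named ``strain_rate_replicate``, design order."""
        return [
            f"{s}_{d:g}_r{r + 1}"
            for s in self.strains
            for d in self.dilution_rates
            for r in range(self.n_replicates)
        ]

    def condition_samples(self, strain: str, rate: float) -> list[str]:
        return [f"{strain}_{rate:g}_r{r + 1}" for r in range(self.n_replicates)]


class AbundanceMatrix:
    """Gene x sample quantitative layer with layer and units tags.

    Values are non-negative or NaN (missing).  ``data`` is a copy of the
    input frame with genes as the index and samples as columns.
    """

    def __init__(self, data: pd.DataFrame, layer: str, units: str):
        if layer not in LAYERS:
            raise ArgumentError(f"unknown layer {layer!r}; expected one of {LAYERS}")
        if units not in UNITS:
            raise ArgumentError(f"unknown units {units!r}; expected one of {UNITS}")
        values = data.to_numpy(dtype=float)
        if np.nanmin(values, initial=np.inf) < 0:
            raise DataError("abundance values must be non-negative")
        self.data = data.astype(float).copy()
        self.layer = layer
        self.units = units

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def with_data(self, data: pd.DataFrame, units: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(data, layer=self.layer, units=units or self.units)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceMatrix(layer={self.layer!r}, units={self.units!r}, "
            f"shape={self.data.shape})"
        )


def annotation_index(annotation: list[GeneRecord]) -> dict[str, GeneRecord]:
    """Index an annotation list by gene id, rejecting duplicates."""
    index: dict[str, GeneRecord] = {}
    for rec in annotation:
        if rec.gene_id in index:
            raise DataError(f"duplicate gene id in annotation: {rec.gene_id}")
        index[rec.gene_id] = rec
    return index
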