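"""Steady-state chemostat physiology: specific rates, yield, productivity.

At steady state the specific growth rate equals the dilution rate D, and a
compound's balance over the vessel reduces to simple arithmetic: what flows
in with the feed and does not remain in the broth was consumed, and anything
present in the effluent that was absent from the feed was secreted.  Rates
are normalised per gram dry cell weight so they plug directly into the
metabolic model's flux units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ArgumentError, DataError


@dataclass
class ChemostatRecord:
    """One steady-state culture: concentrations in mmol/L, titer in mg/L."""

    strain: str
    dilution_rate: float  # /h
    biomass: float  # gDCW/L
    feed_concentrations: dict[str, float] = field(default_factory=dict)
    residual_concentrations: dict[str, float] = field(default_factory=dict)
    product_titer: float = 0.0  # mg/L

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ArgumentError("dilution_rate must be > 0")
        if self.biomass <= 0:
            raise ArgumentError("biomass must be > 0")


def specific_rate(record: ChemostatRecord, compound: str, direction: str) -> float:
    """Specific uptake or secretion rate of one compound, mmol/gDCW/h.

    uptake:    q = D * (c_feed - c_residual) / X
    secretion: q = D * c_residual / X          (c_feed taken as 0)
    """
    if direction not in ("uptake", "secretion"):
        raise ArgumentError("direction must be 'uptake' or 'secretion'")
    d, x = record.dilution_rate, record.biomass
    if direction == "uptake":
        if compound not in record.feed_concentrations:
            raise DataError(f"no feed concentration for {compound!r}")
        feed = record.feed_concentrations[compound]
        residual = record.residual_concentrations.get(compound, 0.0)
        if residual > feed:
            raise DataError(
                f"{compound!r}: residual ({residual:g}) exceeds feed ({feed:g}) "
                "for a declared uptake")
        return d * (feed - residual) / x
    if compound not in record.residual_concentrations:
        raise DataError(f"no residual concentration for {compound!r}")
    return d * record.residual_concentrations[compound] / x


def total_uptake_rate(record: ChemostatRecord, compounds: list[str]) -> float:
    """Summed specific uptake over a compound panel (e.g. 14 medium amino acids)."""
    return sum(specific_rate(record, c, "uptake") for c in compounds)


def product_yield_and_productivity(record: ChemostatRecord) -> tuple[float, float]:
    """(yield mg/gDCW, productivity mg/gDCW/h) of the secreted product.

    yield = titer / X; productivity = yield * D — the steady-state identities
    for a product washing out with the effluent.
    """
    if record.product_titer < 0:
        raise ArgumentError("product titer must be >= 0")
    y = record.product_titer / record.biomass
    return y, y * record.dilution_rate


def rates_table(record: ChemostatRecord, compound_reactions: dict[str, tuple[str, str]],
                ) -> pd.DataFrame:
    """Exchange-rate table for the ec-model from one chemostat record.

    ``compound_reactions`` maps compound -> (exchange reaction id, direction).
    """
    rows = [
        {"reaction_id": rid, "rate": specific_rate(record, compound, direction),
         "direction": direction}
        for compound, (rid, direction) in compound_reactions.items()
    ]
    return pd.DataFrame(rows, columns=["reaction_id", "rate", "direction"])
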