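"""Enzyme-constrained flux balance analysis with an NGAM objective.

The model follows the GECKO mathematical form on a toy scale: a stoichiometric
network is augmented with one enzyme-usage variable per catalysed reaction,
kcat coupling constraints ``v_j <= kcat_ij * e_i``, and a shared enzyme pool

    sum_i MW_i * e_i  <=  P_total * f * sigma

with ``P_total`` the total cell protein (g protein / gDCW), ``f`` the mass
fraction of that protein assumed to be metabolic enzyme, and ``sigma`` the
average enzyme saturation.  Molecular weights in kDa are numerically equal to
g/mmol, so enzyme usages carry mmol/gDCW and fluxes mmol/gDCW/h throughout.

For chemostat conditions the biomass flux is fixed to the dilution rate and
the linear program maximises the flux through the ATP-hydrolysis maintenance
reaction (NGAM).  With all exchange fluxes measured, surplus catabolic
capacity has nowhere to go but maintenance, so the maximised NGAM reads out
the energy the cell spends beyond growth — recombinant-protein synthesis,
misfolding/degradation cycles and stress included.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .containers import AbundanceMatrix
from .errors import ArgumentError, DataError, ModelConstructionError

AVOGADRO = 6.02214076e23

#: Recognised reaction role tags.
ROLES = ("exchange", "internal", "biomass", "ngam", "product_secretion")

#: Default fallback flux bound; every bound in an EcModel must be finite so the
#: feasible region is a polytope (and vertex enumeration is well-defined).
DEFAULT_UB = 1000.0


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UB
    reversible: bool = False
    role: str = "internal"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ArgumentError(f"{self.id}: unknown role {self.role!r}")
        if not self.reversible and self.lower_bound < 0:
            raise ArgumentError(f"{self.id}: irreversible reaction with negative lower bound")
        if self.lower_bound > self.upper_bound:
            raise ArgumentError(f"{self.id}: lower bound exceeds upper bound")


@dataclass
class EnzymeInfo:
    enzyme_id: str
    kcat: float  # per hour
    mw: float  # kDa == g/mmol

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise ModelConstructionError(f"{self.enzyme_id}: kcat must be > 0")
        if self.mw <= 0:
            raise ModelConstructionError(f"{self.enzyme_id}: enzyme MW must be > 0")


@dataclass
class MetabolicNetwork:
    """Stoichiometric network; ``metabolites`` maps id -> internal flag."""

    metabolites: dict[str, bool]
    reactions: list[Reaction]
    enzymes: dict[str, EnzymeInfo] = field(default_factory=dict)  # reaction id -> enzyme

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ModelConstructionError("duplicate reaction ids")
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in self.metabolites:
                    raise ModelConstructionError(f"{r.id}: unknown metabolite {met!r}")
        for tag in ("ngam", "biomass"):
            n = sum(1 for r in self.reactions if r.role == tag)
            if n != 1:
                raise ModelConstructionError(f"network must have exactly one {tag} reaction, found {n}")
        for rid in self.enzymes:
            if rid not in set(ids):
                raise ModelConstructionError(f"enzyme mapped to unknown reaction {rid!r}")

    @property
    def internal_metabolites(self) -> list[str]:
        return [m for m, internal in self.metabolites.items() if internal]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise DataError(f"unknown reaction {rid!r}")

    @property
    def ngam_id(self) -> str:
        return next(r.id for r in self.reactions if r.role == "ngam")

    @property
    def biomass_id(self) -> str:
        return next(r.id for r in self.reactions if r.role == "biomass")


@dataclass
class _Var:
    kind: str  # "flux" or "enzyme"
    rxn_id: str | None
    direction: int  # +1 forward, -1 backward (flux vars)
    enzyme_id: str | None
    lb: float
    ub: float


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: pd.Series
    enzyme_usage: pd.Series
    message: str = ""


class EcModel:
    """LP view of an enzyme-constrained network.

    Variables are directional fluxes (reversible enzymatic reactions are split
    into forward/backward parts, each coupled to the same enzyme) plus one
    usage variable per enzyme.  Constraints: steady state on internal
    metabolites, kcat coupling, the pool constraint, and finite box bounds.
    """

    def __init__(self, network: MetabolicNetwork, pool_cap: float):
        self.network = network
        self.pool_cap = float(pool_cap)
        self.enzyme_ids: list[str] = []
        seen = set()
        for info in network.enzymes.values():
            if info.enzyme_id not in seen:
                seen.add(info.enzyme_id)
                self.enzyme_ids.append(info.enzyme_id)
        self.vars: list[_Var] = []
        for r in network.reactions:
            enzyme_id = network.enzymes[r.id].enzyme_id if r.id in network.enzymes else None
            if r.reversible and enzyme_id is not None:
                self.vars.append(_Var("flux", r.id, +1, enzyme_id, 0.0, max(r.upper_bound, 0.0)))
                self.vars.append(_Var("flux", r.id, -1, enzyme_id, 0.0, max(-r.lower_bound, 0.0)))
            else:
                self.vars.append(_Var("flux", r.id, +1, enzyme_id, r.lower_bound, r.upper_bound))
        for eid in self.enzyme_ids:
            mw = next(i.mw for i in network.enzymes.values() if i.enzyme_id == eid)
            # pool already caps the usage; keeps every bound finite
            self.vars.append(_Var("enzyme", None, 0, eid, 0.0, self.pool_cap / mw))

    # ------------------------------------------------------------------ misc
    def copy(self) -> "EcModel":
        return copy.deepcopy(self)

    def _flux_var_indices(self, rxn_id: str) -> list[int]:
        idx = [i for i, v in enumerate(self.vars) if v.kind == "flux" and v.rxn_id == rxn_id]
        if not idx:
            raise DataError(f"unknown reaction {rxn_id!r}")
        return idx

    def _enzyme_var_index(self, enzyme_id: str) -> int:
        for i, v in enumerate(self.vars):
            if v.kind == "enzyme" and v.enzyme_id == enzyme_id:
                return i
        raise DataError(f"unknown enzyme {enzyme_id!r}")

    def set_flux_bounds(self, rxn_id: str, lb: float, ub: float) -> None:
        """Set net-flux bounds on a reaction (must be non-negative for split ones)."""
        idx = self._flux_var_indices(rxn_id)
        if len(idx) == 1:
            self.vars[idx[0]].lb, self.vars[idx[0]].ub = lb, ub
        else:
            if lb < 0:
                raise ArgumentError(f"{rxn_id}: directional bounds on a split reaction must be >= 0")
            fwd = next(i for i in idx if self.vars[i].direction == 1)
            bwd = next(i for i in idx if self.vars[i].direction == -1)
            self.vars[fwd].lb, self.vars[fwd].ub = lb, ub
            self.vars[bwd].lb, self.vars[bwd].ub = 0.0, 0.0

    # -------------------------------------------------------------- assembly
    def to_lp(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[tuple[float, float]]]:
        """Assemble (A_eq, b_eq, A_ub, b_ub, bounds) dense arrays."""
        n = len(self.vars)
        mets = self.network.internal_metabolites
        A_eq = np.zeros((len(mets), n))
        met_row = {m: i for i, m in enumerate(mets)}
        for j, var in enumerate(self.vars):
            if var.kind != "flux":
                continue
            rxn = self.network.reaction(var.rxn_id)
            for met, coef in rxn.stoichiometry.items():
                if met in met_row:
                    A_eq[met_row[met], j] = coef * var.direction
        b_eq = np.zeros(len(mets))

        rows = []
        for j, var in enumerate(self.vars):
            if var.kind == "flux" and var.enzyme_id is not None:
                row = np.zeros(n)
                row[j] = 1.0
                info = self.network.enzymes[var.rxn_id]
                row[self._enzyme_var_index(var.enzyme_id)] = -info.kcat
                rows.append(row)
        pool_row = np.zeros(n)
        for eid in self.enzyme_ids:
            mw = next(i.mw for i in self.network.enzymes.values() if i.enzyme_id == eid)
            pool_row[self._enzyme_var_index(eid)] = mw
        rows.append(pool_row)
        A_ub = np.vstack(rows) if rows else np.zeros((0, n))
        b_ub = np.zeros(len(rows))
        if len(rows):
            b_ub[-1] = self.pool_cap
        bounds = [(v.lb, v.ub) for v in self.vars]
        return A_eq, b_eq, A_ub, b_ub, bounds

    def objective_vector(self, rxn_id: str) -> np.ndarray:
        c = np.zeros(len(self.vars))
        for i in self._flux_var_indices(rxn_id):
            c[i] = self.vars[i].direction
        return c

    def solution_from_x(self, x: np.ndarray) -> tuple[pd.Series, pd.Series]:
        fluxes = {r.id: 0.0 for r in self.network.reactions}
        enzymes = {}
        for val, var in zip(x, self.vars):
            if var.kind == "flux":
                fluxes[var.rxn_id] += var.direction * val
            else:
                enzymes[var.enzyme_id] = val
        return pd.Series(fluxes), pd.Series(enzymes, dtype=float)


def build_ec_model(network: MetabolicNetwork, p_total: float, f: float = 0.5,
                   sigma: float = 0.5) -> EcModel:
    """Assemble the enzyme-constrained LP from a network.

    ``p_total`` in g protein/gDCW; ``f`` the metabolic-enzyme mass fraction
    (default 0.5); ``sigma`` the mean saturation (default 0.5).  The pool cap
    is their product, in g enzyme/gDCW.
    """
    if p_total < 0 or not (0 <= f <= 1) or not (0 <= sigma <= 1):
        raise ArgumentError("require p_total >= 0, f and sigma in [0, 1]")
    return EcModel(network, pool_cap=p_total * f * sigma)


def apply_proteomics(model: EcModel, protein_abs: AbundanceMatrix, sample: str,
                     cells_per_gdcw: float = 5e10) -> EcModel:
    """Cap enzyme usages with measured absolute abundances.

    Abundances in ``mmol_per_gDCW`` are used directly; ``molecules_per_cell``
    are converted with Avogadro's number and a cells-per-gram-dry-weight
    constant.  Enzymes absent from the data stay limited by the pool only.
    """
    if sample not in protein_abs.sample_ids:
        raise DataError(f"sample {sample!r} not in proteomics matrix")
    col = protein_abs.data[sample]
    if protein_abs.units == "mmol_per_gDCW":
        caps = col
    elif protein_abs.units == "molecules_per_cell":
        caps = col * cells_per_gdcw / AVOGADRO * 1e3
    else:
        raise ArgumentError(f"cannot convert units {protein_abs.units!r} to mmol/gDCW")
    out = model.copy()
    for eid in out.enzyme_ids:
        if eid in caps.index and np.isfinite(caps[eid]):
            cap = float(caps[eid])
            if cap < 0:
                raise DataError(f"negative abundance for enzyme {eid!r}")
            j = out._enzyme_var_index(eid)
            out.vars[j].ub = min(out.vars[j].ub, cap)
    return out


def apply_exchange_constraints(model: EcModel, rates: pd.DataFrame, flex: float = 1.03) -> EcModel:
    """Bound measured exchange fluxes to ``[m/flex, m*flex]``.

    ``rates`` needs columns ``reaction_id``, ``rate`` (mmol/gDCW/h, >= 0 in the
    declared direction) and ``direction`` (uptake/secretion, informational —
    exchange reactions are written so positive flux is the physiological
    direction).  ``flex`` (>= 1) is the flexibility factor that keeps the LP
    from being overconstrained by measurement error.
    """
    if flex < 1.0:
        raise ArgumentError("flex must be >= 1")
    known = {r.id for r in model.network.reactions}
    out = model.copy()
    for _, row in rates.iterrows():
        rid = row["reaction_id"]
        if rid not in known:
            raise DataError(f"rate given for unknown exchange reaction {rid!r}")
        m = float(row["rate"])
        if m < 0:
            raise DataError(f"{rid}: measured rate must be >= 0 in its declared direction")
        out.set_flux_bounds(rid, m / flex, m * flex)
    return out


def fba(model: EcModel, objective_reaction: str, sense: str = "max") -> FluxSolution:
    """Solve the ec-LP for one objective reaction's net flux."""
    if sense not in ("max", "min"):
        raise ArgumentError("sense must be 'max' or 'min'")
    A_eq, b_eq, A_ub, b_ub, bounds = model.to_lp()
    c = model.objective_vector(objective_reaction)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    empty = pd.Series(dtype=float)
    if res.status == 2:
        return FluxSolution("infeasible", float("nan"), empty, empty, res.message)
    if res.status == 3:
        return FluxSolution("unbounded", float("nan"), empty, empty, res.message)
    if not res.success:  # pragma: no cover - solver hiccups
        raise RuntimeError(f"LP solver failed: {res.message}")
    fluxes, enzymes = model.solution_from_x(res.x)
    return FluxSolution("optimal", float(c @ res.x), fluxes, enzymes)


def solve_ngam(model: EcModel, dilution_rate: float) -> FluxSolution:
    """Fix growth to the dilution rate and maximise maintenance ATP hydrolysis.

    In a chemostat at steady state the specific growth rate equals the
    dilution rate, so the biomass flux is pinned to ``dilution_rate`` and the
    LP maximises the NGAM reaction flux.
    """
    if dilution_rate <= 0:
        raise ArgumentError("dilution_rate must be > 0")
    fixed = model.copy()
    fixed.set_flux_bounds(fixed.network.biomass_id, dilution_rate, dilution_rate)
    sol = fba(fixed, fixed.network.ngam_id, sense="max")
    if sol.status == "infeasible":
        pinned = [
            f"{v.rxn_id}:[{v.lb:g},{v.ub:g}]"
            for v in fixed.vars
            if v.kind == "flux" and v.lb > 0
        ]
        sol.message = (
            f"infeasible at growth={dilution_rate:g}; active lower-bounded fluxes: "
            + ", ".join(pinned)
        )
    return sol
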