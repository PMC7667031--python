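"""Exhaustive cross-checks for the ec-FBA linear programs.

Every bound in an :class:`~omniflux.ecfba.EcModel` is finite, so the feasible
region is a polytope and any linear objective attains its optimum at a
vertex (a basic feasible solution).  On small models the vertices can be
enumerated outright: convert the LP to standard equality form with slack
variables, pin ``n - rank(A)`` variables at a bound in every possible way,
and solve for the rest.  The best feasible objective over all such points is
the exact LP optimum — an oracle entirely independent of the simplex solver.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .ecfba import EcModel, FluxSolution


def standard_form(model: EcModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(A, b, lb, ub) with A x = b and finite box bounds, slacks appended."""
    A_eq, b_eq, A_ub, b_ub, bounds = model.to_lp()
    lb = np.array([lo for lo, _ in bounds], dtype=float)
    ub = np.array([hi for _, hi in bounds], dtype=float)
    m_ub = A_ub.shape[0]
    if m_ub == 0:
        return A_eq, b_eq, lb, ub
    # slack s_i = b_i - a_i.x  in [0, b_i - min_box(a_i.x)]
    slack_ub = b_ub - np.minimum(A_ub * lb, A_ub * ub).sum(axis=1)
    A = np.block([[A_eq, np.zeros((A_eq.shape[0], m_ub))],
                  [A_ub, np.eye(m_ub)]])
    b = np.concatenate([b_eq, b_ub])
    lb = np.concatenate([lb, np.zeros(m_ub)])
    ub = np.concatenate([ub, slack_ub])
    return A, b, lb, ub


def enumerate_lp_max(c: np.ndarray, A: np.ndarray, b: np.ndarray,
                     lb: np.ndarray, ub: np.ndarray,
                     tol: float = 1e-7) -> float | None:
    """Maximum of ``c @ x`` over {A x = b, lb <= x <= ub} by brute force.

    Returns None if no feasible basic solution exists.  Intended for systems
    with at most ~12 variables after slack augmentation.
    """
    n = len(c)
    r = int(np.linalg.matrix_rank(A)) if A.size else 0
    n_pin = n - r
    scale = 1.0 + float(np.abs(b).max(initial=0.0))
    best: float | None = None
    for pinned in combinations(range(n), n_pin):
        free = [j for j in range(n) if j not in pinned]
        Af = A[:, free]
        Ap = A[:, pinned]
        for pattern in product((0, 1), repeat=n_pin):
            xp = np.array([lb[j] if s == 0 else ub[j] for j, s in zip(pinned, pattern)])
            rhs = b - Ap @ xp
            xf, *_ = np.linalg.lstsq(Af, rhs, rcond=None)
            if np.abs(Af @ xf - rhs).max(initial=0.0) > tol * scale:
                continue
            x = np.empty(n)
            x[list(pinned)] = xp
            x[free] = xf
            if (x < lb - tol * scale).any() or (x > ub + tol * scale).any():
                continue
            obj = float(c @ x)
            if best is None or obj > best:
                best = obj
    return best


def enumerate_objective(model: EcModel, objective_reaction: str,
                        sense: str = "max") -> float | None:
    """Exact LP optimum of a reaction's net flux by vertex enumeration."""
    A, b, lb, ub = standard_form(model)
    c_core = model.objective_vector(objective_reaction)
    c = np.concatenate([c_core, np.zeros(len(lb) - len(c_core))])
    if sense == "min":
        best = enumerate_lp_max(-c, A, b, lb, ub)
        return None if best is None else -best
    return enumerate_lp_max(c, A, b, lb, ub)


def max_violation(model: EcModel, sol: FluxSolution) -> float:
    """Largest violation of steady state, bounds, coupling or pool by a solution."""
    net = model.network
    worst = 0.0
    balances = {m: 0.0 for m in net.internal_metabolites}
    for r in net.reactions:
        v = sol.fluxes[r.id]
        # net-flux window from the (possibly tightened) model variables
        idx = model._flux_var_indices(r.id)
        lo = sum(model.vars[i].lb if model.vars[i].direction == 1 else -model.vars[i].ub
                 for i in idx)
        hi = sum(model.vars[i].ub if model.vars[i].direction == 1 else -model.vars[i].lb
                 for i in idx)
        worst = max(worst, lo - v, v - hi)
        for met, coef in r.stoichiometry.items():
            if met in balances:
                balances[met] += coef * v
    worst = max(worst, max(abs(x) for x in balances.values()) if balances else 0.0)
    pool = 0.0
    for rid, info in net.enzymes.items():
        e = sol.enzyme_usage[info.enzyme_id]
        worst = max(worst, -e, abs(sol.fluxes[rid]) - info.kcat * e)
    for eid in set(i.enzyme_id for i in net.enzymes.values()):
        mw = next(i.mw for i in net.enzymes.values() if i.enzyme_id == eid)
        e = sol.enzyme_usage[eid]
        cap = model.vars[model._enzyme_var_index(eid)].ub
        worst = max(worst, e - cap)
        pool += mw * e
    worst = max(worst, pool - model.pool_cap)
    return float(worst)
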