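"""Array-level LP/QP solves used by the community and extraction machinery.

All linear programs go through scipy's HiGHS interface; the quadratic
growth-allocation program goes through OSQP. Both are deterministic for a
fixed problem, so every pipeline stage is reproducible without seeding the
solver itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

FEASIBILITY_TOL = 1e-8


class SolverError(RuntimeError):
    """Raised when an optimization terminates without a usable solution."""


@dataclass
class LinearStructure:
    """Stoichiometric matrix plus bounds in column (reaction) order."""

    S: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {r: i for i, r in enumerate(self.reaction_ids)}

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def column(self, reaction_id: str) -> int:
        return self._index[reaction_id]


def structure_from_cobra(model) -> LinearStructure:
    """Assemble S, lb, ub from a cobra model without touching its solver."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lb = np.empty(len(model.reactions))
    ub = np.empty(len(model.reactions))
    rxn_ids = []
    for j, rxn in enumerate(model.reactions):
        rxn_ids.append(rxn.id)
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coef in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            vals.append(float(coef))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return LinearStructure(S, lb, ub, rxn_ids, [m.id for m in model.metabolites])


def solve_lp(
    struct: LinearStructure,
    objective: dict[str, float],
    sense: str = "max",
    extra_constraints: list[tuple[dict[str, float], float, float]] | None = None,
    fixed: dict[str, float] | None = None,
) -> tuple[str, np.ndarray | None, float]:
    """Maximize/minimize a linear objective over {S v = 0, lb <= v <= ub}.

    extra_constraints: list of (coef-dict, lower, upper) row constraints.
    fixed: reaction -> value pins (applied as tightened bounds).
    Returns (status, flux vector or None, objective value).
    """
    n = struct.n_reactions
    c = np.zeros(n)
    for rid, coef in objective.items():
        c[struct.column(rid)] += coef
    if sense == "max":
        c = -c
    elif sense != "min":
        raise ValueError(f"unknown sense {sense!r}")

    lb = struct.lb.copy()
    ub = struct.ub.copy()
    if fixed:
        for rid, value in fixed.items():
            j = struct.column(rid)
            lb[j] = max(lb[j], value)
            ub[j] = min(ub[j], value)

    A_ub_rows = []
    b_ub = []
    if extra_constraints:
        for coefs, lower, upper in extra_constraints:
            row = np.zeros(n)
            for rid, coef in coefs.items():
                row[struct.column(rid)] += coef
            if np.isfinite(upper):
                A_ub_rows.append(row)
                b_ub.append(upper)
            if np.isfinite(lower):
                A_ub_rows.append(-row)
                b_ub.append(-lower)

    res = linprog(
        c,
        A_ub=np.array(A_ub_rows) if A_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=struct.S,
        b_eq=np.zeros(struct.S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        return "infeasible", None, np.nan
    if res.status != 0:
        return f"failed({res.status})", None, np.nan
    value = float(res.fun)
    if sense == "max":
        value = -value
    return "optimal", res.x, value


def solve_l2_growth_qp(
    struct: LinearStructure,
    growth_columns: dict[str, int],
    community_row: dict[int, float],
    min_community_growth: float,
) -> tuple[str, np.ndarray | None]:
    """Minimize sum of squared growth fluxes subject to the flux polytope
    and sum_i a_i mu_i >= min_community_growth.

    growth_columns: member name -> column index of its biomass flux.
    community_row: column index -> abundance coefficient a_i.
    """
    import osqp

    n = struct.n_reactions
    P = sparse.diags(
        [2.0 if j in set(growth_columns.values()) else 0.0 for j in range(n)],
        format="csc",
    )
    q = np.zeros(n)
    arow = np.zeros(n)
    for j, a in community_row.items():
        arow[j] = a
    A = sparse.vstack(
        [struct.S, sparse.eye(n, format="csr"), sparse.csr_matrix(arow)]
    ).tocsc()
    m = struct.S.shape[0]
    l = np.concatenate([np.zeros(m), struct.lb, [min_community_growth]])
    u = np.concatenate([np.zeros(m), struct.ub, [np.inf]])

    status = "unsolved"
    for eps in (1e-9, 1e-8, 1e-7):
        solver = osqp.OSQP()
        solver.setup(
            P=P,
            q=q,
            A=A,
            l=l,
            u=u,
            verbose=False,
            eps_abs=eps,
            eps_rel=eps,
            max_iter=200_000,
            polish=True,
            scaled_termination=False,
        )
        res = solver.solve()
        status = res.info.status.lower()
        if status == "solved":
            return "optimal", np.asarray(res.x)
    return status, None
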