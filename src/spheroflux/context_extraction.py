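"""Context-specific submodel extraction from reaction confidences.

A cost-penalized dependency assessment in the CORDA spirit: every
high-confidence (3) reaction that can carry flux in the base model is a
target that the extracted model must support; for each target we solve a
flux-distribution LP that forces the target above a flux threshold while
minimizing the penalty-weighted total |flux| through not-yet-included low-
and medium-confidence reactions. Small uniform random cost perturbations
over R repetitions reveal alternative supports; every penalized reaction
used above the threshold in any repetition is promoted into the model. The
result is pruned to a flux-consistent submodel containing the biomass
reaction and the medium exchanges.

The procedure is deterministic given the seed and honors the contract of
including as many high-confidence reactions as possible while minimizing
the inclusion of absent (low-confidence) ones and keeping the model able to
grow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from ._solver import solve_lp, structure_from_cobra
from .model_core import (
    MediumDefinition,
    apply_medium,
    biomass_reaction_id,
    exchange_reactions,
)


class ExtractionError(RuntimeError):
    """Biomass cannot be produced even with every reaction available."""


@dataclass
class ExtractionConfig:
    penalty_low: float = 100.0  # cost of including a confidence-1 reaction
    penalty_mid: float = 1.0  # cost of including a confidence-2 reaction
    flux_threshold: float = 1e-4  # a reaction "supports" above this |flux|
    repetitions: int = 5
    perturbation: float = 0.1  # relative cost jitter per repetition
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.penalty_low > self.penalty_mid > 0:
            raise ValueError("need penalty_low > penalty_mid > 0")
        if self.flux_threshold <= 0:
            raise ValueError("flux_threshold must be positive")


def _support_lp(
    struct, costs: np.ndarray, target_col: int, threshold: float, forward: bool
) -> np.ndarray | None:
    """min sum costs*|v| s.t. S v = 0, bounds, and |v_target| >= threshold."""
    n = struct.n_reactions
    lb, ub = struct.lb.copy(), struct.ub.copy()
    if forward:
        lb[target_col] = max(lb[target_col], threshold)
    else:
        ub[target_col] = min(ub[target_col], -threshold)
    if lb[target_col] > ub[target_col]:
        return None
    S = struct.S
    A_eq = sparse.hstack([S, -S], format="csr")
    eye = sparse.eye(n, format="csr")
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, eye])], format="csr"
    )
    b_ub = np.concatenate([ub, -lb])
    bounds = [(0, max(u, 0.0)) for u in ub] + [(0, max(-l, 0.0)) for l in lb]
    res = linprog(
        np.concatenate([costs, costs]),
        A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
        bounds=bounds, method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n] - res.x[n:]


def _consistent_reactions(model, tol: float = 1e-7) -> set[str]:
    """Reaction ids able to carry flux, via cobra's fastcc."""
    from cobra.flux_analysis import fastcc

    if len(model.reactions) == 0:
        return set()
    consistent = fastcc(model, flux_threshold=max(tol, 1e-6))
    return {r.id for r in consistent.reactions}


def extract_context_model(
    base,
    reaction_confidence: dict[str, int],
    cfg: ExtractionConfig,
    medium: MediumDefinition,
):
    """Extract a flux-consistent context model honoring the confidences.

    Returns (model, log) where log is a per-reaction decision table.
    """
    missing = [r.id for r in base.reactions if r.id not in reaction_confidence]
    if missing:
        raise ValueError(f"reactions without confidence: {missing[:5]} ...")

    working = base.copy()
    apply_medium(working, medium)
    biomass = biomass_reaction_id(working)

    if (working.slim_optimize(error_value=0.0) or 0.0) <= 1e-9:
        blocked = _blocking_biomass_precursors(working, biomass)
        raise ExtractionError(
            "biomass is not producible even with all reactions present; "
            f"unproducible precursors: {blocked or 'unresolved'}"
        )

    medium_ex = {
        r.id
        for r in exchange_reactions(working)
        if medium.uptake(next(iter(r.metabolites)).id) > 0
    }
    required = medium_ex | {biomass}

    consistent = _consistent_reactions(working)
    conf3 = {r for r, c in reaction_confidence.items() if c == 3}
    targets = sorted((conf3 & consistent) | (required & consistent) | {biomass})
    included = set(targets) | required

    struct = structure_from_cobra(working)
    base_cost = np.zeros(struct.n_reactions)
    for rid, conf in reaction_confidence.items():
        if rid in included:
            continue
        j = struct.column(rid)
        base_cost[j] = cfg.penalty_low if conf == 1 else (
            cfg.penalty_mid if conf == 2 else 0.0
        )

    rng = np.random.default_rng(cfg.seed)
    support_of: dict[str, str] = {}
    for target in targets:
        j = struct.column(target)
        # force the target at an attainability-scaled level (>= the flux
        # threshold, 10% of its maximum under the medium) so that supporting
        # reactions with small stoichiometric coefficients still rise above
        # the promotion threshold
        _, _, vmax = solve_lp(struct, {target: 1.0}, sense="max")
        _, _, vmin = solve_lp(struct, {target: 1.0}, sense="min")
        force_fwd = force_rev = None
        if np.isfinite(vmax) and vmax >= cfg.flux_threshold:
            force_fwd = max(cfg.flux_threshold, 0.1 * vmax)
        if np.isfinite(vmin) and vmin <= -cfg.flux_threshold:
            force_rev = max(cfg.flux_threshold, 0.1 * abs(vmin))
        for _ in range(cfg.repetitions):
            costs = base_cost * (
                1.0 + cfg.perturbation * rng.random(struct.n_reactions)
            )
            v = None
            if force_fwd is not None:
                v = _support_lp(struct, costs, j, force_fwd, True)
            if v is None and force_rev is not None:
                v = _support_lp(struct, costs, j, force_rev, False)
            if v is None:
                continue
            used = np.abs(v) > cfg.flux_threshold
            for k in np.flatnonzero(used & (base_cost > 0)):
                rid = struct.reaction_ids[k]
                included.add(rid)
                support_of.setdefault(rid, target)
                base_cost[k] = 0.0

    # flux-consistency prune on the included subnetwork
    sub = working.copy()
    sub.remove_reactions(
        [r for r in sub.reactions if r.id not in included], remove_orphans=True
    )
    keep = _consistent_reactions(sub)
    keep |= {biomass}
    sub.remove_reactions(
        [r for r in sub.reactions if r.id not in keep], remove_orphans=True
    )
    sub.id = f"{base.id}_context"
    sub.objective = biomass

    rows = []
    for rxn in base.reactions:
        decision = "included" if rxn.id in {r.id for r in sub.reactions} \
            else "excluded"
        rows.append(
            (rxn.id, reaction_confidence[rxn.id], decision,
             support_of.get(rxn.id, ""))
        )
    log = pd.DataFrame(
        rows, columns=["reaction", "confidence", "decision", "supporting_target"]
    )
    return sub, log


def _blocking_biomass_precursors(model, biomass: str) -> list[str]:
    """Biomass substrates that cannot be produced at all (demand test)."""
    import cobra

    blocked = []
    rxn = model.reactions.get_by_id(biomass)
    for met, coef in rxn.metabolites.items():
        if coef >= 0:
            continue
        with model as m:
            dm = cobra.Reaction(f"__DM_{met.id}")
            m.add_reactions([dm])
            dm.add_metabolites({m.metabolites.get_by_id(met.id): -1})
            dm.bounds = (0, 1000)
            m.objective = dm
            if (m.slim_optimize(error_value=0.0) or 0.0) <= 1e-9:
                blocked.append(met.id)
    return blocked
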