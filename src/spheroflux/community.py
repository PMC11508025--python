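"""Abundance-weighted community models and the two-stage cooperative trade-off.

A community model joins member models through a shared medium compartment
"m". Each member keeps its internal reactions under a ``<member>__`` prefix;
its boundary (exchange) reactions are rewritten into member-exchange
reactions ``<member>__EX_<met>_m`` that couple the member's extracellular
metabolite to the shared pool, entering the medium mass balance with the
member's relative abundance a_i as the stoichiometric coefficient. One
community exchange ``EX_<met>_m`` per shared metabolite connects the pool to
the environment, with uptake limited by the growth medium.

Stage 1 maximizes community growth mu_community = sum_i a_i mu_i under
steady-state mass balance and all bound constraints. Stage 2 (the cooperative
trade-off) minimizes sum_i mu_i^2 subject to retaining at least a fraction
alpha of the stage-1 optimum, which distributes growth as evenly as the flux
polytope allows. Because stage 2 pins only the growth rates, reported fluxes
are additionally passed through a parsimony (minimum total |flux|) tie-break
and labeled as one optimal pattern among possibly many.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from ._solver import (
    FEASIBILITY_TOL,
    LinearStructure,
    SolverError,
    solve_l2_growth_qp,
    solve_lp,
    structure_from_cobra,
)
from .model_core import MediumDefinition, biomass_reaction_id, doubling_time

__all__ = [
    "CommunityMember",
    "CommunityModel",
    "FluxSolution",
    "TradeoffConfig",
    "build_community",
    "community_fba",
    "cooperative_tradeoff",
    "doubling_time",
]

ABUNDANCE_TOL = 1e-9
GROWTH_BALANCE_TOL = 1e-6


@dataclass
class TradeoffConfig:
    """Trade-off parameter alpha in [0, 1]; 1.0 is full cooperation."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass
class CommunityMember:
    name: str
    abundance: float
    biomass_reaction: str  # namespaced id inside the community model


@dataclass
class FluxSolution:
    fluxes: pd.Series
    member_growth: dict[str, float]
    community_growth: float
    objective_stage: str  # "stage1" or "tradeoff"
    status: str
    metadata: dict = field(default_factory=dict)


class CommunityModel:
    """Assembled community: cobra model + members + shared medium."""

    def __init__(
        self,
        model: cobra.Model,
        members: list[CommunityMember],
        medium: MediumDefinition,
        min_growth: dict[str, float],
    ):
        self.model = model
        self.members = members
        self.medium = medium
        self.min_growth = min_growth

    @property
    def member_names(self) -> list[str]:
        return [m.name for m in self.members]

    @property
    def abundances(self) -> dict[str, float]:
        return {m.name: m.abundance for m in self.members}

    def member_exchange_id(self, member: str, metabolite_stub: str) -> str:
        return f"{member}__EX_{metabolite_stub}_m"

    def community_exchange_id(self, metabolite_stub: str) -> str:
        return f"EX_{metabolite_stub}_m"

    def shared_metabolite_stubs(self) -> list[str]:
        return [
            m.id[:-2] for m in self.model.metabolites if m.compartment == "m"
        ]

    def community_exchange_ids(self) -> list[str]:
        return [
            r.id for r in self.model.reactions
            if r.id.startswith("EX_") and r.id.endswith("_m") and "__" not in r.id
        ]

    def member_exchange_ids(self, member: str | None = None) -> list[str]:
        prefixes = [f"{m}__EX_" for m in self.member_names] if member is None \
            else [f"{member}__EX_"]
        return [
            r.id for r in self.model.reactions
            if r.id.endswith("_m") and any(r.id.startswith(p) for p in prefixes)
        ]


def _shared_stub(met_id: str) -> str:
    return met_id[:-2] if met_id.endswith("_e") else met_id


def build_community(
    members: dict[str, cobra.Model] | list[tuple[str, cobra.Model]],
    abundances: dict[str, float],
    medium: MediumDefinition,
    min_growth: dict[str, float] | None = None,
    open_bound: float = 1000.0,
) -> CommunityModel:
    """Assemble member models into one community with a shared medium.

    Abundances must be positive and sum to 1. Member-exchange bounds
    constrain the abundance-scaled flux a_i * v (so a member's stated
    exchange limits apply to its aggregate, population-level exchange);
    community exchange uptake is limited by the medium, secretion is open.
    """
    if isinstance(members, dict):
        members = list(members.items())
    names = [n for n, _ in members]
    if set(names) != set(abundances):
        raise ValueError("abundance keys must match member names")
    total = sum(abundances.values())
    if abs(total - 1.0) > ABUNDANCE_TOL:
        raise ValueError(f"abundances must sum to 1 (got {total!r})")
    if any(a <= 0 for a in abundances.values()):
        raise ValueError("abundances must be positive")
    min_growth = dict(min_growth or {})

    community = cobra.Model("community")
    shared: dict[str, cobra.Metabolite] = {}
    member_records = []

    def shared_met(stub: str, template: cobra.Metabolite) -> cobra.Metabolite:
        if stub not in shared:
            met = cobra.Metabolite(
                f"{stub}_m", name=template.name, formula=template.formula,
                charge=template.charge, compartment="m",
            )
            shared[stub] = met
            community.add_metabolites([met])
        return shared[stub]

    for name, source in members:
        a = abundances[name]
        biomass_id = biomass_reaction_id(source)
        met_map = {}
        for met in source.metabolites:
            clone = cobra.Metabolite(
                f"{name}__{met.id}", name=met.name, formula=met.formula,
                charge=met.charge, compartment=f"{name}__{met.compartment}",
            )
            met_map[met.id] = clone
        community.add_metabolites(list(met_map.values()))

        new_reactions = []
        for rxn in source.reactions:
            mets = rxn.metabolites
            is_exchange = len(mets) == 1
            met0 = next(iter(mets)) if is_exchange else None
            if is_exchange and met0.compartment == "e":
                stub = _shared_stub(met0.id)
                new = cobra.Reaction(
                    f"{name}__EX_{stub}_m",
                    name=f"{name} exchange of {stub} with medium",
                    lower_bound=rxn.lower_bound / a,
                    upper_bound=rxn.upper_bound / a,
                )
                new.add_metabolites(
                    {met_map[met0.id]: -1.0, shared_met(stub, met0): a}
                )
                new.subsystem = "Member exchange"
            else:
                new = cobra.Reaction(
                    f"{name}__{rxn.id}", name=rxn.name,
                    lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
                )
                new.add_metabolites(
                    {met_map[m.id]: coef for m, coef in mets.items()}
                )
                new.subsystem = rxn.subsystem
            new_reactions.append(new)
        community.add_reactions(new_reactions)
        for rxn in source.reactions:  # GPRs after reactions exist
            if len(rxn.metabolites) == 1 and \
                    next(iter(rxn.metabolites)).compartment == "e":
                continue
            if rxn.gene_reaction_rule:
                community.reactions.get_by_id(
                    f"{name}__{rxn.id}"
                ).gene_reaction_rule = rxn.gene_reaction_rule

        ns_biomass = f"{name}__{biomass_id}"
        floor = min_growth.get(name, 0.0)
        if floor > 0:
            community.reactions.get_by_id(ns_biomass).lower_bound = floor
        member_records.append(CommunityMember(name, a, ns_biomass))

    # one community exchange per shared metabolite; medium keys use the
    # member-side extracellular ids ("gal_e")
    ex_rxns = []
    for stub, met in shared.items():
        ex = cobra.Reaction(
            f"EX_{stub}_m", name=f"community exchange of {stub}",
            lower_bound=-medium.uptake(f"{stub}_e"), upper_bound=open_bound,
        )
        ex.add_metabolites({met: -1.0})
        ex.subsystem = "Community exchange"
        ex_rxns.append(ex)
    community.add_reactions(ex_rxns)

    community.objective = {
        community.reactions.get_by_id(m.biomass_reaction): m.abundance
        for m in member_records
    }
    cm = CommunityModel(community, member_records, medium,
                        {m.name: min_growth.get(m.name, 0.0)
                         for m in member_records})
    return cm


def _extract_solution(
    cm: CommunityModel, struct: LinearStructure, x: np.ndarray, stage: str,
    metadata: dict,
) -> FluxSolution:
    fluxes = pd.Series(x, index=struct.reaction_ids)
    growth = {
        m.name: float(fluxes[m.biomass_reaction]) for m in cm.members
    }
    community_growth = float(
        sum(cm.abundances[n] * g for n, g in growth.items())
    )
    return FluxSolution(
        fluxes=fluxes,
        member_growth=growth,
        community_growth=community_growth,
        objective_stage=stage,
        status="optimal",
        metadata=metadata,
    )


def community_fba(cm: CommunityModel) -> FluxSolution:
    """Stage-1 LP: maximize sum_i a_i mu_i over the community polytope."""
    struct = structure_from_cobra(cm.model)
    objective = {m.biomass_reaction: m.abundance for m in cm.members}
    status, x, value = solve_lp(struct, objective, sense="max")
    if status != "optimal":
        floors = {n: g for n, g in cm.min_growth.items() if g > 0}
        detail = (
            f" (member growth floors in force: {floors})" if floors
            else " (check medium uptake bounds and member exchanges)"
        )
        raise SolverError(
            f"community FBA {status}: likely binding constraint class: "
            + ("min-growth floors" if floors else "medium/exchange bounds")
            + detail
        )
    return _extract_solution(
        cm, struct, x, "stage1",
        {"solver": "scipy-highs", "feasibility_tol": FEASIBILITY_TOL},
    )


def _parsimony_pass(
    struct: LinearStructure, growth_pins: dict[str, float],
    pin_tol: float = 1e-7,
) -> np.ndarray | None:
    """Minimize sum |v| with member growths pinned; returns fluxes or None."""
    n = struct.n_reactions
    lb = struct.lb.copy()
    ub = struct.ub.copy()
    for rid, mu in growth_pins.items():
        j = struct.column(rid)
        lb[j] = max(lb[j], mu - pin_tol)
        ub[j] = min(ub[j], mu + pin_tol)
    # v = p - q with p, q >= 0; min sum(p + q)
    S = struct.S
    A_eq = sparse.hstack([S, -S], format="csr")
    eye = sparse.eye(n, format="csr")
    A_ub = sparse.vstack(
        [sparse.hstack([eye, -eye]), sparse.hstack([-eye, eye])], format="csr"
    )
    b_ub = np.concatenate([ub, -lb])
    bounds = [(0, max(u, 0.0)) for u in ub] + [(0, max(-l, 0.0)) for l in lb]
    res = linprog(
        np.ones(2 * n), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n] - res.x[n:]


def cooperative_tradeoff(
    cm: CommunityModel, cfg: TradeoffConfig | None = None,
    parsimony: bool = True,
) -> FluxSolution:
    """Two-stage solve: stage-1 optimum, then min sum mu_i^2 at fraction alpha.

    The QP is solved jointly over the full flux polytope (member growths are
    ordinary flux variables), matching the stated two-stage formulation
    literally. With alpha = 1 the returned community growth equals the
    stage-1 optimum to solver tolerance. Fluxes are post-processed by a
    parsimony (min sum |v|) tie-break with the member growths pinned, and
    flagged as one optimal flux pattern rather than the unique one.
    """
    cfg = cfg or TradeoffConfig()
    stage1 = community_fba(cm)
    mu_c = stage1.community_growth

    struct = structure_from_cobra(cm.model)
    growth_cols = {
        m.name: struct.column(m.biomass_reaction) for m in cm.members
    }
    community_row = {
        struct.column(m.biomass_reaction): m.abundance for m in cm.members
    }
    status, x = solve_l2_growth_qp(
        struct, growth_cols, community_row, cfg.alpha * mu_c - 1e-9
    )
    if x is None:
        raise SolverError(f"cooperative trade-off QP failed: {status}")

    metadata = {
        "alpha": cfg.alpha,
        "stage1_growth": mu_c,
        "solver": "scipy-highs + osqp",
        "feasibility_tol": FEASIBILITY_TOL,
        "parsimony_tiebreak": False,
    }
    sol = _extract_solution(cm, struct, x, "tradeoff", metadata)
    if parsimony:
        pins = {
            m.biomass_reaction: sol.member_growth[m.name] for m in cm.members
        }
        v = _parsimony_pass(struct, pins)
        if v is not None:
            metadata = dict(metadata, parsimony_tiebreak=True)
            sol = _extract_solution(cm, struct, v, "tradeoff", metadata)
    return sol


def exchange_report(sol: FluxSolution, cm: CommunityModel) -> pd.DataFrame:
    """Long-format flux report (reaction, member, flux) as the pipeline's CSV."""
    rows = []
    for rid, flux in sol.fluxes.items():
        member = rid.split("__", 1)[0] if "__" in rid else "medium"
        rows.append((rid, member, flux))
    return pd.DataFrame(rows, columns=["reaction", "member", "flux"])
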