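"""Spatial oxygen layering and oxygen-depletion sweeps.

The spheroid's radial oxygen profile is discretized into three strata
(outer/middle/inner); a spatial configuration assigns each of the three
community members to one stratum and caps that member's per-cell oxygen
uptake at the stratum's bound. All six member-to-stratum bijections are
enumerated (labels A-F, in itertools.permutations order over the member
list) and ranked by cooperative-trade-off community growth — exhaustive
evaluation doubles as its own oracle.

The oxygen sweep instead tightens the community-level oxygen exchange bound
from the normoxic value in fixed decrements down to anoxia, re-optimizing
each scenario independently and recording member exchange fluxes for a
metabolite panel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import (
    CommunityModel,
    FluxSolution,
    TradeoffConfig,
    cooperative_tradeoff,
)

STRATA = ("outer", "middle", "inner")

#: default per-stratum oxygen uptake bounds (mmol·cell⁻¹·h⁻¹); outer is the
#: normoxic 0.16, middle/inner are package defaults and are logged with every
#: result they produce
DEFAULT_STRATUM_OXYGEN = {"outer": 0.16, "middle": 0.08, "inner": 0.01}

DEFAULT_PANEL = ["gln", "lac", "akg", "pyr", "gal", "gly", "ser", "ala"]


@dataclass
class SpatialConfiguration:
    label: str
    assignment: dict[str, str]  # member -> stratum
    oxygen_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_OXYGEN)
    )

    def __post_init__(self) -> None:
        if sorted(self.assignment.values()) != sorted(STRATA):
            raise ValueError("assignment must be a bijection onto the 3 strata")
        levels = [self.oxygen_levels[s] for s in STRATA]
        if any(l < 0 for l in levels):
            raise ValueError("oxygen levels must be non-negative")
        if not (levels[0] >= levels[1] >= levels[2]):
            raise ValueError("oxygen must not increase from outer to inner")


@dataclass
class SweepResult:
    scenarios: list[tuple[float, FluxSolution | None]]
    table: pd.DataFrame  # oxygen_bound, member, metabolite, flux, community_growth
    baseline: FluxSolution | None = None

    def growth_series(self) -> pd.Series:
        return pd.Series(
            {
                b: (s.community_growth if s is not None else np.nan)
                for b, s in self.scenarios
            }
        )


def enumerate_configurations(
    members: list[str],
    oxygen_levels: dict[str, float] | None = None,
) -> list[SpatialConfiguration]:
    """All 3! = 6 member-to-stratum assignments, labeled A-F canonically."""
    if len(members) != 3:
        raise ValueError("the three-stratum layering is defined for 3 members")
    levels = dict(oxygen_levels or DEFAULT_STRATUM_OXYGEN)
    configs = []
    for label, perm in zip(
        "ABCDEF", itertools.permutations(members)
    ):
        assignment = dict(zip(perm, STRATA))
        configs.append(SpatialConfiguration(label, assignment, levels))
    return configs


def evaluate_configuration(
    cm: CommunityModel,
    sc: SpatialConfiguration,
    cfg: TradeoffConfig | None = None,
) -> float:
    """Community growth with each member's oxygen capped by its stratum."""
    unassigned = set(cm.member_names) - set(sc.assignment)
    if unassigned:
        raise ValueError(f"members without a stratum: {sorted(unassigned)}")
    model = cm.model
    o2_ids = {
        name: cm.member_exchange_id(name, "o2") for name in cm.member_names
    }
    with model:
        for name, stratum in sc.assignment.items():
            rid = o2_ids[name]
            if rid not in model.reactions:
                continue  # member without an oxygen route is stratum-blind
            model.reactions.get_by_id(rid).lower_bound = (
                -sc.oxygen_levels[stratum]
            )
        sol = cooperative_tradeoff(cm, cfg, parsimony=False)
    return sol.community_growth


def rank_configurations(
    cm: CommunityModel,
    configs: list[SpatialConfiguration],
    cfg: TradeoffConfig | None = None,
    tie_tol: float = 1e-9,
) -> pd.DataFrame:
    """Exhaustively evaluate and sort configurations by community growth."""
    rows = []
    for sc in configs:
        growth = evaluate_configuration(cm, sc, cfg)
        rows.append(
            {
                "label": sc.label,
                "growth": growth,
                **{f"stratum_{s}": m for m, s in sc.assignment.items()},
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["growth", "label"], ascending=[False, True], ignore_index=True
    )
    df["tied_with_next"] = (
        df["growth"].diff(-1).abs().fillna(np.inf) <= tie_tol
    )
    return df


def oxygen_sweep(
    cm: CommunityModel,
    start: float = 0.16,
    step: float = 0.01,
    panel: list[str] | None = None,
    cfg: TradeoffConfig | None = None,
) -> SweepResult:
    """Tighten the community oxygen uptake from ``start`` down to zero.

    Scenarios sit at start-step, start-2*step, ..., 0 (the start itself is
    the baseline, solved and stored separately); each is optimized
    independently with the cooperative trade-off. Infeasible scenarios are
    recorded with a None solution and the sweep continues.
    """
    if start <= 0 or step <= 0:
        raise ValueError("start and step must be positive")
    panel = list(panel or DEFAULT_PANEL)
    n_steps = int(round(start / step))
    bounds = [max(round(start - k * step, 12), 0.0) for k in range(1, n_steps)]
    bounds.append(0.0)

    o2_ex = cm.model.reactions.get_by_id(cm.community_exchange_id("o2"))

    def solve_at(bound: float) -> FluxSolution | None:
        with cm.model:
            o2_ex.lower_bound = -bound
            try:
                return cooperative_tradeoff(cm, cfg)
            except Exception:
                return None

    baseline = solve_at(start)
    scenarios: list[tuple[float, FluxSolution | None]] = []
    rows = []
    for bound in bounds:
        sol = solve_at(bound)
        scenarios.append((bound, sol))
        for member in cm.member_names:
            for stub in panel:
                rid = cm.member_exchange_id(member, stub)
                flux = (
                    float(sol.fluxes[rid])
                    if sol is not None and rid in sol.fluxes.index
                    else np.nan
                )
                rows.append(
                    {
                        "oxygen_bound": bound,
                        "member": member,
                        "metabolite": stub,
                        "flux": flux,
                        "community_growth": (
                            sol.community_growth if sol else np.nan
                        ),
                        "status": sol.status if sol else "infeasible",
                    }
                )
    return SweepResult(scenarios, pd.DataFrame(rows), baseline)
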