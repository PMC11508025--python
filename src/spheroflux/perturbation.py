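"""Knockout essentiality scans and medium perturbation experiments.

Reaction knockouts close both bounds of one community reaction at a time and
re-optimize; medium essentiality closes one community exchange at a time
under each of three oxygen scenarios (normoxia/mid/hypoxia, reusing the
spatial stratum defaults at the community oxygen exchange); supplementation
opens the uptake of a metabolite absent from the medium.

The essentiality criterion is configurable because "growth reaches zero or
falls below its optimum" admits two readings: the default flags a knockout
as essential when community growth falls below an absolute floor (1e-6);
the alternative flags growth below a fraction of wild type (default 0.01).
With the trade-off parameter alpha = 1 the community growth returned by the
cooperative trade-off equals the stage-1 optimum, so scans re-optimize with
the stage-1 LP in that case; for alpha < 1 the full two-stage solve runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .community import (
    CommunityModel,
    FluxSolution,
    TradeoffConfig,
    community_fba,
    cooperative_tradeoff,
)
from .microenvironment import DEFAULT_STRATUM_OXYGEN
from .model_core import doubling_time

#: community-level oxygen bounds for the three scan scenarios
OXYGEN_SCENARIOS = {
    "normoxia": DEFAULT_STRATUM_OXYGEN["outer"],
    "mid": DEFAULT_STRATUM_OXYGEN["middle"],
    "hypoxia": DEFAULT_STRATUM_OXYGEN["inner"],
}


@dataclass
class KnockoutCriterion:
    mode: str = "absolute"  # "absolute" or "fraction"
    value: float = 1e-6

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "fraction"):
            raise ValueError("mode must be 'absolute' or 'fraction'")
        if self.value <= 0:
            raise ValueError("criterion value must be positive")

    def essential(self, growth: float, wild_type: float) -> bool:
        if self.mode == "absolute":
            return growth < self.value
        return growth < self.value * wild_type


def _community_growth(cm: CommunityModel, cfg: TradeoffConfig) -> float:
    """Community growth under the run's trade-off configuration.

    At alpha = 1 the quadratic stage cannot change community growth, so the
    stage-1 LP value is returned directly.
    """
    try:
        if cfg.alpha >= 1.0:
            return community_fba(cm).community_growth
        return cooperative_tradeoff(cm, cfg, parsimony=False).community_growth
    except Exception:
        return 0.0


def knockout_scan(
    cm: CommunityModel,
    scope: str = "all",
    cfg: TradeoffConfig | None = None,
    criterion: KnockoutCriterion | None = None,
    context: str = "normoxia",
) -> pd.DataFrame:
    """Single-reaction knockout scan over the chosen scope.

    scope: "exchanges" (community exchanges), "internal" (member reactions),
    or "all". Returns a table (knocked_reaction, growth_after_ko, essential)
    with wild-type growth and the criterion recorded in ``attrs``.
    """
    cfg = cfg or TradeoffConfig()
    criterion = criterion or KnockoutCriterion()
    wild_type = _community_growth(cm, cfg)
    if wild_type <= 0:
        raise ValueError("wild-type community growth must be positive")

    community_ex = set(cm.community_exchange_ids())
    if scope == "exchanges":
        targets = sorted(community_ex)
    elif scope == "internal":
        targets = sorted(
            r.id for r in cm.model.reactions
            if "__" in r.id and not r.id.split("__", 1)[1].startswith("EX_")
        )
    elif scope == "all":
        targets = sorted(r.id for r in cm.model.reactions)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    rows = []
    for rid in targets:
        rxn = cm.model.reactions.get_by_id(rid)
        with cm.model:
            rxn.bounds = (0.0, 0.0)
            growth = _community_growth(cm, cfg)
        rows.append(
            {
                "knocked_reaction": rid,
                "growth_after_ko": growth,
                "essential": criterion.essential(growth, wild_type),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs.update(
        wild_type_growth=wild_type, context=context,
        criterion=(criterion.mode, criterion.value), alpha=cfg.alpha,
    )
    return table


def medium_essentiality(
    cm: CommunityModel,
    oxygen_scenarios: dict[str, float] | None = None,
    cfg: TradeoffConfig | None = None,
    criterion: KnockoutCriterion | None = None,
) -> pd.DataFrame:
    """Close each medium metabolite's community uptake under each oxygen
    scenario and flag the essential ones.
    """
    cfg = cfg or TradeoffConfig()
    criterion = criterion or KnockoutCriterion()
    scenarios = dict(oxygen_scenarios or OXYGEN_SCENARIOS)
    o2_ex = cm.model.reactions.get_by_id(cm.community_exchange_id("o2"))

    medium_stubs = [
        stub for stub in cm.shared_metabolite_stubs()
        if cm.medium.uptake(f"{stub}_e") > 0 and stub != "o2"
    ]
    rows = []
    for scen_name, o2_bound in scenarios.items():
        with cm.model:
            o2_ex.lower_bound = -o2_bound
            wild_type = _community_growth(cm, cfg)
            for stub in medium_stubs:
                ex = cm.model.reactions.get_by_id(cm.community_exchange_id(stub))
                with cm.model:
                    ex.lower_bound = 0.0
                    growth = _community_growth(cm, cfg)
                rows.append(
                    {
                        "metabolite": stub,
                        "scenario": scen_name,
                        "oxygen_bound": o2_bound,
                        "wild_type_growth": wild_type,
                        "growth_after_ko": growth,
                        "essential": criterion.essential(growth, wild_type),
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs.update(criterion=(criterion.mode, criterion.value), alpha=cfg.alpha)
    return table


@dataclass
class SupplementResult:
    metabolite: str
    bound: float
    baseline_growth: float
    growth: float
    solution: FluxSolution

    @property
    def baseline_doubling_time_h(self) -> float:
        return doubling_time(self.baseline_growth)

    @property
    def doubling_time_h(self) -> float:
        return doubling_time(self.growth)


def supplement_medium(
    cm: CommunityModel,
    metabolite_stub: str,
    bound: float,
    cfg: TradeoffConfig | None = None,
) -> SupplementResult:
    """Open the community uptake of a metabolite to ``bound`` and re-optimize.

    As a pure relaxation of the uptake constraint, growth can only rise or
    stay put relative to baseline.
    """
    if bound <= 0:
        raise ValueError("supplementation bound must be positive")
    ex_id = cm.community_exchange_id(metabolite_stub)
    if ex_id not in cm.model.reactions:
        raise KeyError(
            f"{metabolite_stub!r} has no community exchange in the shared medium"
        )
    cfg = cfg or TradeoffConfig()
    baseline = cooperative_tradeoff(cm, cfg, parsimony=False).community_growth
    with cm.model:
        cm.model.reactions.get_by_id(ex_id).lower_bound = -bound
        sol = cooperative_tradeoff(cm, cfg)
    return SupplementResult(metabolite_stub, bound, baseline,
                            sol.community_growth, sol)
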