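"""Community assembly, stage-1 LP, cooperative trade-off QP, hand oracles."""

import numpy as np
import pytest

from conftest import DAY6, brute_force_lp_max, unit_member
from spheroflux import (
    TradeoffConfig,
    build_community,
    community_fba,
    cooperative_tradeoff,
    make_medium,
)
from spheroflux._solver import structure_from_cobra
from spheroflux.model_core import MediumDefinition, apply_medium

MEDIUM_S10 = MediumDefinition({"s_e": 10.0})


def test_day6_abundances_accepted(day6_community):
    assert sum(day6_community.abundances.values()) == pytest.approx(1.0)
    assert set(day6_community.member_names) == set(DAY6)


def test_bad_abundances_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        build_community(
            {"A": unit_member(), "B": unit_member()},
            {"A": 0.5, "B": 0.6},
            MEDIUM_S10,
        )
    with pytest.raises(ValueError):
        build_community(
            {"A": unit_member(), "B": unit_member()},
            {"A": 1.5, "B": -0.5},
            MEDIUM_S10,
        )


def test_member_without_biomass_rejected():
    from spheroflux.model_core import MissingBiomassError

    m = unit_member()
    m.objective = {}
    with pytest.raises(MissingBiomassError):
        build_community({"A": m}, {"A": 1.0}, MEDIUM_S10)


def test_symmetric_members_hand_lp_and_qp(symmetric_pair_community):
    """Two unit-yield members sharing uptake <= 10 at a = (1/2, 1/2):
    stage-1 community growth is 10, and the L2 trade-off splits it equally
    (hand QP: min mu1^2 + mu2^2 s.t. (mu1 + mu2)/2 = 10)."""
    cm = symmetric_pair_community
    s1 = community_fba(cm)
    assert s1.community_growth == pytest.approx(10.0, abs=1e-6)
    st = cooperative_tradeoff(cm, TradeoffConfig(1.0))
    assert st.member_growth["A"] == pytest.approx(10.0, abs=1e-5)
    assert st.member_growth["B"] == pytest.approx(10.0, abs=1e-5)


def test_asymmetric_capacity_hand_qp():
    """Member A capped at growth 4: the trade-off pushes A to its cap and
    B makes up the community optimum (hand QP: mu_A = 4, mu_B = 16)."""
    cm = build_community(
        {"A": unit_member(cap=4.0), "B": unit_member()},
        {"A": 0.5, "B": 0.5},
        MEDIUM_S10,
    )
    sol = cooperative_tradeoff(cm, TradeoffConfig(1.0))
    assert sol.member_growth["A"] == pytest.approx(4.0, abs=1e-5)
    assert sol.member_growth["B"] == pytest.approx(16.0, abs=1e-5)
    assert sol.community_growth == pytest.approx(10.0, abs=1e-6)


def test_alpha_zero_minimizes_norm(symmetric_pair_community):
    sol = cooperative_tradeoff(symmetric_pair_community, TradeoffConfig(0.0))
    # the growth constraint is vacuous; min sum mu^2 with floors 0 gives 0
    assert all(abs(mu) < 1e-5 for mu in sol.member_growth.values())
    assert sol.community_growth >= -1e-9


def test_alpha_validation():
    with pytest.raises(ValueError):
        TradeoffConfig(1.2)
    with pytest.raises(ValueError):
        TradeoffConfig(-0.1)


def test_single_member_reduces_to_plain_fba(toy_model, l15):
    """a = 1 community equals an independent FBA solve (cobra/GLPK)."""
    cm = build_community({"only": toy_model}, {"only": 1.0}, l15)
    mine = community_fba(cm).community_growth
    reference = toy_model.copy()
    apply_medium(reference, l15)
    assert mine == pytest.approx(reference.slim_optimize(), abs=1e-6)


def test_identical_members_get_symmetric_growth():
    cm = build_community(
        {"A": unit_member(), "B": unit_member()}, {"A": 0.5, "B": 0.5},
        MEDIUM_S10,
    )
    sol = cooperative_tradeoff(cm)
    assert sol.member_growth["A"] == pytest.approx(
        sol.member_growth["B"], abs=1e-6
    )


def test_stage1_matches_vertex_enumeration_oracle(symmetric_pair_community):
    """On a <= 8-reaction community the LP optimum equals exhaustive vertex
    enumeration of the polytope."""
    cm = symmetric_pair_community
    struct = structure_from_cobra(cm.model)
    assert struct.n_reactions <= 8
    c = np.zeros(struct.n_reactions)
    for m in cm.members:
        c[struct.column(m.biomass_reaction)] = m.abundance
    oracle = brute_force_lp_max(
        struct.S.toarray(), struct.lb, struct.ub, c
    )
    assert community_fba(cm).community_growth == pytest.approx(
        oracle, abs=1e-6
    )


def test_solution_invariants_on_toy_community(day6_community):
    """Mass balance, growth identity, and medium conservation on a real
    three-member solve, for both optimization stages."""
    cm = day6_community
    struct = structure_from_cobra(cm.model)
    for sol in (community_fba(cm), cooperative_tradeoff(cm)):
        v = sol.fluxes.reindex(struct.reaction_ids).to_numpy()
        assert np.abs(struct.S @ v).max() < 1e-6  # S v = 0
        assert sol.community_growth == pytest.approx(
            sum(cm.abundances[n] * g for n, g in sol.member_growth.items()),
            abs=1e-6,
        )
        for stub in cm.shared_metabolite_stubs():
            weighted = sum(
                cm.abundances[m.name]
                * sol.fluxes[cm.member_exchange_id(m.name, stub)]
                for m in cm.members
            )
            assert weighted == pytest.approx(
                sol.fluxes[cm.community_exchange_id(stub)], abs=1e-6
            ), stub


def test_tradeoff_alpha1_attains_stage1(day6_community):
    s1 = community_fba(day6_community)
    st = cooperative_tradeoff(day6_community, TradeoffConfig(1.0))
    assert st.community_growth == pytest.approx(
        s1.community_growth, abs=1e-6
    )


def test_tradeoff_growth_vector_unique(day6_community):
    """Strict convexity in the member growths: re-solving agrees to 1e-6."""
    a = cooperative_tradeoff(day6_community, TradeoffConfig(1.0))
    b = cooperative_tradeoff(day6_community, TradeoffConfig(1.0))
    for name in day6_community.member_names:
        assert a.member_growth[name] == pytest.approx(
            b.member_growth[name], abs=1e-6
        )


def test_uptake_tightening_never_increases_growth(variants, l15):
    """LP monotonicity: shrinking the galactose uptake bound can only
    shrink community growth."""
    growths = []
    for gal in (0.05, 0.03, 0.02, 0.01, 0.0):
        medium = make_medium("l15_like", {"gal_e": gal})
        cm = build_community(variants, DAY6, medium)
        growths.append(community_fba(cm).community_growth)
    diffs = np.diff(growths)
    assert (diffs <= 1e-9).all(), growths


def test_min_growth_floor_enforced():
    cm = build_community(
        {"A": unit_member(cap=4.0), "B": unit_member()},
        {"A": 0.5, "B": 0.5},
        MEDIUM_S10,
        min_growth={"A": 2.0},
    )
    sol = cooperative_tradeoff(cm, TradeoffConfig(0.0))
    assert sol.member_growth["A"] >= 2.0 - 1e-6


def test_infeasible_floor_reports_constraint_class():
    from spheroflux._solver import SolverError

    cm = build_community(
        {"A": unit_member(), "B": unit_member()},
        {"A": 0.5, "B": 0.5},
        MEDIUM_S10,
        min_growth={"B": 25.0},  # unreachable under the shared uptake limit
    )
    with pytest.raises(SolverError, match="min-growth"):
        community_fba(cm)
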