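"""Exchange classification, cross-feeding edges, pathway directionality."""

import numpy as np
import pandas as pd
import pytest

from spheroflux import (
    build_community,
    classify_exchanges,
    cooperative_tradeoff,
    crossfeeding_edges,
    exchange_boolean_matrix,
    make_obligate_pair,
    pathway_activity,
)
from spheroflux.community import FluxSolution
from spheroflux.crossfeeding import categorize_exchange_dynamics, edges_table


@pytest.fixture()
def obligate_community():
    members, medium = make_obligate_pair()
    return build_community(members, {"producer": 0.5, "consumer": 0.5}, medium)


def _zero_solution(cm):
    fluxes = pd.Series(0.0, index=[r.id for r in cm.model.reactions])
    return FluxSolution(fluxes, {m.name: 0.0 for m in cm.members}, 0.0,
                        "stage1", "optimal")


def test_obligate_pair_classified_and_edged(obligate_community):
    cm = obligate_community
    sol = cooperative_tradeoff(cm)
    table = classify_exchanges(sol, cm)
    idx = table.set_index(["member", "metabolite"])["state"]
    assert idx[("producer", "x")] == "secreted"
    assert idx[("consumer", "x")] == "consumed"
    edges = crossfeeding_edges(sol, cm)
    assert len(edges) == 1
    e = edges[0]
    assert (e.metabolite, e.producer, e.consumer) == ("x", "producer", "consumer")
    assert e.producer_flux > 0 > e.consumer_flux
    assert not e.in_medium  # x is absent from the initial medium


def test_edges_match_brute_force_scan(day6_community):
    """Edge detection equals an independent scan over every
    (producer, consumer, metabolite) triple."""
    cm = day6_community
    sol = cooperative_tradeoff(cm)
    edges = {
        (e.metabolite, e.producer, e.consumer)
        for e in crossfeeding_edges(sol, cm)
    }
    tol = 1e-6
    expected = set()
    for stub in cm.shared_metabolite_stubs():
        for p in cm.member_names:
            for c in cm.member_names:
                if p == c:
                    continue
                fp = sol.fluxes.get(cm.member_exchange_id(p, stub), 0.0)
                fc = sol.fluxes.get(cm.member_exchange_id(c, stub), 0.0)
                if fp > tol and fc < -tol:
                    expected.add((stub, p, c))
    assert edges == expected
    assert len(edges) > 0


def test_day6_reverse_warburg_signature(day6_community):
    """The designed community reproduces the headline pattern: the
    proliferative member secretes lactate that the invasive member consumes
    (an edge for a metabolite absent from the medium), and the consumer runs
    LDH against its forward direction."""
    cm = day6_community
    sol = cooperative_tradeoff(cm)
    edges = crossfeeding_edges(sol, cm)
    lactate = [
        e for e in edges
        if e.metabolite == "lac" and e.producer == "proliferative"
        and e.consumer == "invasive"
    ]
    assert lactate and not lactate[0].in_medium
    activity = pathway_activity(sol, cm)
    per_rxn = activity.attrs["per_reaction"]
    ldh = per_rxn.set_index(["member", "reaction"]).loc[("invasive", "LDH")]
    assert bool(ldh["reversed"])
    glyc = activity.set_index(["member", "subsystem"]).loc[
        ("invasive", "Glycolysis")
    ]
    assert glyc["reversed_count"] >= 1
    assert (
        glyc["forward_count"] + glyc["reversed_count"]
        == glyc["active_reaction_count"]
    )


def test_edges_respect_medium_mass_balance(day6_community):
    cm = day6_community
    sol = cooperative_tradeoff(cm)
    for e in crossfeeding_edges(sol, cm):
        weighted = sum(
            cm.abundances[m.name]
            * sol.fluxes[cm.member_exchange_id(m.name, e.metabolite)]
            for m in cm.members
        )
        assert weighted == pytest.approx(
            sol.fluxes[cm.community_exchange_id(e.metabolite)], abs=1e-6
        )


def test_zero_fluxes_are_inactive_and_edgeless(day6_community):
    cm = day6_community
    sol = _zero_solution(cm)
    table = classify_exchanges(sol, cm)
    assert (table["state"] == "inactive").all()
    assert crossfeeding_edges(sol, cm) == []
    activity = pathway_activity(sol, cm)
    assert (activity["active_reaction_count"] == 0).all()


def test_single_member_has_no_edges(toy_model, l15):
    cm = build_community({"only": toy_model}, {"only": 1.0}, l15)
    sol = cooperative_tradeoff(cm)
    assert crossfeeding_edges(sol, cm) == []


def test_metabolite_consumed_by_all_yields_no_edge(day6_community):
    cm = day6_community
    sol = cooperative_tradeoff(cm)
    gal_edges = [e for e in crossfeeding_edges(sol, cm)
                 if e.metabolite == "gal"]
    assert gal_edges == []  # galactose only flows medium -> members


def test_irreversible_reactions_never_reversed(day6_community):
    cm = day6_community
    sol = cooperative_tradeoff(cm)
    per_rxn = pathway_activity(sol, cm).attrs["per_reaction"]
    for _, row in per_rxn[per_rxn["reversed"]].iterrows():
        rxn = cm.model.reactions.get_by_id(f"{row['member']}__{row['reaction']}")
        assert rxn.lower_bound < 0  # only reversible reactions can reverse


def test_top_n_truncates_per_member(day6_community):
    cm = day6_community
    sol = cooperative_tradeoff(cm)
    table = classify_exchanges(sol, cm, top_n=5)
    assert (table.groupby("member").size() <= 5).all()
    full = classify_exchanges(sol, cm)
    assert len(full) > len(table)


def test_boolean_matrix_detects_switching(day6_community):
    """Reservoir lactate handling flips between normoxia and anoxia, so the
    two-condition Boolean matrix must report it as switching."""
    cm = day6_community
    o2 = cm.model.reactions.get_by_id(cm.community_exchange_id("o2"))
    with cm.model:
        o2.lower_bound = -0.16
        normoxia = cooperative_tradeoff(cm)
    with cm.model:
        o2.lower_bound = 0.0
        anoxia = cooperative_tradeoff(cm)
    matrix = exchange_boolean_matrix(
        {"normoxia": normoxia, "anoxia": anoxia}, cm
    )
    cats = categorize_exchange_dynamics(matrix)
    assert cats[("reservoir", "lac")] == "switching"
    assert cats[("proliferative", "gal")] == "always_consumed"
    assert cats[("proliferative", "lac")] == "always_secreted"
    # single condition: no switching class possible
    single = categorize_exchange_dynamics(
        exchange_boolean_matrix({"normoxia": normoxia}, cm)
    )
    assert not (single == "switching").any()


def test_boolean_matrix_requires_consistent_members(
    day6_community, obligate_community
):
    sol = cooperative_tradeoff(obligate_community)
    with pytest.raises(ValueError):
        exchange_boolean_matrix({"cond": sol}, day6_community)


def test_edges_table_columns(obligate_community):
    sol = cooperative_tradeoff(obligate_community)
    df = edges_table(crossfeeding_edges(sol, obligate_community))
    assert list(df.columns) == [
        "metabolite", "producer", "consumer",
        "producer_flux", "consumer_flux", "in_medium",
    ]
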