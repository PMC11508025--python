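"""Cost-penalized context extraction: dependencies, route choice, recovery."""

import cobra
import pytest

from spheroflux import ExtractionConfig, extract_context_model, make_medium
from spheroflux.context_extraction import ExtractionError
from spheroflux.expression_confidence import confidence_for_cluster
from spheroflux.model_core import MediumDefinition, apply_medium


def _chain_model(parallel=False):
    """A_e -> A_c -> B_c -> C_c -> biomass, optionally with a bypass A->C."""
    m = cobra.Model("chain")
    mets = {
        mid: cobra.Metabolite(mid, compartment=("e" if mid.endswith("_e") else "c"))
        for mid in ["A_e", "A_c", "B_c", "C_c"]
    }
    m.add_metabolites(list(mets.values()))

    def add(rid, stoich, lb=0, ub=1000):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        m.add_reactions([r])

    add("EX_A_e", {"A_e": -1}, lb=-1000)
    add("At", {"A_e": -1, "A_c": 1})
    add("R1", {"A_c": -1, "B_c": 1})
    add("R2", {"B_c": -1, "C_c": 1})
    if parallel:
        add("BYPASS", {"A_c": -1, "C_c": 1})
    add("BIOMASS", {"C_c": -1})
    m.objective = "BIOMASS"
    return m


MEDIUM_A = MediumDefinition({"A_e": 10.0})


def test_chain_dependency_retains_low_confidence_middle():
    m = _chain_model()
    conf = {"EX_A_e": 3, "At": 3, "R1": 3, "R2": 1, "BIOMASS": 3}
    sub, log = extract_context_model(m, conf, ExtractionConfig(seed=0), MEDIUM_A)
    ids = {r.id for r in sub.reactions}
    assert "R2" in ids  # the only route to biomass, kept despite confidence 1
    assert log.set_index("reaction").loc["R2", "decision"] == "included"


def test_parallel_routes_prefer_cheaper_confidence():
    m = _chain_model(parallel=True)
    conf = {"EX_A_e": 3, "At": 3, "R1": 2, "R2": 2, "BYPASS": 1, "BIOMASS": 3}
    sub, _ = extract_context_model(m, conf, ExtractionConfig(seed=0), MEDIUM_A)
    ids = {r.id for r in sub.reactions}
    assert {"R1", "R2"} <= ids  # confidence-2 route retained
    assert "BYPASS" not in ids  # confidence-1 alternative dropped


def test_monotonicity_raising_confidence_keeps_reaction():
    """Promoting the dropped route to confidence 3 makes it a target that
    must be included; nothing else disappears."""
    m = _chain_model(parallel=True)
    conf_lo = {"EX_A_e": 3, "At": 3, "R1": 2, "R2": 2, "BYPASS": 1, "BIOMASS": 3}
    sub_lo, _ = extract_context_model(
        m, conf_lo, ExtractionConfig(seed=0), MEDIUM_A
    )
    assert "BYPASS" not in {r.id for r in sub_lo.reactions}
    conf_hi = dict(conf_lo, BYPASS=3)
    sub_hi, _ = extract_context_model(
        m, conf_hi, ExtractionConfig(seed=0), MEDIUM_A
    )
    assert "BYPASS" in {r.id for r in sub_hi.reactions}
    # raising an already-included reaction never evicts it
    conf_r1 = dict(conf_lo, R1=3)
    sub_r1, _ = extract_context_model(
        m, conf_r1, ExtractionConfig(seed=0), MEDIUM_A
    )
    assert "R1" in {r.id for r in sub_r1.reactions}


def test_all_confidence_three_keeps_flux_consistent_subset(toy_model, l15):
    conf = {r.id: 3 for r in toy_model.reactions}
    sub, _ = extract_context_model(
        toy_model, conf, ExtractionConfig(seed=0), l15
    )
    ids = {r.id for r in sub.reactions}
    # the only inconsistent reaction is the transporterless choline exchange
    assert ids == {r.id for r in toy_model.reactions} - {"EX_chol_e"}


def test_extraction_deterministic_per_seed(toy_model, expression, l15):
    matrix, labels = expression
    _, conf, _ = confidence_for_cluster(toy_model, matrix, labels, "invasive", l15)
    a, _ = extract_context_model(toy_model, conf, ExtractionConfig(seed=5), l15)
    b, _ = extract_context_model(toy_model, conf, ExtractionConfig(seed=5), l15)
    assert {r.id for r in a.reactions} == {r.id for r in b.reactions}


def test_missing_confidence_rejected(toy_model, l15):
    with pytest.raises(ValueError, match="without confidence"):
        extract_context_model(toy_model, {}, ExtractionConfig(seed=0), l15)


def test_infeasible_biomass_reports_blocking_precursor():
    m = _chain_model()
    conf = {r.id: 3 for r in m.reactions}
    with pytest.raises(ExtractionError, match="C_c"):
        extract_context_model(
            m, conf, ExtractionConfig(seed=0), MediumDefinition({})
        )


def test_invalid_extraction_config():
    with pytest.raises(ValueError):
        ExtractionConfig(penalty_low=1.0, penalty_mid=2.0)
    with pytest.raises(ValueError):
        ExtractionConfig(flux_threshold=0.0)


def test_marker_capability_recovery(toy_model, expression, l15):
    """The invasive cluster's extracted model can consume lactate; the
    proliferative cluster's can secrete it (ground truth of the designed
    phenotypes, recovered from expression alone)."""
    matrix, labels = expression

    def extracted(cluster):
        _, conf, _ = confidence_for_cluster(
            toy_model, matrix, labels, cluster, l15
        )
        sub, _ = extract_context_model(
            toy_model, conf, ExtractionConfig(seed=0), l15
        )
        return sub

    invasive = extracted("invasive")
    assert {"LDH", "LACt", "EX_lac_e"} <= {r.id for r in invasive.reactions}
    with_lactate = make_medium("l15_like", {"lac_e": 0.05})
    m = invasive.copy()
    apply_medium(m, with_lactate)
    m.objective = "EX_lac_e"
    m.objective_direction = "min"
    assert m.slim_optimize(error_value=0.0) < -1e-3  # uptake capability

    proliferative = extracted("proliferative")
    assert {"LDH", "LACt", "EX_lac_e"} <= {
        r.id for r in proliferative.reactions
    }
    p = proliferative.copy()
    apply_medium(p, l15)
    p.objective = "EX_lac_e"
    assert p.slim_optimize(error_value=0.0) > 1e-3  # secretion capability
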