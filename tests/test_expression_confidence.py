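"""Gene confidence tiers, differential expression, GPR propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spheroflux import make_medium
from spheroflux.expression_confidence import (
    DegenerateExpressionError,
    apply_de_overrides,
    cluster_gene_confidence,
    confidence_for_cluster,
    differential_expression,
    reaction_confidence,
)
from spheroflux.synthetic_data import MARKER_GENES


def _matrix_three_tiers(n_cells=10, seed=0):
    """30 genes at well-separated mean counts 0 / 10 / 100, one cluster."""
    rng = np.random.default_rng(seed)
    means = np.repeat([0.0, 10.0, 100.0], 10)
    counts = rng.poisson(means, size=(n_cells, 30))
    genes = [f"g{i:02d}" for i in range(30)]
    cells = [f"c{i}" for i in range(n_cells)]
    matrix = pd.DataFrame(counts, index=cells, columns=genes)
    labels = pd.Series(["target"] * n_cells, index=cells)
    return matrix, labels


def test_three_tier_genes_get_confidence_1_2_3():
    matrix, labels = _matrix_three_tiers()
    conf = cluster_gene_confidence(matrix, labels, "target")
    got = pd.Series(conf)
    assert (got[[f"g{i:02d}" for i in range(10)]] == 1).all()
    assert (got[[f"g{i:02d}" for i in range(10, 20)]] == 2).all()
    assert (got[[f"g{i:02d}" for i in range(20, 30)]] == 3).all()


def test_constant_matrix_falls_back_to_all_mid():
    matrix, labels = _matrix_three_tiers()
    matrix.loc[:, :] = 5
    conf = cluster_gene_confidence(matrix, labels, "target")
    assert set(conf.values()) == {2}


def test_two_distinct_profiles_is_degenerate():
    matrix, labels = _matrix_three_tiers()
    matrix.loc[:, :] = 0
    matrix.iloc[:, 0] = 50
    with pytest.raises(DegenerateExpressionError):
        cluster_gene_confidence(matrix, labels, "target")


def test_gene_order_permutation_invariance():
    matrix, labels = _matrix_three_tiers(seed=4)
    conf = cluster_gene_confidence(matrix, labels, "target")
    shuffled = matrix.sample(frac=1.0, axis=1, random_state=1)
    conf2 = cluster_gene_confidence(shuffled, labels, "target")
    assert conf == conf2


def test_tiny_cluster_rejected():
    matrix, labels = _matrix_three_tiers(n_cells=1)
    with pytest.raises(ValueError):
        cluster_gene_confidence(matrix, labels, "target")


def _two_cluster_matrix():
    rng = np.random.default_rng(11)
    n = 20
    genes = ["marker", "flat", "silent"]
    a = pd.DataFrame(
        {
            "marker": rng.poisson(40, n),
            "flat": rng.poisson(10, n),
            "silent": 0,
        },
        index=[f"a{i}" for i in range(n)],
    )
    b = pd.DataFrame(
        {
            "marker": rng.poisson(10, n),
            "flat": rng.poisson(10, n),
            "silent": 0,
        },
        index=[f"b{i}" for i in range(n)],
    )
    matrix = pd.concat([a, b])
    labels = pd.Series(["A"] * n + ["B"] * n, index=matrix.index)
    return matrix, labels


def test_differential_expression_calls():
    matrix, labels = _two_cluster_matrix()
    de = differential_expression(matrix, labels, "A")
    t = de.table
    assert t.loc["marker", "fold_change"] >= 2.0
    assert t.loc["marker", "p_value"] <= 0.05
    assert t.loc["marker", "direction"] == "up"
    assert t.loc["flat", "fold_change"] == pytest.approx(1.0, abs=0.3)
    assert t.loc["flat", "p_value"] > 0.05
    # all-zero gene: pseudocount fold change of exactly 1, flagged
    assert t.loc["silent", "fold_change"] == pytest.approx(1.0)
    assert bool(t.loc["silent", "all_zero"])


def test_differential_expression_needs_cells_on_both_sides():
    matrix, labels = _two_cluster_matrix()
    labels[:] = "A"
    with pytest.raises(ValueError):
        differential_expression(matrix, labels, "A")


def test_de_overrides_rules_and_idempotence():
    matrix, labels = _two_cluster_matrix()
    de = differential_expression(matrix, labels, "A")
    base_conf = {"marker": 2, "flat": 2, "silent": 2}
    out = apply_de_overrides(base_conf, de)
    assert out["marker"] == 3  # significant up -> forced high
    assert out["flat"] == 2  # unchanged
    assert apply_de_overrides(out, de) == out  # idempotent
    de_b = differential_expression(matrix, labels, "B")
    out_b = apply_de_overrides(base_conf, de_b)
    assert out_b["marker"] == 1  # significant down in the other cluster


def test_reaction_confidence_gpr_and_forcing(toy_model, l15):
    gene_conf = {g.id: 2 for g in toy_model.genes}
    gene_conf.update({"LDHA": 3, "LDHB": 1, "GAPDH": 3, "PKM": 1})
    conf = reaction_confidence(toy_model, gene_conf, l15)
    assert conf["LDH"] == 3  # "LDHA or LDHB" -> max
    assert conf["GLYCL"] == 1  # "GAPDH and PKM" -> min
    assert conf["O2t"] == 2  # empty GPR -> medium confidence
    assert conf["EX_gal_e"] == 3  # medium exchange forced high
    assert conf["EX_lac_e"] == 2  # lactate absent from the medium: not forced
    assert conf["BIOMASS"] == 3


def test_reaction_confidence_unknown_gene_treated_as_mid(toy_model, l15):
    conf = reaction_confidence(toy_model, {}, l15)
    assert conf["LDH"] == 2  # both leaves unknown -> 2


def test_marker_reactions_reach_high_confidence(toy_model, expression, l15):
    """Each phenotype's designed marker reactions score 3 in their cluster."""
    matrix, labels = expression
    marker_reactions = {
        "proliferative": ["GALK", "GLYCL", "LDH", "GALt"],
        "invasive": ["LDH", "LACt", "AKGDH", "SUCD", "OXPHOS", "GLS", "GDH"],
        "reservoir": ["ATPSEC", "FUMt", "SUCCt", "FUMH", "SUCOAS"],
    }
    for cluster, reactions in marker_reactions.items():
        _, rxn_conf, _ = confidence_for_cluster(
            toy_model, matrix, labels, cluster, l15
        )
        for rid in reactions:
            assert rxn_conf[rid] == 3, (cluster, rid, rxn_conf[rid])


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_confidence_values_always_in_range(seed):
    rng = np.random.default_rng(seed)
    n_cells, n_genes = 8, 12
    matrix = pd.DataFrame(
        rng.poisson(rng.uniform(0, 50, n_genes), size=(n_cells, n_genes)),
        index=[f"c{i}" for i in range(n_cells)],
        columns=[f"g{i}" for i in range(n_genes)],
    )
    labels = pd.Series(["t"] * n_cells, index=matrix.index)
    try:
        conf = cluster_gene_confidence(matrix, labels, "t")
    except DegenerateExpressionError:
        return
    assert set(conf.values()) <= {1, 2, 3}
    assert set(conf) == set(matrix.columns)
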