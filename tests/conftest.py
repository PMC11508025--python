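"""Shared fixtures: all inputs are generated programmatically at test time."""

import itertools
import warnings

import cobra
import numpy as np
import pytest

from spheroflux import (
    build_community,
    make_expression_matrix,
    make_medium,
    make_phenotype_variants,
    make_toy_base_model,
)
from spheroflux.model_core import MediumDefinition

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

DAY6 = {"invasive": 0.0977, "reservoir": 0.3910, "proliferative": 0.5113}
DAY19 = {"invasive": 0.5739, "reservoir": 0.2739, "proliferative": 0.1522}


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_base_model()


@pytest.fixture(scope="session")
def l15():
    return make_medium("l15_like")


@pytest.fixture(scope="session")
def variants(toy_model):
    return make_phenotype_variants(toy_model)


@pytest.fixture(scope="session")
def expression(toy_model):
    return make_expression_matrix(toy_model)


@pytest.fixture()
def day6_community(variants, l15):
    return build_community(variants, DAY6, l15)


@pytest.fixture()
def day19_community(variants, l15):
    return build_community(variants, DAY19, l15)


def unit_member(cap: float | None = None, model_id: str = "unit") -> cobra.Model:
    """One-substrate, unit-yield member: EX_s <-> , St, GROW (objective)."""
    m = cobra.Model(model_id)
    s_e = cobra.Metabolite("s_e", compartment="e")
    s_c = cobra.Metabolite("s_c", compartment="c")
    m.add_metabolites([s_e, s_c])
    for rid, stoich, lb, ub in [
        ("EX_s_e", {s_e: -1}, -1000, 1000),
        ("St", {s_e: -1, s_c: 1}, 0, 1000),
        ("GROW", {s_c: -1}, 0, cap if cap is not None else 1000),
    ]:
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(stoich)
        m.add_reactions([r])
    m.objective = "GROW"
    return m


@pytest.fixture()
def symmetric_pair_community():
    medium = MediumDefinition({"s_e": 10.0})
    return build_community(
        {"A": unit_member(), "B": unit_member()}, {"A": 0.5, "B": 0.5}, medium
    )


def brute_force_lp_max(S, lb, ub, c, tol=1e-9):
    """Exhaustive vertex enumeration of {S v = 0, lb <= v <= ub}.

    Independent of the production LP path: enumerates candidate basic
    solutions by fixing (n - rank) variables at bounds and solving the rest.
    Only viable for a handful of reactions.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_fix = n - rank
    best = -np.inf
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.asarray(bounds_choice)
            sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            if np.max(np.abs(S[:, free] @ sol - rhs)) > 1e-7:
                continue
            v = np.empty(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            best = max(best, float(c @ v))
    return best
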