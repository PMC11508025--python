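"""Constraint-based model I/O and structural validation.

Models are carried as :class:`cobra.Model` objects throughout the package:
metabolites, reactions (with bounds in mmol·cell⁻¹·h⁻¹), gene-protein-reaction
rules and subsystem annotations map directly onto cobra's types. This module
wraps reading/writing (SBML Level 3 with the fbc package, and cobra's JSON
dialect), medium definitions, and a structural validation report covering
elemental mass balance, blocked reactions, biomass producibility and orphan
metabolites.

Sign convention: exchange reactions are single-metabolite boundary reactions
"1 M_e <-> (nothing)"; negative flux is uptake into the system, positive flux
is secretion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis

#: Biomass flux below this is treated as "not producible".
BIOMASS_TOL = 1e-9


class ModelFormatError(ValueError):
    """A model file failed to parse under the requested standard."""


class MissingBiomassError(ValueError):
    """The model declares no objective/biomass reaction."""


@dataclass
class MediumDefinition:
    """Growth-medium composition: extracellular metabolite -> maximum uptake.

    Bounds are non-negative maximum uptake rates (mmol·cell⁻¹·h⁻¹); a
    metabolite absent from ``bounds`` cannot be taken up. Secretion is never
    limited by the medium.
    """

    bounds: dict[str, float] = field(default_factory=dict)
    #: overrides that referenced unknown metabolites, kept for reporting
    ignored: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, bound in self.bounds.items():
            if bound < 0:
                raise ValueError(f"negative uptake bound for {met!r}: {bound}")

    def uptake(self, metabolite_id: str) -> float:
        return self.bounds.get(metabolite_id, 0.0)

    def with_overrides(self, overrides: dict[str, float]) -> "MediumDefinition":
        new = dict(self.bounds)
        new.update({k: float(v) for k, v in overrides.items()})
        return MediumDefinition({k: v for k, v in new.items() if v > 0})

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.bounds.items()), columns=["metabolite_id", "max_uptake"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MediumDefinition":
        df = pd.read_csv(path)
        return cls(dict(zip(df["metabolite_id"], df["max_uptake"].astype(float))))


@dataclass
class ValidationReport:
    """Structural health summary of a metabolic model."""

    mass_balanced_fraction: float
    blocked_reaction_count: int
    biomass_producible: bool
    orphan_metabolite_count: int
    blocked_reaction_ids: list[str] = field(default_factory=list)
    formula_free_reaction_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mass_balanced_fraction <= 1.0:
            raise ValueError("mass_balanced_fraction outside [0, 1]")
        if self.blocked_reaction_count < 0 or self.orphan_metabolite_count < 0:
            raise ValueError("counts must be non-negative")


def read_model(path: str | Path, format: str = "sbml") -> cobra.Model:
    """Read a model from SBML (Level 3 / fbc) or cobra JSON.

    Raises :class:`ModelFormatError` on parse failure and
    :class:`MissingBiomassError` when no objective reaction is declared
    (set one via ``model.objective`` after loading, or fix the file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if format == "sbml":
                model = cobra.io.read_sbml_model(str(path))
            elif format == "json":
                model = cobra.io.load_json_model(str(path))
            else:
                raise ValueError(f"unknown format {format!r}")
    except ValueError:
        raise
    except Exception as exc:  # libsbml/cobra raise assorted types
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc
    if not biomass_reaction_id(model, required=False):
        raise MissingBiomassError(
            f"{path} declares no objective reaction; set the biomass reaction "
            "explicitly via model.objective or the run configuration"
        )
    return model


def write_model(model: cobra.Model, path: str | Path, format: str = "sbml") -> None:
    """Write a model to SBML or JSON; round-trips through read_model."""
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if format == "sbml":
            cobra.io.write_sbml_model(model, str(path))
        elif format == "json":
            cobra.io.save_json_model(model, str(path))
        else:
            raise ValueError(f"unknown format {format!r}")


def biomass_reaction_id(model: cobra.Model, required: bool = True) -> str | None:
    """Return the id of the objective (biomass) reaction."""
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = linear_reaction_coefficients(model)
    for rxn in coeffs:
        return rxn.id
    if required:
        raise MissingBiomassError(f"model {model.id!r} has no objective reaction")
    return None


def exchange_reactions(model: cobra.Model) -> list[cobra.Reaction]:
    """Single-metabolite boundary reactions, by the COBRA convention."""
    return [r for r in model.reactions if len(r.metabolites) == 1]


def apply_medium(
    model: cobra.Model, medium: MediumDefinition, open_secretion: float = 1000.0
) -> None:
    """Constrain the model's exchange reactions to a medium, in place.

    Metabolites in the medium get uptake (lower) bound -max_uptake; all other
    exchanged metabolites get uptake 0. Secretion is opened to
    ``open_secretion`` unless the reaction is declared secretion-incapable
    (upper bound already 0).
    """
    for rxn in exchange_reactions(model):
        met = next(iter(rxn.metabolites))
        rxn.lower_bound = -medium.uptake(met.id)
        if rxn.upper_bound > 0:
            rxn.upper_bound = open_secretion


def validate_model(
    model: cobra.Model,
    medium: MediumDefinition | None = None,
    fva_fraction: float = 0.0,
) -> ValidationReport:
    """Structural validation: mass balance, blocked reactions, biomass, orphans.

    Reactions lacking complete elemental formulas (biomass and other
    pseudo-reactions) are excluded from the mass-balance denominator and
    counted separately. Blocked reactions are detected by flux variability
    on the model as given (exchange reactions open as configured, or under
    ``medium`` if one is passed). Degenerate models yield a report rather
    than an exception.
    """
    working = model.copy()
    if medium is not None:
        apply_medium(working, medium)

    boundary = {r.id for r in exchange_reactions(working)}
    objective_id = biomass_reaction_id(working, required=False)
    balanced = 0
    with_formula = 0
    for rxn in working.reactions:
        if rxn.id in boundary or rxn.id == objective_id:
            continue
        mets = list(rxn.metabolites)
        if any(not m.formula for m in mets):
            continue
        with_formula += 1
        if not rxn.check_mass_balance():
            balanced += 1
    formula_free = len(working.reactions) - len(boundary) - with_formula
    frac = balanced / with_formula if with_formula else 1.0

    try:
        max_biomass = working.slim_optimize(error_value=0.0)
    except Exception:
        max_biomass = 0.0
    producible = bool(max_biomass is not None and max_biomass > BIOMASS_TOL)

    blocked: list[str] = []
    try:
        fva = flux_variability_analysis(
            working, fraction_of_optimum=fva_fraction, processes=1
        )
        blocked = [
            rid
            for rid in fva.index
            if abs(fva.loc[rid, "minimum"]) < 1e-9 and abs(fva.loc[rid, "maximum"]) < 1e-9
        ]
    except Exception:
        blocked = []

    orphans = sum(1 for m in working.metabolites if len(m.reactions) == 0)

    return ValidationReport(
        mass_balanced_fraction=frac,
        blocked_reaction_count=len(blocked),
        biomass_producible=producible,
        orphan_metabolite_count=orphans,
        blocked_reaction_ids=blocked,
        formula_free_reaction_count=formula_free,
    )


def doubling_time(mu: float) -> float:
    """Doubling time in hours for an exponential growth rate mu (h⁻¹)."""
    if not mu > 0:
        raise ValueError(f"doubling time undefined for growth rate {mu}")
    return math.log(2.0) / mu
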