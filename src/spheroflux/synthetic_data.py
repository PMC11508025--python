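"""Synthetic inputs: toy metabolic network, phenotype variants, expression
matrices, and growth media.

The toy network is a hand-balanced core-carbon model (~54 reactions) built to
exercise every pipeline stage without external downloads. It covers galactose
entry into glycolysis, a reversible lactate dehydrogenase with lactate
exchange, a TCA segment (alpha-ketoglutarate dehydrogenase, succinate-CoA
ligase, reversible succinate dehydrogenase, fumarase, malate dehydrogenase),
glutaminase/glutamate dehydrogenase anaplerosis, alanine transaminase, a
lumped oxygen-consuming oxidative phosphorylation, amino-acid uptakes and an
ATP-consuming biomass reaction. Every metabolite carries an elemental formula
and charge, and every non-boundary, non-biomass reaction is elementally and
charge balanced, so the structural validator can be exercised honestly.

Energetics (hand-checkable): galactose fermentation to lactate nets 2 ATP per
galactose; full oxidation nets ~27 ATP and consumes 6 O2. Biomass requires
glucose-6-phosphate (so a glycolytic carbon entry is obligatory), glutamate
(so glutamine is obligatory) and three uptaken amino acids. The TCA cycle has
no pyruvate carboxylase, so running it requires glutamine anaplerosis for the
C4 pool, as in the real system the network emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .model_core import MediumDefinition

# ---------------------------------------------------------------------------
# metabolite catalogue: id-stub -> (name, formula, charge)

_CYTOSOLIC = {
    "gal": ("D-galactose", "C6H12O6", 0),
    "g6p": ("D-glucose 6-phosphate", "C6H11O9P", -2),
    "pyr": ("pyruvate", "C3H3O3", -1),
    "lac": ("L-lactate", "C3H5O3", -1),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4),
    "cit": ("citrate", "C6H5O7", -3),
    "akg": ("2-oxoglutarate", "C5H4O5", -2),
    "succoa": ("succinyl-CoA", "C25H35N7O19P3S", -5),
    "succ": ("succinate", "C4H4O4", -2),
    "fum": ("fumarate", "C4H2O4", -2),
    "mal": ("L-malate", "C4H4O5", -2),
    "oaa": ("oxaloacetate", "C4H2O5", -2),
    "glu": ("L-glutamate", "C5H8NO4", -1),
    "gln": ("L-glutamine", "C5H10N2O3", 0),
    "nh4": ("ammonium", "H4N", 1),
    "ala": ("L-alanine", "C3H7NO2", 0),
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "pi": ("phosphate", "HO4P", -2),
    "h": ("proton", "H", 1),
    "h2o": ("water", "H2O", 0),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "o2": ("oxygen", "O2", 0),
    "co2": ("carbon dioxide", "CO2", 0),
}

#: amino acids that can feed biomass, in catalogue order
AMINO_ACID_CATALOGUE = {
    "ser": ("L-serine", "C3H7NO3", 0),
    "gly": ("glycine", "C2H5NO2", 0),
    "his": ("L-histidine", "C6H9N3O2", 0),
    "trp": ("L-tryptophan", "C11H12N2O2", 0),
    "lys": ("L-lysine", "C6H15N2O2", 1),
}

_EXCHANGED = [
    "gal", "lac", "pyr", "akg", "fum", "succ", "gln", "nh4", "ala",
    "o2", "co2", "h2o", "h", "pi",
]

PHENOTYPES = ("invasive", "reservoir", "proliferative")

#: normoxic per-cell oxygen transport bound (mmol·cell⁻¹·h⁻¹)
NORMOXIC_O2_PER_CELL = 0.16

#: marker genes elevated in each phenotype's expression cluster
MARKER_GENES = {
    "proliferative": ["GALK1", "GAPDH", "PKM", "LDHA", "SLC2A1"],
    "invasive": ["LDHB", "SLC16A1", "OGDH", "SDHA", "NDUFS1", "ATP5F1A",
                 "GLS", "GLUD1"],
    "reservoir": ["PANX1", "SLC25A10", "SLC13A3", "FH", "SUCLG1"],
}

DECOY_GENES = [f"DECOY_{i:02d}" for i in range(1, 21)]


class ToyConstructionError(ValueError):
    """The configured toy network cannot produce biomass."""


@dataclass
class ToyNetworkConfig:
    include_reverse_ldh: bool = True
    include_akg_shuttle: bool = True
    n_amino_acids: int = 3
    yields: dict[str, float] = field(
        default_factory=lambda: {"atp": 20.0, "g6p": 0.1, "glu": 0.5}
    )
    #: biomass coefficient for each uptaken amino acid
    amino_acid_yield: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_amino_acids < 3:
            raise ValueError("n_amino_acids must be >= 3")
        if self.n_amino_acids > len(AMINO_ACID_CATALOGUE):
            raise ValueError(
                f"amino-acid catalogue holds {len(AMINO_ACID_CATALOGUE)} entries"
            )
        if any(v <= 0 for v in self.yields.values()) or self.amino_acid_yield <= 0:
            raise ValueError("biomass yields must be strictly positive")


@dataclass
class SyntheticExpressionConfig:
    n_cells_per_cluster: int = 60
    dispersion: float = 2.0
    dropout_rate: float = 0.1
    marker_fold_change: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_cluster < 2:
            raise ValueError("need at least 2 cells per cluster")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.marker_fold_change < 2:
            raise ValueError("marker_fold_change must be >= 2")


def _met(model: cobra.Model, stub: str, compartment: str) -> cobra.Metabolite:
    mid = f"{stub}_{compartment[0]}" if compartment in ("c", "e") else stub
    if mid in model.metabolites:
        return model.metabolites.get_by_id(mid)
    catalogue = {**_CYTOSOLIC, **AMINO_ACID_CATALOGUE}
    name, formula, charge = catalogue.get(stub, (stub, None, None))
    met = cobra.Metabolite(
        mid, name=name, formula=formula, charge=charge, compartment=compartment
    )
    model.add_metabolites([met])
    return met


def _rxn(
    model: cobra.Model,
    rid: str,
    stoich: dict[cobra.Metabolite, float],
    lb: float,
    ub: float,
    gpr: str = "",
    subsystem: str = "",
    name: str = "",
) -> cobra.Reaction:
    rxn = cobra.Reaction(rid, name=name or rid, lower_bound=lb, upper_bound=ub)
    rxn.add_metabolites(stoich)
    rxn.subsystem = subsystem
    model.add_reactions([rxn])
    if gpr:
        rxn.gene_reaction_rule = gpr
    return rxn


def make_toy_base_model(config: ToyNetworkConfig | None = None) -> cobra.Model:
    """Construct the toy base network. Deterministic given the config."""
    cfg = config or ToyNetworkConfig()
    model = cobra.Model("toy_spheroid_base")

    def c(stub):
        return _met(model, stub, "c")

    def e(stub):
        return _met(model, stub, "e")

    aa_ids = list(AMINO_ACID_CATALOGUE)[: cfg.n_amino_acids]

    # --- exchanges (negative flux = uptake) and passive transports
    exchanged = list(_EXCHANGED) + aa_ids
    if not cfg.include_akg_shuttle:
        exchanged.remove("akg")
    for stub in exchanged:
        _rxn(model, f"EX_{stub}_e", {e(stub): -1}, -1000, 1000,
             subsystem="Exchange", name=f"{stub} exchange")
    # choline: present in the medium but transported by nobody (vitamin-like)
    chol_e = cobra.Metabolite("chol_e", name="choline", formula="C5H14NO",
                              charge=1, compartment="e")
    model.add_metabolites([chol_e])
    _rxn(model, "EX_chol_e", {chol_e: -1}, -1000, 1000, subsystem="Exchange")

    # transports: written X_e <-> X_c, positive flux = import into the cell
    transport_gpr = {
        "gal": "SLC2A1", "lac": "SLC16A1", "pyr": "SLC16A7", "gln": "SLC1A5",
        "akg": "SLC25A11", "fum": "SLC25A10", "succ": "SLC13A3",
        "ala": "SLC38A2", "ser": "SLC1A4", "gly": "SLC6A9", "his": "SLC7A8",
    }
    import_only = {"gal", "gln", "o2"} | set(aa_ids)
    export_only = {"co2"}
    for stub in exchanged:
        lb, ub = -1000, 1000
        if stub in import_only:
            lb = 0
        if stub in export_only:
            lb = 0
        if stub == "o2":
            ub = NORMOXIC_O2_PER_CELL  # per-cell oxygen transport cap
        stoich = {e(stub): -1.0, c(stub): 1.0}
        if stub in export_only:
            stoich = {c(stub): -1.0, e(stub): 1.0}
        _rxn(model, f"{stub.upper()}t", stoich, lb, ub,
             gpr=transport_gpr.get(stub, ""), subsystem="Transport",
             name=f"{stub} transport")

    # --- glycolysis / galactose entry / gluconeogenesis
    _rxn(model, "GALK",
         {c("gal"): -1, c("atp"): -1, c("g6p"): 1, c("adp"): 1, c("h"): 1},
         0, 1000, gpr="GALK1", subsystem="Galactose metabolism",
         name="galactose entry (Leloir, lumped)")
    _rxn(model, "GLYCL",
         {c("g6p"): -1, c("adp"): -3, c("pi"): -2, c("nad"): -2,
          c("pyr"): 2, c("atp"): 3, c("nadh"): 2, c("h"): 1, c("h2o"): 2},
         0, 1000, gpr="GAPDH and PKM", subsystem="Glycolysis",
         name="glycolysis, lumped (g6p -> 2 pyruvate)")
    _rxn(model, "GNG",
         {c("pyr"): -2, c("atp"): -4, c("nadh"): -2, c("h2o"): -3,
          c("g6p"): 1, c("adp"): 4, c("pi"): 3, c("nad"): 2},
         0, 1000, gpr="PCK1 and FBP1", subsystem="Glycolysis",
         name="gluconeogenesis, lumped (2 pyruvate -> g6p)")
    ldh_lb = -1000 if cfg.include_reverse_ldh else 0
    _rxn(model, "LDH",
         {c("pyr"): -1, c("nadh"): -1, c("h"): -1, c("lac"): 1, c("nad"): 1},
         ldh_lb, 1000, gpr="LDHA or LDHB", subsystem="Glycolysis",
         name="lactate dehydrogenase")

    # --- pyruvate oxidation and TCA segment
    _rxn(model, "PDH",
         {c("pyr"): -1, c("coa"): -1, c("nad"): -1,
          c("accoa"): 1, c("nadh"): 1, c("co2"): 1},
         0, 1000, gpr="PDHA1", subsystem="TCA cycle",
         name="pyruvate dehydrogenase")
    _rxn(model, "CS",
         {c("accoa"): -1, c("oaa"): -1, c("h2o"): -1,
          c("cit"): 1, c("coa"): 1, c("h"): 1},
         0, 1000, gpr="CS", subsystem="TCA cycle", name="citrate synthase")
    _rxn(model, "ICDH",
         {c("cit"): -1, c("nad"): -1, c("akg"): 1, c("nadh"): 1, c("co2"): 1},
         0, 1000, gpr="IDH3A", subsystem="TCA cycle",
         name="isocitrate dehydrogenase (lumped from citrate)")
    _rxn(model, "AKGDH",
         {c("akg"): -1, c("coa"): -1, c("nad"): -1,
          c("succoa"): 1, c("nadh"): 1, c("co2"): 1},
         0, 1000, gpr="OGDH", subsystem="TCA cycle",
         name="alpha-ketoglutarate dehydrogenase")
    _rxn(model, "SUCOAS",
         {c("succoa"): -1, c("adp"): -1, c("pi"): -1,
          c("succ"): 1, c("coa"): 1, c("atp"): 1},
         0, 1000, gpr="SUCLG1", subsystem="TCA cycle",
         name="succinate-CoA ligase")
    _rxn(model, "SUCD",
         {c("succ"): -1, c("nad"): -1, c("fum"): 1, c("nadh"): 1, c("h"): 1},
         -1000, 1000, gpr="SDHA", subsystem="TCA cycle",
         name="succinate dehydrogenase (reversible)")
    _rxn(model, "FUMH",
         {c("fum"): -1, c("h2o"): -1, c("mal"): 1},
         -1000, 1000, gpr="FH", subsystem="TCA cycle", name="fumarase")
    _rxn(model, "MDH",
         {c("mal"): -1, c("nad"): -1, c("oaa"): 1, c("nadh"): 1, c("h"): 1},
         -1000, 1000, gpr="MDH2", subsystem="TCA cycle",
         name="malate dehydrogenase")

    # --- glutamine anaplerosis and transamination
    _rxn(model, "GLS",
         {c("gln"): -1, c("h2o"): -1, c("glu"): 1, c("nh4"): 1},
         0, 1000, gpr="GLS", subsystem="Glutamate metabolism",
         name="glutaminase")
    _rxn(model, "GDH",
         {c("glu"): -1, c("h2o"): -1, c("nad"): -1,
          c("akg"): 1, c("nh4"): 1, c("nadh"): 1, c("h"): 1},
         0, 1000, gpr="GLUD1", subsystem="Glutamate metabolism",
         name="glutamate dehydrogenase (oxidative deamination)")
    _rxn(model, "ALT",
         {c("pyr"): -1, c("glu"): -1, c("ala"): 1, c("akg"): 1},
         -1000, 1000, gpr="GPT", subsystem="Glutamate metabolism",
         name="alanine transaminase (reversible)")

    # --- respiration (P/O ~ 2, lumped respiratory chain + ATP synthase)
    _rxn(model, "OXPHOS",
         {c("nadh"): -1, c("o2"): -0.5, c("h"): -3, c("adp"): -2, c("pi"): -2,
          c("nad"): 1, c("atp"): 2, c("h2o"): 3},
         0, 1000, gpr="NDUFS1 and ATP5F1A",
         subsystem="Oxidative phosphorylation",
         name="oxidative phosphorylation, lumped")

    # --- reservoir-style ATP provisioning to the medium (hydrolysis-coupled)
    atpsig_e = cobra.Metabolite("atpsig_e", name="extracellular ATP equivalent",
                                compartment="e")
    model.add_metabolites([atpsig_e])
    _rxn(model, "ATPSEC",
         {c("atp"): -1, c("h2o"): -1, c("adp"): 1, c("pi"): 1, c("h"): 1,
          atpsig_e: 1},
         0, 1000, gpr="PANX1", subsystem="Transport",
         name="ATP secretion (hydrolysis-coupled export)")
    _rxn(model, "EX_atpsig_e", {atpsig_e: -1}, 0, 1000, subsystem="Exchange")

    # --- biomass: ATP hydrolysis plus carbon/nitrogen precursors
    stoich = {
        c("atp"): -cfg.yields["atp"],
        c("h2o"): -cfg.yields["atp"],
        c("adp"): cfg.yields["atp"],
        c("pi"): cfg.yields["atp"],
        c("h"): cfg.yields["atp"],
        c("g6p"): -cfg.yields["g6p"],
        c("glu"): -cfg.yields["glu"],
    }
    for stub in aa_ids:
        stoich[c(stub)] = -cfg.amino_acid_yield
    _rxn(model, "BIOMASS", stoich, 0, 1000, subsystem="Biomass",
         name="biomass (growth pseudo-reaction)")
    model.objective = "BIOMASS"

    # decoy genes carried on the model so confidence clustering sees
    # expression without reaction evidence
    for gid in DECOY_GENES:
        if gid not in model.genes:
            model.genes.append(cobra.Gene(gid))

    growth = _growth_on(model, make_medium("l15_like"))
    if growth <= 1e-9:
        raise ToyConstructionError(
            "configured yields make biomass unproducible on the default medium"
        )
    return model


def _growth_on(model: cobra.Model, medium: MediumDefinition) -> float:
    from .model_core import apply_medium

    with model as m:
        apply_medium(m, medium)
        value = m.slim_optimize(error_value=0.0)
    return float(value or 0.0)


def make_phenotype_variants(base: cobra.Model) -> dict[str, cobra.Model]:
    """Bound-restricted submodels for the three subpopulation phenotypes.

    proliferative: fermentative — LDH runs pyruvate -> lactate only, and
        respiration is capped per cell so excess carbon overflows to lactate
        (the Warburg trait).
    invasive: LDH runs lactate -> pyruvate only (lactate consumer), weak
        galactose entry, oxidative TCA left intact.
    reservoir: the only variant allowed to export fumarate and ATP.
    """
    variants = {}
    for name in PHENOTYPES:
        m = base.copy()
        m.id = f"toy_{name}"
        if name == "proliferative":
            m.reactions.LDH.lower_bound = 0.0
            # Warburg trait: respiration capped per cell, excess carbon
            # overflows to lactate even when oxygen is available
            m.reactions.OXPHOS.upper_bound = 0.05
            m.reactions.FUMt.lower_bound = 0.0  # import only: no fumarate export
            m.reactions.ATPSEC.upper_bound = 0.0
        elif name == "invasive":
            m.reactions.LDH.upper_bound = 0.0
            m.reactions.GALK.upper_bound = 0.005
            m.reactions.FUMt.lower_bound = 0.0
            m.reactions.ATPSEC.upper_bound = 0.0
        else:  # reservoir keeps fumarate/ATP export capability
            pass
        variants[name] = m
    return variants


def make_medium(style: str = "l15_like",
                overrides: dict[str, float] | None = None) -> MediumDefinition:
    """Growth-medium definitions.

    ``l15_like`` emulates the qualitative composition of the Leibovitz-style
    medium the spheroids grow in: galactose is the carbohydrate (no glucose),
    pyruvate, glutamine and uptakeable amino acids, choline, oxygen at the
    normoxic bound 0.16, phosphate and water. Lactate, alpha-ketoglutarate,
    fumarate, succinate, ammonium and alanine are deliberately absent, so
    their later appearance in the shared medium is attributable to the
    community itself. ``custom`` starts empty.
    """
    known = {
        "gal_e", "pyr_e", "gln_e", "ser_e", "gly_e", "his_e", "trp_e",
        "lys_e", "ala_e", "chol_e", "o2_e", "pi_e", "h2o_e", "h_e", "lac_e",
        "akg_e", "fum_e", "succ_e", "nh4_e", "co2_e", "atpsig_e",
    }
    if style == "l15_like":
        bounds = {
            "gal_e": 0.05, "pyr_e": 0.01, "gln_e": 0.02,
            "ser_e": 0.05, "gly_e": 0.05, "his_e": 0.05,
            "trp_e": 0.05, "lys_e": 0.05,
            "chol_e": 0.01, "o2_e": 0.16,
            "pi_e": 10.0, "h2o_e": 1000.0, "h_e": 1000.0,
        }
    elif style == "custom":
        bounds = {}
    else:
        raise ValueError(f"unknown medium style {style!r}")
    ignored = {}
    for met, bound in (overrides or {}).items():
        if met not in known:
            warnings.warn(f"medium override for unknown metabolite {met!r} ignored")
            ignored[met] = float(bound)
            continue
        if bound <= 0:
            bounds.pop(met, None)
        else:
            bounds[met] = float(bound)
    medium = MediumDefinition(bounds)
    medium.ignored = ignored
    return medium


def make_expression_matrix(
    base: cobra.Model, config: SyntheticExpressionConfig | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Cells x genes negative-binomial count matrix with three labeled clusters.

    Genes are the base model's genes plus decoys. Each phenotype's marker
    genes are elevated by ``marker_fold_change`` in that phenotype's cluster
    and correspondingly suppressed in the other clusters, giving the
    three-tier (low/medium/high) structure the confidence clustering expects.
    Bernoulli dropout zeroes entries independently. Deterministic per seed.
    """
    cfg = config or SyntheticExpressionConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = sorted({g.id for g in base.genes} | set(DECOY_GENES))
    base_mean = pd.Series(
        rng.lognormal(mean=np.log(8.0), sigma=0.25, size=len(genes)), index=genes
    )

    frames = []
    labels = []
    for cluster in PHENOTYPES:
        means = base_mean.copy()
        for phen, markers in MARKER_GENES.items():
            present = [g for g in markers if g in means.index]
            if phen == cluster:
                means[present] *= cfg.marker_fold_change
            else:
                means[present] /= cfg.marker_fold_change
        r = cfg.dispersion
        p = r / (r + means.values)
        counts = rng.negative_binomial(
            r, p[None, :], size=(cfg.n_cells_per_cluster, len(genes))
        )
        if cfg.dropout_rate > 0:
            keep = rng.random(counts.shape) >= cfg.dropout_rate
            counts = counts * keep
        idx = [f"{cluster}_{i:03d}" for i in range(cfg.n_cells_per_cluster)]
        frames.append(pd.DataFrame(counts, index=idx, columns=genes))
        labels.extend([cluster] * cfg.n_cells_per_cluster)
    matrix = pd.concat(frames)
    return matrix, pd.Series(labels, index=matrix.index, name="cluster")


# --- dedicated small fixtures ------------------------------------------------


def make_obligate_pair() -> tuple[dict[str, cobra.Model], MediumDefinition]:
    """Producer/consumer pair with obligate cross-feeding of metabolite x.

    The producer converts substrate s into x and can grow on s alone; the
    consumer's biomass requires x and it cannot make it. Blocking the x route
    through the shared medium abolishes consumer growth.
    """
    producer = cobra.Model("producer")
    s_e = cobra.Metabolite("s_e", compartment="e", formula="C6H12O6", charge=0)
    s_c = cobra.Metabolite("s_c", compartment="c", formula="C6H12O6", charge=0)
    x_e = cobra.Metabolite("x_e", compartment="e", formula="C6H12O6", charge=0)
    x_c = cobra.Metabolite("x_c", compartment="c", formula="C6H12O6", charge=0)
    producer.add_metabolites([s_e, s_c, x_e, x_c])
    _rxn(producer, "EX_s_e", {s_e: -1}, -1000, 1000, subsystem="Exchange")
    _rxn(producer, "EX_x_e", {x_e: -1}, -1000, 1000, subsystem="Exchange")
    _rxn(producer, "St", {s_e: -1, s_c: 1}, 0, 1000, subsystem="Transport")
    _rxn(producer, "Xt", {x_c: -1, x_e: 1}, -1000, 1000, subsystem="Transport")
    _rxn(producer, "CONV", {s_c: -1, x_c: 1}, 0, 1000, subsystem="Core")
    _rxn(producer, "BIOMASS", {s_c: -1}, 0, 1000, subsystem="Biomass")
    producer.objective = "BIOMASS"

    consumer = cobra.Model("consumer")
    s_e2 = cobra.Metabolite("s_e", compartment="e", formula="C6H12O6", charge=0)
    x_e2 = cobra.Metabolite("x_e", compartment="e", formula="C6H12O6", charge=0)
    x_c2 = cobra.Metabolite("x_c", compartment="c", formula="C6H12O6", charge=0)
    consumer.add_metabolites([s_e2, x_e2, x_c2])
    _rxn(consumer, "EX_s_e", {s_e2: -1}, -1000, 1000, subsystem="Exchange")
    _rxn(consumer, "EX_x_e", {x_e2: -1}, -1000, 1000, subsystem="Exchange")
    _rxn(consumer, "Xt", {x_e2: -1, x_c2: 1}, 0, 1000, subsystem="Transport")
    _rxn(consumer, "BIOMASS", {x_c2: -1}, 0, 1000, subsystem="Biomass")
    consumer.objective = "BIOMASS"

    medium = MediumDefinition({"s_e": 10.0})
    return {"producer": producer, "consumer": consumer}, medium


def make_oxygen_bypass_model() -> tuple[cobra.Model, MediumDefinition]:
    """Single model whose biomass precursor x is either taken from the medium
    or synthesized by an oxidation that needs oxygen to recycle NAD+.

    With x in the medium the model grows at any oxygen level; without it, x
    synthesis (s + nad -> x + nadh) requires respiration, so x becomes
    medium-essential exactly under hypoxia. Formulas are deliberately absent:
    this synthetic fixture trades elemental bookkeeping for a clean redox
    switch.
    """
    m = cobra.Model("oxygen_bypass")
    mets = {
        mid: cobra.Metabolite(mid, compartment=("e" if mid.endswith("_e") else "c"))
        for mid in ["s_e", "s_c", "x_e", "x_c", "o2_e", "o2_c", "nad_c", "nadh_c"]
    }
    m.add_metabolites(list(mets.values()))
    _rxn(m, "EX_s_e", {mets["s_e"]: -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "EX_x_e", {mets["x_e"]: -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "EX_o2_e", {mets["o2_e"]: -1}, -1000, 1000, subsystem="Exchange")
    _rxn(m, "St", {mets["s_e"]: -1, mets["s_c"]: 1}, 0, 1000, subsystem="Transport")
    _rxn(m, "Xt", {mets["x_e"]: -1, mets["x_c"]: 1}, 0, 1000, subsystem="Transport")
    _rxn(m, "O2t", {mets["o2_e"]: -1, mets["o2_c"]: 1}, 0, 1000,
         subsystem="Transport")
    _rxn(m, "SYNX", {mets["s_c"]: -1, mets["nad_c"]: -1,
                     mets["x_c"]: 1, mets["nadh_c"]: 1}, 0, 1000,
         subsystem="Core", name="oxidative synthesis of x")
    _rxn(m, "RESP", {mets["nadh_c"]: -1, mets["o2_c"]: -0.5, mets["nad_c"]: 1},
         0, 1000, subsystem="Core", name="NADH oxidation")
    _rxn(m, "BIOMASS", {mets["x_c"]: -1}, 0, 1000, subsystem="Biomass")
    m.objective = "BIOMASS"
    medium = MediumDefinition({"s_e": 10.0, "x_e": 5.0, "o2_e": 10.0})
    return m, medium
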