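"""End-to-end orchestration: confidence -> extraction -> community ->
spatial ranking -> oxygen sweep -> essentiality -> cross-feeding.

`run_pipeline` executes every stage on either user-supplied inputs (model,
expression matrix, labels, medium read from paths) or the package's
synthetic inputs, writing one CSV per stage plus a provenance record
(config, seeds, solver tolerances) into the run directory. Re-running with
the same configuration reproduces all numbers to solver tolerance: every
stochastic stage is seeded and both solvers are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import crossfeeding as xf
from ._solver import FEASIBILITY_TOL
from .community import TradeoffConfig, build_community, cooperative_tradeoff
from .context_extraction import ExtractionConfig, extract_context_model
from .expression_confidence import confidence_for_cluster
from .microenvironment import (
    DEFAULT_STRATUM_OXYGEN,
    enumerate_configurations,
    oxygen_sweep,
    rank_configurations,
)
from .model_core import MediumDefinition, doubling_time, read_model, write_model
from .perturbation import (
    KnockoutCriterion,
    knockout_scan,
    medium_essentiality,
    supplement_medium,
)
from .synthetic_data import (
    SyntheticExpressionConfig,
    ToyNetworkConfig,
    make_expression_matrix,
    make_medium,
    make_toy_base_model,
)

logger = logging.getLogger(__name__)

#: subpopulation relative abundances at the two sampled days
DAY6_ABUNDANCES = {"invasive": 0.0977, "reservoir": 0.3910,
                   "proliferative": 0.5113}
DAY19_ABUNDANCES = {"invasive": 0.5739, "reservoir": 0.2739,
                    "proliferative": 0.1522}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths are optional; missing inputs fall back to the synthetic module."""

    base_model_path: str | None = None
    expression_path: str | None = None  # cells x genes CSV
    labels_path: str | None = None  # two-column CSV (cell, cluster)
    medium_path: str | None = None
    abundances: dict[str, float] = field(
        default_factory=lambda: dict(DAY6_ABUNDANCES)
    )
    alpha: float = 1.0
    sweep_start: float = 0.16
    sweep_step: float = 0.01
    stratum_oxygen: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_OXYGEN)
    )
    essentiality_criterion: tuple[str, float] = ("absolute", 1e-6)
    extraction_seed: int = 0
    expression_seed: int = 0
    supplements: dict[str, float] = field(
        default_factory=lambda: {"lac": 0.05, "akg": 0.05}
    )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages and write results under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.base_model_path:
            base = read_model(config.base_model_path)
        else:
            base = make_toy_base_model(ToyNetworkConfig())
        if config.medium_path:
            path = Path(config.medium_path)
            if not path.exists():
                raise FileNotFoundError(f"medium file not found: {path}")
            medium = MediumDefinition.from_csv(path)
        else:
            medium = make_medium("l15_like")
        if config.expression_path and config.labels_path:
            matrix = pd.read_csv(config.expression_path, index_col=0)
            labels = pd.read_csv(config.labels_path, index_col=0).iloc[:, 0]
        else:
            matrix, labels = make_expression_matrix(
                base, SyntheticExpressionConfig(seed=config.expression_seed)
            )
        members = sorted(config.abundances)

        stage = "confidence"
        confidences = {}
        for member in members:
            gene_conf, rxn_conf, de = confidence_for_cluster(
                base, matrix, labels, member, medium
            )
            confidences[member] = rxn_conf
            pd.Series(rxn_conf, name="confidence").rename_axis("id").to_csv(
                outdir / f"confidence_{member}.tsv", sep="\t"
            )
            de.table.rename_axis("gene").to_csv(
                outdir / f"de_{member}.tsv", sep="\t"
            )

        stage = "extraction"
        models = {}
        for member in members:
            sub, log = extract_context_model(
                base, confidences[member],
                ExtractionConfig(seed=config.extraction_seed), medium,
            )
            models[member] = sub
            log.to_csv(outdir / f"extraction_{member}.tsv", sep="\t",
                       index=False)
            write_model(sub, outdir / f"model_{member}.json", format="json")

        stage = "community"
        cm = build_community(models, config.abundances, medium)
        tcfg = TradeoffConfig(config.alpha)
        sol = cooperative_tradeoff(cm, tcfg)
        growth = sol.community_growth
        pd.DataFrame(
            [
                {"reaction": rid,
                 "member": rid.split("__", 1)[0] if "__" in rid else "medium",
                 "flux": flux}
                for rid, flux in sol.fluxes.items()
            ]
        ).to_csv(outdir / "community_fluxes.csv", index=False)

        stage = "spatial"
        configs = enumerate_configurations(members, config.stratum_oxygen)
        ranking = rank_configurations(cm, configs, tcfg)
        ranking.to_csv(outdir / "spatial_ranking.csv", index=False)

        stage = "sweep"
        sweep = oxygen_sweep(cm, config.sweep_start, config.sweep_step,
                             cfg=tcfg)
        sweep.table.to_csv(outdir / "oxygen_sweep.csv", index=False)

        stage = "essentiality"
        criterion = KnockoutCriterion(*config.essentiality_criterion)
        ko = knockout_scan(cm, "exchanges", tcfg, criterion)
        ko.to_csv(outdir / "knockout_exchanges.csv", index=False)
        med_ess = medium_essentiality(cm, cfg=tcfg, criterion=criterion)
        med_ess.to_csv(outdir / "medium_essentiality.csv", index=False)
        supp_rows = []
        for stub, bound in config.supplements.items():
            try:
                res = supplement_medium(cm, stub, bound, tcfg)
            except KeyError:
                continue
            supp_rows.append(
                {"metabolite": stub, "bound": bound,
                 "baseline_growth": res.baseline_growth, "growth": res.growth,
                 "doubling_time_h": res.doubling_time_h}
            )
        pd.DataFrame(supp_rows).to_csv(outdir / "supplementation.csv",
                                       index=False)

        stage = "crossfeeding"
        table = xf.classify_exchanges(sol, cm)
        table.to_csv(outdir / "exchange_states.csv", index=False)
        edges = xf.crossfeeding_edges(sol, cm, medium)
        xf.edges_table(edges).to_csv(outdir / "crossfeeding_edges.csv",
                                     index=False)
        activity = xf.pathway_activity(sol, cm)
        activity.to_csv(outdir / "pathway_activity.csv", index=False)

        stage = "provenance"
        provenance = {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "community_growth": growth,
            "doubling_time_h": doubling_time(growth) if growth > 0 else None,
            "solver": {"lp": "scipy-highs", "qp": "osqp",
                       "feasibility_tol": FEASIBILITY_TOL},
        }
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str)
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    return outdir
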