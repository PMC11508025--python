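"""Per-gene and per-reaction confidence scores from clustered expression data.

For one target cell cluster, genes are partitioned into exactly three groups
by agglomerative clustering (Euclidean metric, average linkage) of their
log-normalized expression profiles across that cluster's cells; the groups
are ranked by mean expression and mapped to confidence 1 (low), 2 (medium),
3 (high). Differential expression against the remaining cells then overrides
the clustering: genes significantly overexpressed (fold change >= 2,
p <= 0.05) are forced to 3, significantly underexpressed (fold change <= 1/2)
to 1. Reaction confidences follow from gene confidences through the GPR rule
(AND -> min, OR -> max); exchanges for medium metabolites and the biomass
reaction are forced to 3 so the extraction step can always feed the cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from .model_core import MediumDefinition, biomass_reaction_id, exchange_reactions

logger = logging.getLogger(__name__)

FC_THRESHOLD = 2.0
P_THRESHOLD = 0.05
PSEUDOCOUNT = 1.0


class DegenerateExpressionError(ValueError):
    """Too little structure in the expression matrix to cluster genes."""


@dataclass
class DEResult:
    """Per-gene differential-expression table for one target cluster."""

    table: pd.DataFrame  # index gene, columns fold_change, p_value, direction

    def significant_up(self) -> pd.Index:
        t = self.table
        return t.index[
            (t["fold_change"] >= FC_THRESHOLD) & (t["p_value"] <= P_THRESHOLD)
        ]

    def significant_down(self) -> pd.Index:
        t = self.table
        return t.index[
            (t["fold_change"] <= 1.0 / FC_THRESHOLD)
            & (t["p_value"] <= P_THRESHOLD)
        ]


def _lognorm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalization to the median depth, then log1p."""
    depth = matrix.sum(axis=1)
    target = float(depth.median()) or 1.0
    scale = target / depth.replace(0, np.nan)
    return np.log1p(matrix.mul(scale.fillna(0.0), axis=0))


def cluster_gene_confidence(
    matrix: pd.DataFrame, labels: pd.Series, target_cluster: str
) -> dict[str, int]:
    """Assign confidence 1/2/3 to every gene from the target cluster's cells.

    matrix: cells x genes counts; labels: cluster label per cell.
    Genes are clustered on their log-normalized expression vectors over the
    target cluster's cells; the three groups are ranked by mean expression.
    A constant matrix falls back to a tertile split (all ties -> 2) with a
    logged warning; fewer than three distinct profiles is an error.
    """
    cells = labels.index[labels == target_cluster]
    if len(cells) < 2:
        raise ValueError(f"target cluster {target_cluster!r} has < 2 cells")
    X = _lognorm(matrix.loc[cells]).T  # genes x cells
    profiles = X.to_numpy()
    distinct = np.unique(profiles.round(12), axis=0)
    if distinct.shape[0] == 1:
        logger.warning(
            "all gene profiles identical in cluster %s; tertile fallback",
            target_cluster,
        )
        return {g: 2 for g in X.index}
    if distinct.shape[0] < 3:
        raise DegenerateExpressionError(
            f"only {distinct.shape[0]} distinct gene profiles in cluster "
            f"{target_cluster!r}; cannot form 3 confidence groups"
        )
    groups = AgglomerativeClustering(
        n_clusters=3, metric="euclidean", linkage="average"
    ).fit_predict(profiles)
    means = X.mean(axis=1).to_numpy()
    order = np.argsort([means[groups == g].mean() for g in range(3)])
    rank = {g: i + 1 for i, g in enumerate(order)}  # lowest mean -> 1
    return {gene: rank[grp] for gene, grp in zip(X.index, groups)}


def differential_expression(
    matrix: pd.DataFrame, labels: pd.Series, target_cluster: str
) -> DEResult:
    """Fold change (pseudocount 1) and two-sided Mann-Whitney p per gene."""
    in_cells = labels.index[labels == target_cluster]
    out_cells = labels.index[labels != target_cluster]
    if len(in_cells) < 2 or len(out_cells) < 2:
        raise ValueError("need >= 2 cells inside and outside the target cluster")
    raw_in = matrix.loc[in_cells].mean()
    raw_out = matrix.loc[out_cells].mean()
    fc = (raw_in + PSEUDOCOUNT) / (raw_out + PSEUDOCOUNT)
    # rank test on the raw counts, matching the scale of the fold change
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.mannwhitneyu(
            matrix.loc[in_cells], matrix.loc[out_cells], alternative="two-sided"
        )
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "direction": np.where(fc >= 1.0, "up", "down"),
        },
        index=matrix.columns,
    )
    flagged = (raw_in == 0) & (raw_out == 0)
    table["all_zero"] = flagged
    return DEResult(table)


def apply_de_overrides(
    gene_confidence: dict[str, int], de: DEResult
) -> dict[str, int]:
    """Force significant up-genes to 3 and down-genes to 1; idempotent."""
    out = dict(gene_confidence)
    for gene in de.significant_up():
        if gene in out:
            out[gene] = 3
    for gene in de.significant_down():
        if gene in out:
            out[gene] = 1
    return out


def _gpr_confidence(expr, gene_conf: dict[str, int], missing: set[str]) -> int:
    """Evaluate a cobra GPR AST with AND -> min, OR -> max."""
    import ast

    node = expr
    if isinstance(node, ast.Expression):
        return _gpr_confidence(node.body, gene_conf, missing)
    if isinstance(node, ast.BoolOp):
        values = [_gpr_confidence(v, gene_conf, missing) for v in node.values]
        return min(values) if isinstance(node.op, ast.And) else max(values)
    if isinstance(node, ast.Name):
        if node.id not in gene_conf:
            missing.add(node.id)
            return 2
        return gene_conf[node.id]
    raise ValueError(f"unsupported GPR node {node!r}")


def reaction_confidence(
    model,
    gene_confidence: dict[str, int],
    medium: MediumDefinition,
) -> dict[str, int]:
    """Per-reaction confidence from gene confidences and the medium.

    Empty-GPR reactions default to 2 (transporters without gene evidence are
    neither forced in nor out); exchange reactions for medium metabolites and
    the biomass reaction are forced to 3.
    """
    biomass = biomass_reaction_id(model)
    medium_ex = {
        r.id
        for r in exchange_reactions(model)
        if medium.uptake(next(iter(r.metabolites)).id) > 0
    }
    missing: set[str] = set()
    conf = {}
    for rxn in model.reactions:
        if rxn.id == biomass or rxn.id in medium_ex:
            conf[rxn.id] = 3
        elif not rxn.gene_reaction_rule:
            conf[rxn.id] = 2
        else:
            import ast

            tree = ast.parse(rxn.gene_reaction_rule, mode="eval")
            conf[rxn.id] = _gpr_confidence(tree, gene_confidence, missing)
    if missing:
        logger.warning(
            "GPR genes without expression data treated as confidence 2: %s",
            sorted(missing),
        )
    return conf


def confidence_for_cluster(
    model,
    matrix: pd.DataFrame,
    labels: pd.Series,
    target_cluster: str,
    medium: MediumDefinition,
) -> tuple[dict[str, int], dict[str, int], DEResult]:
    """Full gene -> reaction confidence pipeline for one cluster."""
    gene_conf = cluster_gene_confidence(matrix, labels, target_cluster)
    de = differential_expression(matrix, labels, target_cluster)
    gene_conf = apply_de_overrides(gene_conf, de)
    rxn_conf = reaction_confidence(model, gene_conf, medium)
    return gene_conf, rxn_conf, de
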