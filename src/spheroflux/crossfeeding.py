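"""Exchange classification, cross-feeding edges, pathway activity.

Exchange reactions are recognized by the ``EX_<metabolite>_m`` naming
convention of the community model (both member exchanges and community
exchanges). A member secretes a metabolite when its member-exchange flux
exceeds the direction tolerance, consumes it below the negative tolerance,
and is inactive otherwise. A cross-feeding edge exists for every
(producer, consumer) pair sharing a metabolite through the medium; edge
fluxes are abundance-scaled (a_i * v) and flagged with whether the
metabolite was present in the initial growth medium. Because trade-off
fluxes are not unique, edges report one optimal flux pattern (the parsimony
tie-break solution), not the unique one.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .community import CommunityModel, FluxSolution
from .model_core import MediumDefinition

#: flux-direction tolerance used by every classification in this module
DIRECTION_TOL = 1e-6


@dataclass
class CrossFeedingEdge:
    metabolite: str
    producer: str
    consumer: str
    producer_flux: float  # abundance-scaled, > 0
    consumer_flux: float  # abundance-scaled, < 0
    in_medium: bool


def _state(flux: float, tol: float) -> str:
    if flux > tol:
        return "secreted"
    if flux < -tol:
        return "consumed"
    return "inactive"


def classify_exchanges(
    sol: FluxSolution,
    cm: CommunityModel,
    top_n: int | None = None,
    tol: float = DIRECTION_TOL,
) -> pd.DataFrame:
    """Secretion/consumption table over all EX_*_m reactions.

    Member rows carry the member name; environment-level rows carry
    "medium". ``top_n`` truncates each member block to the n highest
    |flux| rows (presentation only — compute edges from the full table).
    """
    rows = []
    for member in cm.member_names:
        for rid in cm.member_exchange_ids(member):
            stub = rid.split("__EX_", 1)[1][:-2]
            flux = float(sol.fluxes[rid])
            rows.append(
                {
                    "member": member,
                    "metabolite": stub,
                    "flux": flux,
                    "state": _state(flux, tol),
                }
            )
    for rid in cm.community_exchange_ids():
        stub = rid[3:-2]
        flux = float(sol.fluxes[rid])
        rows.append(
            {
                "member": "medium",
                "metabolite": stub,
                "flux": flux,
                # positive community-exchange flux leaves to the environment
                "state": _state(flux, tol),
            }
        )
    df = pd.DataFrame(rows)
    if top_n is not None:
        df = (
            df.assign(_abs=df["flux"].abs())
            .sort_values(["member", "_abs"], ascending=[True, False])
            .groupby("member", group_keys=False)
            .head(top_n)
            .drop(columns="_abs")
            .reset_index(drop=True)
        )
    df.attrs["tolerance"] = tol
    return df


def crossfeeding_edges(
    sol: FluxSolution,
    cm: CommunityModel,
    medium: MediumDefinition | None = None,
    tol: float = DIRECTION_TOL,
) -> list[CrossFeedingEdge]:
    """All (producer, consumer) pairs routed through the shared medium."""
    medium = medium or cm.medium
    abund = cm.abundances
    edges = []
    for stub in cm.shared_metabolite_stubs():
        producers = []
        consumers = []
        for member in cm.member_names:
            rid = cm.member_exchange_id(member, stub)
            if rid not in sol.fluxes.index:
                continue
            flux = float(sol.fluxes[rid])
            if flux > tol:
                producers.append((member, flux))
            elif flux < -tol:
                consumers.append((member, flux))
        for pname, pflux in producers:
            for cname, cflux in consumers:
                if pname == cname:
                    continue
                edges.append(
                    CrossFeedingEdge(
                        metabolite=stub,
                        producer=pname,
                        consumer=cname,
                        producer_flux=abund[pname] * pflux,
                        consumer_flux=abund[cname] * cflux,
                        in_medium=medium.uptake(f"{stub}_e") > 0,
                    )
                )
    return edges


def edges_table(edges: list[CrossFeedingEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": e.metabolite,
                "producer": e.producer,
                "consumer": e.consumer,
                "producer_flux": e.producer_flux,
                "consumer_flux": e.consumer_flux,
                "in_medium": e.in_medium,
            }
            for e in edges
        ],
        columns=[
            "metabolite", "producer", "consumer",
            "producer_flux", "consumer_flux", "in_medium",
        ],
    )


def pathway_activity(
    sol: FluxSolution,
    cm: CommunityModel,
    tol: float = DIRECTION_TOL,
) -> pd.DataFrame:
    """Active reaction counts per (member, subsystem).

    A reaction is active when |flux| > tol; flux against the declared
    forward direction counts as reversed. Reactions without a subsystem are
    grouped under "unannotated"; member exchanges are excluded.
    """
    rows = []
    for rxn in cm.model.reactions:
        if "__" not in rxn.id:
            continue
        member, local = rxn.id.split("__", 1)
        if local.startswith("EX_"):
            continue
        flux = float(sol.fluxes[rxn.id])
        rows.append(
            {
                "member": member,
                "subsystem": rxn.subsystem or "unannotated",
                "reaction": local,
                "active": abs(flux) > tol,
                "forward": flux > tol,
                "reversed": flux < -tol,
            }
        )
    per_rxn = pd.DataFrame(rows)
    summary = (
        per_rxn.groupby(["member", "subsystem"])[["active", "forward", "reversed"]]
        .sum()
        .astype(int)
        .rename(
            columns={
                "active": "active_reaction_count",
                "forward": "forward_count",
                "reversed": "reversed_count",
            }
        )
        .reset_index()
    )
    summary.attrs["tolerance"] = tol
    summary.attrs["per_reaction"] = per_rxn
    return summary


def exchange_boolean_matrix(
    solutions: dict[str, FluxSolution],
    cm: CommunityModel,
    tol: float = DIRECTION_TOL,
) -> pd.DataFrame:
    """State matrix over named conditions, rows (member, metabolite)."""
    if not solutions:
        raise ValueError("need at least one condition")
    columns = {}
    for condition, sol in solutions.items():
        states = {}
        for member in cm.member_names:
            for stub in cm.shared_metabolite_stubs():
                rid = cm.member_exchange_id(member, stub)
                if rid not in sol.fluxes.index:
                    raise ValueError(
                        f"condition {condition!r} lacks member exchange {rid}"
                    )
                states[(member, stub)] = _state(float(sol.fluxes[rid]), tol)
        columns[condition] = states
    df = pd.DataFrame(columns)
    df.index.names = ["member", "metabolite"]
    df.attrs["tolerance"] = tol
    return df


def categorize_exchange_dynamics(matrix: pd.DataFrame) -> pd.Series:
    """Classify each (member, metabolite) across conditions.

    "always_consumed" / "always_secreted" for pairs active in at least one
    condition and never changing sign; "switching" for pairs that both
    secrete and consume across conditions; inactive-everywhere pairs are
    excluded.
    """
    out = {}
    for key, row in matrix.iterrows():
        states = set(row)
        if states == {"inactive"}:
            continue
        if "secreted" in states and "consumed" in states:
            out[key] = "switching"
        elif "secreted" in states:
            out[key] = "always_secreted"
        else:
            out[key] = "always_consumed"
    series = pd.Series(out, dtype=object, name="category")
    if len(series):
        series.index.names = ["member", "metabolite"]
    return series
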