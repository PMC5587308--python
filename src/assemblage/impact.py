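"""SDI-weighted climate-impact aggregation for assemblage clusters.

Given per-(plot, species, scenario) projected importance-value changes
(delta IV) with reliability grades, a cluster is *eligible* for impact
assessment when (1) it contains at least ``min_plots`` plots, (2) every
dominant species has projections covering all of the cluster's plots, and
(3) more than half of its dominant species carry at least medium
reliability.  For eligible clusters two summaries are computed:

- assemblage impact: the mean delta-IV of the dominant species over all
  plots of the cluster, weighted by each species' SDI —
  sum_p sum_s SDI_s * delta_ps / (n_plots * sum_s SDI_s);
- plot impact: the unweighted mean delta-IV across dominant species at each
  plot, for mapping spatial pattern within the cluster.

When a ``current_iv`` baseline column is present, a percent change is
reported alongside the raw delta (delta relative to the SDI-weighted mean
current IV); the raw scale is always emitted since the baseline convention
is a choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EligibilityConfig",
    "eligible_clusters",
    "assemblage_impact",
    "plot_impact",
    "impact_summary",
]

_RELIABILITY_RANK = {"low": 0, "medium": 1, "high": 2}


@dataclass(frozen=True)
class EligibilityConfig:
    min_plots: int = 100
    require_all_dominant_projected: bool = True
    min_majority_reliability: str = "medium"

    def __post_init__(self):
        if self.min_plots < 1:
            raise ValueError("min_plots must be >= 1")
        if self.min_majority_reliability not in _RELIABILITY_RANK:
            raise ValueError("min_majority_reliability must be low/medium/high")


def _dominant_by_cluster(dominant: pd.DataFrame) -> dict:
    dom = dominant[dominant["dominant"]] if "dominant" in dominant.columns else dominant
    return {c: g.set_index("species")["SDI"] for c, g in dom.groupby("cluster")}


def eligible_clusters(
    membership,
    dominant: pd.DataFrame,
    delta: pd.DataFrame,
    cfg: EligibilityConfig = EligibilityConfig(),
    scenario: str | None = None,
) -> pd.DataFrame:
    """Per-(cluster, scenario) eligibility with the failed criterion as reason.

    ``membership`` maps plot_id -> cluster; ``dominant`` is the flagged SDI
    table; ``delta`` the projection table.  Reasons: "min_plots",
    "no_dominant_species", "missing_projection", "reliability"; eligible
    rows carry reason "".
    """
    memb = pd.Series(membership)
    scenarios = [scenario] if scenario is not None else sorted(delta["scenario"].unique())
    dom = _dominant_by_cluster(dominant)
    rows = []
    for scen in scenarios:
        d = delta[delta["scenario"] == scen]
        proj_plots = {s: set(g["plot_id"]) for s, g in d.groupby("species")}
        grade = d.drop_duplicates("species").set_index("species")["reliability"]
        for cluster in sorted(memb.unique()):
            plots = set(memb.index[memb == cluster].astype(str))
            reason = ""
            sdis = dom.get(cluster)
            if len(plots) < cfg.min_plots:
                reason = "min_plots"
            elif sdis is None or sdis.empty:
                reason = "no_dominant_species"
            elif cfg.require_all_dominant_projected and any(
                not plots <= proj_plots.get(s, set()) for s in sdis.index
            ):
                reason = "missing_projection"
            else:
                ranks = [
                    _RELIABILITY_RANK.get(grade.get(s, "low"), 0) for s in sdis.index
                ]
                need = _RELIABILITY_RANK[cfg.min_majority_reliability]
                if np.mean([r >= need for r in ranks]) <= 0.5:
                    reason = "reliability"
            rows.append(
                {
                    "cluster": cluster,
                    "scenario": scen,
                    "n_plots": len(plots),
                    "eligible": reason == "",
                    "reason": reason,
                }
            )
    return pd.DataFrame(rows)


def _delta_matrix(plots, species, delta, scen, column="delta_iv"):
    d = delta[delta["scenario"] == scen]
    mat = d.pivot_table(index="plot_id", columns="species", values=column, aggfunc="first")
    mat.index = mat.index.astype(str)
    try:
        mat = mat.loc[list(plots), list(species)]
    except KeyError as e:
        raise ValueError(f"missing projection rows for cluster plots/species: {e}") from None
    if mat.isna().any().any():
        raise ValueError("missing delta_iv for a dominant species at some plot")
    return mat


def assemblage_impact(membership, cluster, dominant: pd.DataFrame, delta: pd.DataFrame, scenario: str) -> dict:
    """SDI-weighted mean dominant-species delta-IV over all plots of a cluster."""
    memb = pd.Series(membership)
    plots = [str(p) for p in memb.index[memb == cluster]]
    if not plots:
        raise ValueError(f"cluster {cluster!r} has no plots")
    sdis = _dominant_by_cluster(dominant).get(cluster)
    if sdis is None or sdis.empty:
        raise ValueError(f"cluster {cluster!r} has no dominant species")
    mat = _delta_matrix(plots, sdis.index, delta, scenario)
    w = sdis.to_numpy()
    weighted = float((mat.to_numpy() @ w).sum() / (len(plots) * w.sum()))
    out = {
        "cluster": cluster,
        "scenario": scenario,
        "weighted_mean_delta": weighted,
        "n_plots": len(plots),
    }
    if "current_iv" in delta.columns and delta["current_iv"].notna().all():
        base = _delta_matrix(plots, sdis.index, delta, scenario, column="current_iv")
        wbase = float((base.to_numpy() @ w).sum() / (len(plots) * w.sum()))
        out["percent_change"] = 100.0 * weighted / wbase if wbase != 0 else np.nan
    return out


def plot_impact(membership, cluster, dominant: pd.DataFrame, delta: pd.DataFrame, scenario: str) -> pd.DataFrame:
    """Unweighted mean delta-IV over the cluster's dominant species per plot."""
    memb = pd.Series(membership)
    plots = [str(p) for p in memb.index[memb == cluster]]
    if not plots:
        raise ValueError(f"cluster {cluster!r} has no plots")
    sdis = _dominant_by_cluster(dominant).get(cluster)
    if sdis is None or sdis.empty:
        raise ValueError(f"cluster {cluster!r} has no dominant species")
    mat = _delta_matrix(plots, sdis.index, delta, scenario)
    out = pd.DataFrame(
        {"plot_id": mat.index, "cluster": cluster, "scenario": scenario,
         "mean_delta": mat.to_numpy().mean(axis=1)}
    )
    if {"x", "y"} <= set(delta.columns):
        coords = delta.drop_duplicates("plot_id").set_index("plot_id")[["x", "y"]]
        coords.index = coords.index.astype(str)
        out = out.join(coords, on="plot_id")
    return out.reset_index(drop=True)


def impact_summary(
    membership,
    dominant: pd.DataFrame,
    delta: pd.DataFrame,
    cfg: EligibilityConfig = EligibilityConfig(),
    scenario: str | None = None,
) -> pd.DataFrame:
    """Assemblage impact for every eligible (cluster, scenario)."""
    elig = eligible_clusters(membership, dominant, delta, cfg, scenario=scenario)
    rows = []
    for _, r in elig[elig["eligible"]].iterrows():
        rows.append(assemblage_impact(membership, r["cluster"], dominant, delta, r["scenario"]))
    cols = ["cluster", "scenario", "weighted_mean_delta", "n_plots"]
    return pd.DataFrame(rows, columns=cols if not rows or "percent_change" not in rows[0] else cols + ["percent_change"])
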