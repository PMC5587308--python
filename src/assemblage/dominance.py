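"""Species dominance index (SDI) within clusters and dominant-species lists.

Within a cluster, a species can dominate in three ways: by having high
relative importance across many plots, by occurring with few other species,
or by having very high importance in the (possibly few) plots where it does
occur.  The SDI averages one component for each:

    SDI = (MC + MSS + THC) / 3

MC   mean relative IV (0-1) over *all* plots of the cluster (zeros count);
MSS  mean of 1 / plot richness over the plots where the species occurs;
THC  fraction of occurrence plots where the species has > 25% relative IV
     (strict) and at least as much as every other species (ties count).

Dominant species are the (species, cluster) records whose SDI reaches a
percentile cutoff pooled over all records (default the 90th percentile;
85th and 95th are standard alternatives).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_sdi", "dominant_species"]

COVER_THRESHOLD = 0.25


def compute_sdi(ivm, membership, mc_denominator: str = "cluster") -> pd.DataFrame:
    """SDI per (species, cluster); records for absent species are omitted.

    mc_denominator
        "cluster" (default) — MC averages over the plots of the cluster;
        "all" — over every plot in the matrix (an alternative reading of
        "mean cover across all plots").
    """
    if mc_denominator not in ("cluster", "all"):
        raise ValueError("mc_denominator must be 'cluster' or 'all'")
    if not isinstance(ivm, pd.DataFrame):
        ivm = pd.DataFrame(np.asarray(ivm, dtype=float))
    memb = pd.Series(membership).reindex(ivm.index)
    if memb.isna().any():
        raise ValueError("membership missing for some plots")
    V = ivm.to_numpy(dtype=float) / 100.0  # relative IV on the 0-1 scale
    present = V > 0
    richness = present.sum(axis=1)
    if (richness == 0).any():
        raise ValueError("plot with no species present")
    inv_rich = 1.0 / richness
    row_max = V.max(axis=1)
    qualifies = (V > COVER_THRESHOLD) & (V >= row_max[:, None] - 1e-12)

    species = np.asarray(ivm.columns)
    records = []
    n_total = len(ivm)
    for cluster in np.unique(memb.to_numpy()):
        rows = (memb == cluster).to_numpy()
        Vc, Pc, Qc = V[rows], present[rows], qualifies[rows]
        occ = Pc.sum(axis=0)
        has = occ > 0
        denom = n_total if mc_denominator == "all" else rows.sum()
        mc = Vc.sum(axis=0) / denom
        mss = np.zeros(len(species))
        mss[has] = (Pc * inv_rich[rows][:, None]).sum(axis=0)[has] / occ[has]
        thc = np.zeros(len(species))
        thc[has] = Qc.sum(axis=0)[has] / occ[has]
        sdi = (mc + mss + thc) / 3.0
        for j in np.flatnonzero(has):
            records.append(
                {
                    "species": species[j],
                    "cluster": cluster,
                    "MC": mc[j],
                    "MSS": mss[j],
                    "THC": thc[j],
                    "SDI": sdi[j],
                }
            )
    return pd.DataFrame.from_records(records)


def dominant_species(sdi: pd.DataFrame, percentile: float = 90.0):
    """Dominant (species, cluster) records at a pooled SDI percentile cutoff.

    The cutoff is the given percentile (linear interpolation between order
    statistics) of all SDI records pooled across clusters; a record is
    dominant iff SDI >= cutoff, so ties at the cutoff are included.  Returns
    ``(table, cutoff)`` with the table flagged and sorted by cluster then
    SDI descending.
    """
    if sdi.empty:
        raise ValueError("empty SDI table")
    if not 0 <= percentile < 100:
        raise ValueError("percentile must lie in [0, 100)")
    cutoff = float(np.percentile(sdi["SDI"].to_numpy(), percentile))
    out = sdi.copy()
    out["dominant"] = out["SDI"] >= cutoff
    out["cutoff"] = cutoff
    out = out.sort_values(["cluster", "SDI"], ascending=[True, False], kind="stable")
    return out.reset_index(drop=True), cutoff
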