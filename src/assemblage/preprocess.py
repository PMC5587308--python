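"""Raw tree records -> analysis-ready plot x species importance-value matrix.

The pipeline's external input is a *tree record table*: one row per stem with
``plot_id``, ``species_code`` and either ``dbh_cm`` or ``basal_area_m2``
(optionally ``region_code``, ``plot_flags``, ``x``, ``y``).  This module
recodes species (merges of varieties, drops of generic labels, regional
splits), filters flagged plots and rare species, and computes relative
importance values:

    IV[p, s] = 100 * (BA_s / sum BA + N_s / sum N) / 2

per plot, where BA is summed basal area and N is stem count, so every plot's
IVs sum to 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RecodingRule",
    "basal_area_from_dbh",
    "ensure_basal_area",
    "apply_recoding",
    "filter_plots",
    "filter_rare_species",
    "compute_iv",
    "preprocess_records",
    "read_records",
    "write_iv_matrix",
    "read_iv_matrix",
]

#: Plot flags excluded by default: plots with few or no trees, and plots
#: typed as nonnative assemblages.
DEFAULT_EXCLUDE_FLAGS = ("nonstocked", "nonnative_type")

_REQUIRED_COLUMNS = ("plot_id", "species_code")


def basal_area_from_dbh(dbh_cm):
    """Stem basal area in m^2 from diameter at breast height in cm.

    BA = pi * (dbh / 200)^2 — the cross-sectional area of the stem.
    Accepts scalars or arrays; raises on nonpositive diameters.
    """
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(~np.isfinite(dbh)) or np.any(dbh <= 0):
        raise ValueError("dbh_cm must be finite and strictly positive")
    ba = math.pi * (dbh / 200.0) ** 2
    return float(ba) if np.isscalar(dbh_cm) else ba


def _check_records(records: pd.DataFrame) -> None:
    for col in _REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"record table lacks required column {col!r}")
    if "dbh_cm" not in records.columns and "basal_area_m2" not in records.columns:
        raise ValueError("record table needs dbh_cm or basal_area_m2")


def ensure_basal_area(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``basal_area_m2`` filled in from ``dbh_cm`` where absent."""
    _check_records(records)
    out = records.copy()
    if "basal_area_m2" not in out.columns:
        out["basal_area_m2"] = np.nan
    missing = out["basal_area_m2"].isna()
    if missing.any():
        if "dbh_cm" not in out.columns or out.loc[missing, "dbh_cm"].isna().any():
            raise ValueError("rows lacking basal_area_m2 must carry dbh_cm")
        out.loc[missing, "basal_area_m2"] = basal_area_from_dbh(
            out.loc[missing, "dbh_cm"].to_numpy()
        )
    ba = out["basal_area_m2"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ba)) or np.any(ba <= 0):
        raise ValueError("basal areas must be finite and strictly positive")
    return out


@dataclass(frozen=True)
class RecodingRule:
    """A species recoding step.

    kind
        ``"merge"`` — replace every code in ``source_codes`` by ``target_code``
        (varieties folded into one taxon).
        ``"drop"`` — delete records carrying any of ``source_codes``
        (generic labels representing few records).
        ``"regional_split"`` — split the single code in ``source_codes`` by
        ``region_map`` (region code -> new species code), with
        ``default_target`` for unmatched regions.  Used e.g. to separate
        coastal from interior Douglas-fir populations by region.
    """

    kind: str
    source_codes: tuple
    target_code: str | None = None
    region_map: dict = field(default_factory=dict)
    default_target: str | None = None

    def __post_init__(self):
        if self.kind not in ("merge", "drop", "regional_split"):
            raise ValueError(f"unknown recoding kind {self.kind!r}")
        if self.kind == "merge" and not self.target_code:
            raise ValueError("merge rule needs a target_code")
        if self.kind == "regional_split":
            if self.region_map and not self.default_target:
                raise ValueError("regional_split needs a default_target")
            if len(self.source_codes) != 1:
                raise ValueError("regional_split takes exactly one source code")
            if self.target_code is not None:
                raise ValueError("regional_split uses region_map, not target_code")
        elif self.region_map:
            raise ValueError(f"{self.kind} rule must not carry a region_map")


def rules_from_config(blocks) -> list[RecodingRule]:
    """Build rules from parsed YAML/JSON blocks (list of dicts)."""
    rules = []
    for b in blocks:
        rules.append(
            RecodingRule(
                kind=b["kind"],
                source_codes=tuple(b["source_codes"]),
                target_code=b.get("target_code"),
                region_map=dict(b.get("region_map", {})),
                default_target=b.get("default_target"),
            )
        )
    return rules


def apply_recoding(records: pd.DataFrame, rules) -> pd.DataFrame:
    """Apply merge / drop / regional-split rules; idempotent for a fixed rule set."""
    _check_records(records)
    seen: dict[str, str] = {}
    for rule in rules:
        for code in rule.source_codes:
            if code in seen:
                raise ValueError(f"conflicting rules target source code {code!r}")
            seen[code] = rule.kind
    out = records.copy()
    for rule in rules:
        codes = out["species_code"]
        if rule.kind == "merge":
            out.loc[codes.isin(rule.source_codes), "species_code"] = rule.target_code
        elif rule.kind == "drop":
            out = out[~codes.isin(rule.source_codes)]
        else:  # regional_split
            src = rule.source_codes[0]
            mask = codes == src
            if mask.any():
                if "region_code" not in out.columns:
                    raise ValueError("regional_split needs a region_code column")
                regions = out.loc[mask, "region_code"]
                out.loc[mask, "species_code"] = regions.map(rule.region_map).fillna(
                    rule.default_target
                )
    return out.reset_index(drop=True)


def _flag_sets(flags: pd.Series) -> pd.Series:
    return flags.fillna("").astype(str).map(
        lambda s: frozenset(t for t in s.replace(",", ";").split(";") if t)
    )


def filter_plots(records: pd.DataFrame, exclude_flags=DEFAULT_EXCLUDE_FLAGS) -> pd.DataFrame:
    """Drop every plot that carries any excluded flag (on any of its rows)."""
    _check_records(records)
    if "plot_flags" not in records.columns or not len(exclude_flags):
        return records.copy()
    exclude = frozenset(exclude_flags)
    flagged = records.loc[
        _flag_sets(records["plot_flags"]).map(lambda s: bool(s & exclude)), "plot_id"
    ].unique()
    out = records[~records["plot_id"].isin(flagged)].reset_index(drop=True)
    if out.empty and not records.empty:
        warnings.warn("all plots excluded by flags; empty record table", stacklevel=2)
    return out


def filter_rare_species(records: pd.DataFrame, min_plots: int = 250) -> pd.DataFrame:
    """Remove species occurring in fewer than ``min_plots`` distinct plots.

    Applied once, not iterated: plots emptied by the removal are dropped
    later when the IV matrix is built, and that removal does not feed back
    into the species counts.
    """
    _check_records(records)
    if min_plots < 1:
        raise ValueError("min_plots must be >= 1")
    n_plots = records.groupby("species_code")["plot_id"].nunique()
    keep = n_plots.index[n_plots >= min_plots]
    return records[records["species_code"].isin(keep)].reset_index(drop=True)


def compute_iv(records: pd.DataFrame) -> pd.DataFrame:
    """Plot x species relative importance values on the 0-100 scale.

    IV = 100 * (relative basal area + relative stem count) / 2 per plot.
    Rows (plots) and columns (species) are sorted lexicographically; every
    row sums to 100.  Plots with no surviving records are absent.
    """
    records = ensure_basal_area(records)
    if records.empty:
        raise ValueError("no records to compute importance values from")
    g = records.groupby(["plot_id", "species_code"], sort=True)
    ba = g["basal_area_m2"].sum().unstack(fill_value=0.0)
    n = g.size().unstack(fill_value=0).astype(float)
    ba_tot = ba.sum(axis=1)
    if (ba_tot <= 0).any():
        raise ValueError("plot with zero total basal area")
    iv = 100.0 * 0.5 * (ba.div(ba_tot, axis=0) + n.div(n.sum(axis=1), axis=0))
    iv = iv.loc[sorted(iv.index), sorted(iv.columns)]
    iv.index.name = "plot_id"
    iv.columns.name = "species"
    return iv


def preprocess_records(
    records: pd.DataFrame,
    rules=(),
    exclude_flags=DEFAULT_EXCLUDE_FLAGS,
    min_plots: int = 250,
) -> pd.DataFrame:
    """Full preprocessing chain: recode, filter plots, filter rare species, IV matrix."""
    r = apply_recoding(records, rules)
    r = filter_plots(r, exclude_flags)
    r = filter_rare_species(r, min_plots)
    return compute_iv(r)


# ---------------------------------------------------------------------------
# Tab-separated text I/O


def read_records(path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t", dtype={"plot_id": str, "species_code": str})
    _check_records(records)
    return records


def write_iv_matrix(iv: pd.DataFrame, path, species_path=None) -> None:
    iv.to_csv(path, sep="\t", index_label="plot_id", float_format="%.10g")
    if species_path is not None:
        with open(species_path, "w") as fh:
            fh.write("\n".join(map(str, iv.columns)) + "\n")


def read_iv_matrix(path) -> pd.DataFrame:
    iv = pd.read_csv(path, sep="\t", index_col="plot_id")
    iv.index = iv.index.astype(str)
    return iv.astype(float)
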