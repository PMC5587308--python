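"""Synthetic forest-inventory generator with planted assemblage structure.

Real national inventories are too large (and too access-restricted) to ship
with a method package, so every downstream stage here is exercised against
simulated inventories whose ground truth is known.  The generator plants
``n_templates`` latent assemblages.  Each template owns a species pool with
a few *indicator species* exclusive to it (high occupancy), plus species
shared with other templates.  Plots are drawn from a template: species
presence by per-species occupancy probabilities, basal-area shares as
normalized exponentials of Gaussian log-weights around the template's mean
shares (a skewed, Dirichlet-like dominance structure), stem counts
proportional to shares with a floor of one stem.  A ``mixing_prob`` lets a
plot borrow one species from a foreign template, blurring cluster borders.

Plot coordinates are uniform on the unit square; ``region_code`` is "west"
for x < 0.5 and "east" otherwise, which gives the regional species-split
rules something to bite on.  Smooth per-species trend surfaces (linear in
x, y) provide projected importance-value changes per climate scenario for
the impact stage.

All randomness flows from ``rng_seed``; identical configs reproduce
byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssemblageTemplate",
    "SyntheticConfig",
    "DeltaIVSurfaceConfig",
    "make_templates",
    "simulate_inventory",
    "make_delta_surface_config",
    "simulate_delta_iv",
    "write_records",
    "write_labels",
    "write_delta_iv",
]

RELIABILITY_GRADES = ("low", "medium", "high")


@dataclass(frozen=True)
class AssemblageTemplate:
    """A latent assemblage: species pool, occupancy, expected IV shares."""

    template_id: str
    species_pool: tuple
    occupancy_prob: tuple  # aligned with species_pool, each in [0, 1]
    mean_iv_share: tuple  # aligned, nonnegative, sums to 1
    indicator_species: tuple  # subset of species_pool, exclusive to this template

    def __post_init__(self):
        share = np.asarray(self.mean_iv_share, dtype=float)
        occ = np.asarray(self.occupancy_prob, dtype=float)
        if len(share) != len(self.species_pool) or len(occ) != len(self.species_pool):
            raise ValueError("occupancy_prob and mean_iv_share must align with species_pool")
        if abs(share.sum() - 1.0) > 1e-9 or (share < 0).any():
            raise ValueError("mean_iv_share must be nonnegative and sum to 1")
        if (occ < 0).any() or (occ > 1).any():
            raise ValueError("occupancy_prob must lie in [0, 1]")
        pool = dict(zip(self.species_pool, occ))
        for sp in self.indicator_species:
            if sp not in pool:
                raise ValueError(f"indicator species {sp!r} not in species_pool")
            if pool[sp] < 0.8:
                raise ValueError("indicator species must have occupancy_prob >= 0.8")


@dataclass(frozen=True)
class SyntheticConfig:
    n_templates: int = 4
    n_plots: int = 800
    n_species: int = 30
    richness_range: tuple = (1, 12)
    noise_sd: float = 0.6
    mixing_prob: float = 0.1
    separation: float = 0.7  # probability a non-indicator pool species is template-exclusive
    n_indicators: int = 1  # exclusive species per template
    pool_size_range: tuple = (5, 10)  # species per template pool (incl. indicators)
    mean_stems: float = 15.0  # expected stems per plot
    total_ba_log_mean: float = math.log(2.0)  # ~30 m^2/ha on a 0.067-ha plot
    total_ba_log_sd: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        lo, hi = self.richness_range
        if hi > self.n_species:
            # the richness ceiling can never exceed the species pool
            hi = self.n_species
            object.__setattr__(self, "richness_range", (lo, hi))
        if not (1 <= lo <= hi):
            raise ValueError("richness_range must lie within [1, n_species]")
        if not 0.0 <= self.mixing_prob <= 1.0:
            raise ValueError("mixing_prob must lie in [0, 1]")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _species_codes(n: int) -> list:
    return [f"SP{i:03d}" for i in range(1, n + 1)]


def make_templates(config: SyntheticConfig, rng=None) -> list:
    """Draw assemblage templates with disjoint indicator species.

    Indicator species get occupancy 0.9 and a boosted expected IV share;
    shared species are sampled from the non-indicator pool with moderate
    occupancies.  Needs ``n_species >= 2 * n_templates`` so pools are
    nondegenerate and the indicator sets fit disjointly.
    """
    if config.n_species < 2 * config.n_templates:
        raise ValueError("need n_species >= 2 * n_templates for disjoint indicator pools")
    if config.n_species < config.n_templates * config.n_indicators:
        raise ValueError("too few species for disjoint indicator sets")
    rng = np.random.default_rng([config.rng_seed, 1]) if rng is None else rng
    species = _species_codes(config.n_species)
    n_ind = config.n_templates * config.n_indicators
    order = rng.permutation(config.n_species)
    ind_order = order[:n_ind]
    rest = [species[i] for i in order[n_ind:]]
    # `separation` splits the non-indicator species between per-template
    # exclusive slices and a pool common to all templates
    n_exclusive = int(round(config.separation * len(rest)))
    n_exclusive -= n_exclusive % config.n_templates
    slice_len = n_exclusive // config.n_templates
    slices = [rest[t * slice_len : (t + 1) * slice_len] for t in range(config.n_templates)]
    common = rest[n_exclusive:]
    templates = []
    lo, hi = config.pool_size_range
    for t in range(config.n_templates):
        indicators = tuple(
            species[i] for i in ind_order[t * config.n_indicators : (t + 1) * config.n_indicators]
        )
        n_extra = int(rng.integers(lo, hi + 1)) - len(indicators)
        n_extra = max(1, n_extra)
        n_own = min(int(round(config.separation * n_extra)), len(slices[t]))
        own = list(rng.choice(slices[t], size=n_own, replace=False)) if n_own else []
        n_common = min(n_extra - n_own, len(common))
        borrowed = list(rng.choice(common, size=n_common, replace=False)) if n_common else []
        extra = tuple(own + borrowed)
        if not extra:
            raise ValueError("infeasible config: template pool would hold only indicators")
        pool = indicators + extra
        # indicators carry a guaranteed block of the expected IV mass (the
        # planted assemblages are "named after" their dominant indicator);
        # the rest is spread Dirichlet-flat over the shared species
        ind_mass = rng.uniform(0.35, 0.55)
        share = np.concatenate(
            [
                np.full(len(indicators), ind_mass / len(indicators)),
                (1.0 - ind_mass) * rng.dirichlet(np.ones(len(extra))),
            ]
        )
        # indicators are near-constant members of their assemblage; shared
        # species occur often but strictly less reliably, so the planted
        # indicator keeps the top fidelity of its template
        occ = np.concatenate(
            [np.full(len(indicators), 0.97), rng.uniform(0.6, 0.9, size=len(extra))]
        )
        templates.append(
            AssemblageTemplate(
                template_id=f"T{t + 1}",
                species_pool=pool,
                occupancy_prob=tuple(occ),
                mean_iv_share=tuple(share),
                indicator_species=indicators,
            )
        )
    return templates


def simulate_inventory(templates, config: SyntheticConfig, rng=None):
    """Simulate a per-stem tree record table from assemblage templates.

    Returns ``(records, labels)``: records with one row per stem
    (plot_id, species_code, dbh_cm, basal_area_m2, region_code, plot_flags,
    x, y) and labels mapping plot_id -> true template_id.
    """
    rng = np.random.default_rng([config.rng_seed, 2]) if rng is None else rng
    rmin, rmax = config.richness_range
    all_pools = [list(t.species_pool) for t in templates]
    rows = []
    labels = []
    for p in range(config.n_plots):
        plot_id = f"P{p + 1:05d}"
        t_idx = int(rng.integers(len(templates)))
        tpl = templates[t_idx]
        pool = np.asarray(tpl.species_pool, dtype=object)
        occ = np.asarray(tpl.occupancy_prob, dtype=float)
        share = np.asarray(tpl.mean_iv_share, dtype=float)

        present = rng.random(len(pool)) < occ
        if not present.any():
            present[int(np.argmax(share))] = True
        sp = list(pool[present])
        wt = list(share[present])

        if len(templates) > 1 and rng.random() < config.mixing_prob:
            foreign_t = int(rng.choice([i for i in range(len(templates)) if i != t_idx]))
            cand = [s for s in all_pools[foreign_t] if s not in sp]
            if cand:
                j = int(rng.integers(len(cand)))
                borrowed = cand[j]
                ft = templates[foreign_t]
                sp.append(borrowed)
                wt.append(ft.mean_iv_share[ft.species_pool.index(borrowed)])

        # clamp richness into the configured range
        if len(sp) > rmax:
            order = np.argsort(wt)[::-1][:rmax]
            sp = [sp[i] for i in order]
            wt = [wt[i] for i in order]
        if len(sp) < rmin:
            absent = [
                (s, w) for s, w in zip(pool, share) if s not in sp
            ]
            absent.sort(key=lambda x: -x[1])
            for s, w in absent[: rmin - len(sp)]:
                sp.append(s)
                wt.append(w)

        wt = np.asarray(wt, dtype=float)
        wt = np.where(wt > 0, wt, wt[wt > 0].min() if (wt > 0).any() else 1.0)
        logw = np.log(wt) + config.noise_sd * rng.standard_normal(len(wt))
        shares = np.exp(logw - logw.max())
        shares /= shares.sum()

        total_stems = max(
            len(sp), int(rng.poisson(config.mean_stems))
        )
        stems = np.maximum(1, np.round(shares * total_stems).astype(int))
        total_ba = float(
            np.exp(config.total_ba_log_mean + config.total_ba_log_sd * rng.standard_normal())
        )
        ba_sp = shares * total_ba

        x, y = rng.random(), rng.random()
        region = "west" if x < 0.5 else "east"
        for s, c, ba in zip(sp, stems, ba_sp):
            per_stem = ba / c
            dbh = 200.0 * math.sqrt(per_stem / math.pi)
            for _ in range(int(c)):
                rows.append((plot_id, s, dbh, per_stem, region, "", x, y))
        labels.append((plot_id, tpl.template_id))

    records = pd.DataFrame(
        rows,
        columns=[
            "plot_id",
            "species_code",
            "dbh_cm",
            "basal_area_m2",
            "region_code",
            "plot_flags",
            "x",
            "y",
        ],
    )
    label_df = pd.DataFrame(labels, columns=["plot_id", "template_id"])
    return records, label_df


@dataclass(frozen=True)
class DeltaIVSurfaceConfig:
    """Per-species linear trend surfaces for projected IV change.

    ``trend_coefficients[(species, scenario)] = (a, b, c)`` gives
    delta_iv(x, y) = a + b*x + c*y; ``reliability[(species, scenario)]``
    grades the projection low/medium/high.
    """

    scenarios: tuple
    trend_coefficients: dict = field(default_factory=dict)
    reliability: dict = field(default_factory=dict)

    def species(self):
        return sorted({s for s, _ in self.trend_coefficients})

    def validate_against(self, species) -> None:
        for s in species:
            for scen in self.scenarios:
                if (s, scen) not in self.trend_coefficients:
                    raise ValueError(f"no trend for species {s!r} under {scen!r}")
                if self.reliability.get((s, scen)) not in RELIABILITY_GRADES:
                    raise ValueError(f"no reliability grade for {s!r} under {scen!r}")


def make_delta_surface_config(
    species,
    scenarios=("PCM_Low", "Hadley_High"),
    delta_scale: float = 5.0,
    reliability_weights=(0.15, 0.35, 0.5),
    rng_seed: int = 0,
    rng=None,
) -> DeltaIVSurfaceConfig:
    """Random smooth surfaces: intercept and x/y slopes ~ N(0, delta_scale)."""
    rng = np.random.default_rng([rng_seed, 3]) if rng is None else rng
    trends, grades = {}, {}
    for s in species:
        for scen in scenarios:
            trends[(s, scen)] = tuple(delta_scale * rng.standard_normal(3))
            grades[(s, scen)] = str(rng.choice(RELIABILITY_GRADES, p=reliability_weights))
    return DeltaIVSurfaceConfig(
        scenarios=tuple(scenarios), trend_coefficients=trends, reliability=grades
    )


def simulate_delta_iv(records: pd.DataFrame, surface_config: DeltaIVSurfaceConfig) -> pd.DataFrame:
    """Evaluate the trend surfaces at every plot: one row per (plot, species, scenario)."""
    if "x" not in records.columns or "y" not in records.columns:
        raise ValueError("records must carry x, y plot coordinates")
    plots = records[["plot_id", "x", "y"]].drop_duplicates("plot_id").sort_values("plot_id")
    if plots[["x", "y"]].isna().any().any():
        raise ValueError("missing plot coordinates")
    species = sorted(records["species_code"].unique())
    surface_config.validate_against(species)
    out = []
    for scen in surface_config.scenarios:
        for s in species:
            a, b, c = surface_config.trend_coefficients[(s, scen)]
            grade = surface_config.reliability[(s, scen)]
            delta = a + b * plots["x"].to_numpy() + c * plots["y"].to_numpy()
            out.append(
                pd.DataFrame(
                    {
                        "plot_id": plots["plot_id"].to_numpy(),
                        "species": s,
                        "scenario": scen,
                        "delta_iv": delta,
                        "reliability": grade,
                        "x": plots["x"].to_numpy(),
                        "y": plots["y"].to_numpy(),
                    }
                )
            )
    delta = pd.concat(out, ignore_index=True)
    if not np.isfinite(delta["delta_iv"]).all():
        raise ValueError("non-finite delta_iv values generated")
    return delta


# ---------------------------------------------------------------------------
# Tab-separated text writers

_FLOAT_FMT = "%.10g"


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def write_delta_iv(delta: pd.DataFrame, path) -> None:
    delta.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
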