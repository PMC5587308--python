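import numpy as np
import pandas as pd
import pytest

import assemblage as asm
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted():
    """Low-noise four-assemblage inventory: (config, records, labels, iv)."""
    cfg = asm.SyntheticConfig(
        n_templates=4,
        n_plots=800,
        n_species=30,
        noise_sd=0.15,
        mixing_prob=0.02,
        rng_seed=11,
    )
    templates = asm.make_templates(cfg)
    records, labels = asm.simulate_inventory(templates, cfg)
    iv = asm.preprocess_records(records, min_plots=1)
    return cfg, records, labels, iv


@pytest.fixture(scope="session")
def planted_model(planted):
    _, _, _, iv = planted
    return asm.SeededAssemblageClustering(random_state=1).fit(iv)


@pytest.fixture()
def toy_records():
    """Five plots, hand-sized; plot P4/P5 flagged."""
    return pd.DataFrame(
        {
            "plot_id": ["P1", "P1", "P2", "P3", "P3", "P4", "P5"],
            "species_code": ["A", "B", "A", "B", "C", "A", "C"],
            "basal_area_m2": [0.8, 0.2, 1.0, 0.3, 0.3, 0.5, 0.2],
            "region_code": ["west", "west", "east", "east", "east", "west", "east"],
            "plot_flags": ["", "", "", "", "", "nonstocked", "nonstocked"],
        }
    )


def brute_force_indval(X, labels):
    """Independent IndVal oracle: explicit loops over clusters and species."""
    X = np.asarray(X, dtype=float)
    labs = np.asarray(labels)
    clusters = sorted(set(labs.tolist()))
    n_species = X.shape[1]
    iv = np.zeros(n_species)
    best = [None] * n_species
    for s in range(n_species):
        means = []
        for c in clusters:
            rows = X[labs == c, s]
            means.append(rows.mean())
        tot = sum(means)
        vals = []
        for ci, c in enumerate(clusters):
            rows = X[labs == c, s]
            A = means[ci] / tot if tot > 0 else 0.0
            B = np.mean(rows > 0)
            vals.append(A * B)
        j = int(np.argmax(vals))
        iv[s] = vals[j]
        best[s] = clusters[j]
    return iv, best
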