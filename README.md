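# assemblage

Empirical, hierarchical typologies of tree species assemblages from
forest-inventory plots.

Forest communities are usually classified top-down (expert forest types) or
species-by-species (range maps), but neither captures how species actually
co-occur and share dominance on the ground. `assemblage` builds a
data-driven classification directly from plot records — the species and
basal area of every stem — and carries it through to a screening-level
assessment of how projected species-level changes aggregate at the
community level. It is aimed at vegetation and community ecologists working
with large plot networks (national forest inventories, or any site ×
species abundance data).

## The method

1. **Importance values.** For each plot, every species gets a relative
   importance value
   `IV = 100 · (BA_s / ΣBA + N_s / ΣN) / 2`
   — the mean of its relative basal area and relative stem count — so each
   plot's IVs sum to 100. Species recoding rules (merging varieties,
   dropping generic labels, regional splits) and filters (flagged plots,
   species present in fewer than 250 plots) are applied first.
2. **Seeded hierarchical clustering.** A plot × plot dissimilarity matrix
   for 10⁵ plots is far beyond memory, so k-means with a large k (default
   `min(20 000, ⌈n/6⌉)`) first collapses near-identical plots into seeds.
   Bray-Curtis dissimilarity `d(u,v) = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ)` between seed
   centroids then feeds a **size-weighted UPGMA**: the Lance–Williams
   update `d(i∪j, m) = (nᵢ d(i,m) + nⱼ d(j,m)) / (nᵢ + nⱼ)` with leaf
   weights equal to seed plot counts, which reproduces plain plot-level
   UPGMA exactly when seeds are pure duplicates.
3. **Typology selection.** The dendrogram is cut at every level k in a
   scan range and Dufrêne–Legendre indicator species analysis is run at
   each: `IndVal_s = max_j A_sj · B_sj` with specificity A (concentration
   of the species' mean IV in cluster j) and fidelity B (fraction of the
   cluster's plots containing it), significance by permutation of plot
   labels. Candidate typologies must have at least one significant
   indicator per cluster; among those, four indices — sum of significant
   indicator values, number of significant indicator species, mean
   significant p-value, and mean (size-weighted) silhouette width — flag
   global and local optima without being combined into one score.
4. **Dominance.** Within each cluster every species gets a dominance index
   `SDI = (MC + MSS + THC)/3`: mean relative IV over all plots of the
   cluster, mean inverse richness where it occurs, and its tendency toward
   high cover (> 25% relative IV and the plot maximum). Dominant species
   are those at or above a pooled percentile cutoff (default 90th).
5. **Impact aggregation.** Given projected per-species changes in IV (ΔIV)
   under climate scenarios, eligible clusters (≥ 100 plots, all dominant
   species projected, majority at ≥ medium reliability) get an
   SDI-weighted mean ΔIV of their dominant species — a screening statistic
   for where community-level impacts are likely.

A synthetic-inventory generator plants known assemblage templates
(exclusive indicator species, skewed IV shares, configurable noise, mixing
and separation) plus smooth ΔIV trend surfaces, so the whole pipeline is
testable against ground truth without any inventory download.

## Worked example

```python
import assemblage as asm

cfg = asm.SyntheticConfig(n_templates=4, n_plots=800, n_species=30,
                          noise_sd=0.15, mixing_prob=0.02, rng_seed=11)
templates = asm.make_templates(cfg)
records, labels = asm.simulate_inventory(templates, cfg)
iv = asm.preprocess_records(records, min_plots=1)

model = asm.SeededAssemblageClustering(random_state=1).fit(iv)
scan = asm.scan_hierarchy(iv, model.dendrogram_, model.seed_set_,
                          asm.SelectionConfig(n_perm=999, k_range=(2, 8), rng_seed=5))
print(scan.round(3).to_string())
best_k = int(asm.select_optima(scan).index[0])

membership = model.cut(best_k)
sdi = asm.compute_sdi(iv, membership)
table, cutoff = asm.dominant_species(sdi, percentile=90)
```

prints

```
   sum_sig_indval  n_sig_species  mean_sig_p  mean_silhouette  all_clusters_covered
k
2          10.870             26       0.001            0.414                  True
3          15.873             27       0.001            0.586                  True
4          20.385             27       0.001            0.760                  True
5          20.238             27       0.005            0.749                  True
6          18.658             27       0.008            0.734                  True
7          18.443             27       0.009            0.720                  True
8          17.628             27       0.008            0.696                  True
```

The scan is eligible everywhere (every cluster has a significant
indicator), and k = 4 — the number of planted assemblages — maximizes the
sum of significant indicator values and the silhouette while minimizing the
mean significant p-value, so `select_optima` ranks it first. The dominant
species at the 90th-percentile SDI cutoff (0.277 here) are the planted
template indicators: e.g. `SP009` (SDI 0.52) dominates cluster 1 and
`SP002` (0.57) cluster 3.

The same study runs from the shell:

```bash
assemblage pipeline --config config.yaml --out-dir run/
```

with the stage commands (`simulate`, `preprocess`, `cluster`, `diagnose`,
`dominance`, `impact`) available individually; all outputs are
tab-separated text plus a Newick dendrogram.

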