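# Methods

## Importance values

The analysis matrix is plots × species with relative importance values

    IV[p, s] = 100 · ( BA_s/ΣBA + N_s/ΣN ) / 2

where BA is summed stem basal area and N is the stem count of species s in
plot p. "Abundance" is the per-plot stem count — the input records one row
per stem — so IV mixes a size-weighted and a count-weighted share; rows sum
to 100 by construction. Basal area is taken from the records when present
and otherwise derived from diameter at breast height as π(dbh/200)² m².
IVs are scale-invariant within a plot: multiplying all basal areas of a
plot by a constant changes nothing.

Preprocessing order is fixed: species recoding (merges of varieties, drops
of generic labels, regional splits on a plain region-code column — no GIS
logic), removal of flagged plots (non-stocked, nonnative types), then a
single pass of the rare-species filter (default: species in fewer than 250
distinct plots are removed). The filter is deliberately not iterated:
plots left with no species are dropped when the IV matrix is built, but
that removal does not feed back into the species occurrence counts. Plot
and species orderings are lexicographic, so the matrix is reproducible
byte for byte.

## Seeded weighted clustering

Hierarchical clustering of n plots needs an O(n²) dissimilarity matrix,
which is infeasible at inventory scale (~1.3 × 10⁵ plots). The pipeline
therefore clusters in two stages:

1. **Seeding.** Euclidean Lloyd k-means on the IV rows, best of 5 restarts
   by within-cluster sum of squares, at most 100 iterations, with
   k = min(20 000, ⌈n/6⌉) by default (capped at the number of distinct
   rows). Inventory data contain many plots with identical or
   near-identical IVs (single-species plots especially), so large-k
   k-means mostly groups duplicates. Centroids are recomputed as exact
   means of the final assignment so every seed satisfies the
   centroid-equals-member-mean invariant regardless of convergence. Note
   the seeding metric (Euclidean) deliberately differs from the
   dissimilarity used downstream (Bray-Curtis); the seeds are a
   memory-reduction device, not a classification.
2. **Size-weighted UPGMA.** Bray-Curtis dissimilarity between seed
   centroids, then average-linkage agglomeration with the Lance–Williams
   update d(i∪j, m) = (nᵢ d(i,m) + nⱼ d(j,m)) / (nᵢ + nⱼ), where leaf
   weights are seed plot counts. When seeds are exact duplicate groups
   this reproduces plot-level UPGMA merge heights exactly (tested to
   1e-9 against brute-force expansion); otherwise it is the natural
   approximation. Ties in the minimum dissimilarity are broken by the
   smallest active index pair, so dendrograms are identical across reruns.
   The agglomeration refuses more than 30 000 leaves — beyond that the
   dense matrix is the very problem seeding exists to solve — with a
   message to increase the seeding.

Cutting the dendrogram at level k and mapping seeds back to plots yields
the plot-level typology; cluster ids 1..k are assigned by each cluster's
smallest leaf index (a stable rule). Memberships are nested across k by
construction. Dendrograms export to Newick with ultrametric branch lengths
(leaf depth below a node = node height / 2).

## Indicator species analysis and typology selection

For a cut with clusters j = 1..k, each species s gets specificity
A_sj = mean-IV share of cluster j among cluster means, fidelity
B_sj = occurrence fraction within j, and IndVal_s = max_j A_sj·B_sj on the
0–1 scale. Significance is a permutation test of plot labels:
p = (1 + #{IndVal* ≥ IndVal}) / (n_perm + 1), add-one corrected, default
n_perm = 999, so the smallest attainable p is 1/1000. Exceedance uses a
1e-12 slack so exact ties (a species constant across plots) count as
exceedances — marginally conservative, never anti-conservative.
Permutations act on plot labels (not seed labels) so inference is at the
plot level even though the clustering was seeded.

The hierarchy scan (default cut levels 2–200) computes per level: the sum
of significant indicator values, the number of significant indicator
species (each species counted once, at its best cluster), the mean of
significant p-values (missing if none), the size-weighted mean silhouette,
and whether every cluster has at least one significant indicator. The
significance level alpha defaults to 0.05. Each level uses an independent
RNG stream derived from (seed, k), so a row does not depend on the scanned
range.

Silhouettes are computed at the seed level with plot-count weights:
treating a seed as n coincident plots, a(i) = Σ_{j∈own} nⱼ d(i,j) / (N_own − 1)
and b(i) is the minimum size-weighted mean distance to another cluster;
seeds alone in their cluster with n = 1 score 0. With unit sizes this is
the classical silhouette (tested against scikit-learn), and for pure
duplicate seeds it equals the plot-level silhouette exactly. Plot-level
silhouette on 10⁵ plots would need the very matrix seeding avoids, which
is why the seed-level form is the default.

Typology selection first restricts to levels where every cluster is
covered by a significant indicator, then flags, per index, the global best
and the local optima (strictly better than both neighbouring eligible
levels; an edge level is compared to its single neighbour). The four
indices are deliberately not combined into a scalar; `select_optima`
returns all flags ranked by how many indices support each level, for
inspection.

## Species dominance index

Within each cluster, SDI = (MC + MSS + THC)/3 per species, with IVs
rescaled to 0–1:

- **MC** — mean relative IV over *all* plots of the cluster (absences count
  as zeros). The natural alternative (denominator = all plots in the
  study) is exposed as `mc_denominator="all"`, but within-cluster is the
  default since SDI is a within-cluster summary.
- **MSS** — mean of 1/richness over the plots where the species occurs
  (1 iff it always occurs alone).
- **THC** — fraction of occurrence plots where the species has strictly
  more than 25% relative IV *and* at least as much as every other species;
  ties count as "most cover" (co-dominance qualifies), the 25% threshold
  is strict.

Records are emitted only for (species, cluster) pairs where the species
occurs. Dominant species are records with SDI at or above a percentile of
the pooled SDI values across all (species, cluster) records — pooled, not
per cluster, so one global cutoff applies; the percentile uses linear
interpolation between order statistics (numpy's default). Default 90th,
with 85th/95th as standard sensitivity settings; raising the percentile
can only shrink the dominant sets. Ties at the cutoff are included (≥).

## Impact aggregation

Projected per-(plot, species, scenario) IV changes with reliability grades
are consumed as data. A (cluster, scenario) is eligible when the cluster
has at least `min_plots` (default 100) plots, every dominant species has a
projection at every plot of the cluster, and strictly more than half of
the dominant species carry at least medium reliability. Partially
projected clusters fail eligibility rather than being silently averaged.

For eligible clusters,

    impact = Σ_p Σ_s SDI_s · Δ_{p,s} / (n_plots · Σ_s SDI_s)

a convex combination of the observed ΔIV values (so it respects their
range and scales linearly). Per-plot impact is the unweighted mean over
dominant species, for mapping spatial pattern; with equal SDIs its plot
average equals the cluster impact. When a `current_iv` baseline column is
supplied, a percent change is also reported relative to the SDI-weighted
mean current IV over the cluster's plots — the baseline convention is a
choice, so the raw ΔIV scale is always emitted alongside.

## Synthetic inventory generator

The generator plants `n_templates` latent assemblages over `n_species`
codes. Defaults (4 templates, 800 plots, 30 species, richness 1–12,
noise_sd 0.6, mixing_prob 0.1, separation 0.7) describe a moderate-noise
regional study; the sizes keep a full pipeline run in seconds while
leaving ~200 plots per assemblage, enough for stable indicator statistics.

- Each template owns `n_indicators` exclusive indicator species (occupancy
  0.97, a guaranteed 35–55% block of expected IV share split among them):
  assemblages are "named after" their dominant indicators, and the
  guaranteed mass keeps every planted template distinguishable — a purely
  Dirichlet-drawn profile occasionally produces a template without any
  distinctive species, which defeats a planted ground truth.
- `separation` sets the fraction of the remaining pool species drawn from
  a template-exclusive slice versus a pool common to all templates;
  shared species get occupancy U(0.6, 0.9) — characteristic but strictly
  less faithful than indicators — and the residual Dirichlet-flat share
  mass. Rare visitors are modelled by `mixing_prob`: a plot borrows one
  species from a foreign template with that probability.
- Per plot: present species are occupancy draws clamped into
  `richness_range`; basal-area shares are normalized exponentials of
  Gaussian perturbations (sd `noise_sd`) of log mean shares — a skewed,
  Dirichlet-like dominance structure; stem counts are proportional to
  shares (Poisson total, floor of one stem); total plot basal area is
  log-normal around 2 m² (≈ 30 m²/ha on a 0.067-ha plot). Coordinates are
  uniform on the unit square with `region_code` split at x = 0.5.
- ΔIV surfaces are linear trends a + b·x + c·y per (species, scenario)
  with per-species reliability grades; the defaults draw coefficients
  N(0, 5 IV units) — comparable to end-of-century projected IV shifts for
  sensitive species.

All randomness flows from `rng_seed` through named substreams
(templates / inventory / surfaces), so identical configs give byte-identical
tables.

What the generator does *not* emulate: real inventory sampling designs
(subplot geometry, systematic grids), spatial autocorrelation of community
composition (plots are exchangeable within a template), species abundance
distributions with many genuinely rare species, measurement error in
species identification, or non-linear climate response surfaces. Passing
recovery tests therefore show the pipeline recovers planted, exchangeable
mixture structure — not that any particular real inventory has such
structure.

## Verification design and problem sizes

The test suite checks every stage against an independent route: weighted
UPGMA against scipy's plain UPGMA on brute-force-expanded duplicate
matrices (200 plots); IndVal and its permutation p against a loop-written
oracle and exhaustive enumeration of all distinct label arrangements
(≤ 8 plots); the weighted silhouette against scikit-learn's at unit
weights and against plot-level expansion for duplicate seeds; Newick
export against an independent parser (dendropy). Null calibration of the
permutation test uses a 400-plot, 50-species inventory with template
labels destroyed by shuffling; the realized false-positive fraction at
alpha 0.05 is pooled over five independent shuffles because p-values of
co-occurring species are strongly positively correlated (they share the
community structure and the permutation stream), making a single-shuffle
fraction too noisy to be informative at this scale. Planted-typology
recovery uses 4 templates × 800 plots at noise_sd 0.15, mixing 0.02 — a
low-noise regime where the true k should be decisively recoverable —
with 999 permutations over cut levels 2–8.

## Known limitations

- Lloyd k-means offers no global optimum; different seeds give different
  seed sets (the hierarchy built on them is deterministic given the
  seeds). With k far below the number of distinct rows the weighted UPGMA
  is an approximation to plot-level UPGMA, exact only for duplicate seeds.
- The agglomeration is the naive O(n³) full-matrix algorithm — simple and
  exactly tie-stable, appropriate up to the 30 000-leaf guard but far from
  scipy's optimized nearest-neighbor-chain for big inputs.
- No multiple-testing correction is applied across species in the
  indicator analysis; "number of significant indicators" is a descriptive
  selection index, not a family-wise inference.
- Percent impact depends on an externally supplied current-IV baseline;
  without one, only raw ΔIV is reported.
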