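# Methods

## The composition graph

Let `X` be a samples×taxa matrix of non-negative read counts. The
composition graph has one node per sample and per taxon and one directed
edge `s → t` for every strictly positive cell, with

* `weight_absolute = X[s,t]`
* `weight_relative = X[s,t] / Σ_t X[s,t]` (within-sample).

The direction convention reserves `source` for samples and `target` for
taxa. Because zero cells produce no edge, all-zero rows/columns would
become isolated nodes with undefined relative weights; they are dropped
before construction with a logged warning. Relative abundance appears in
two distinct senses and both are kept deliberately separate: the
*edge* weight is row-relative (it answers "how much of this sample is
this taxon", which is what the hover highlight displays), while the
*taxon node* attribute `total_relative_abundance` is the column sum over
the table grand total (what the sequential color ramp displays).

Node attributes computed at build time: per taxon, `prevalence` (number
of samples with a positive cell) and `total_relative_abundance`; per
sample, Chao1, Shannon, and Inverse-Simpson, plus any metadata columns.
The graph is held in a `networkx.DiGraph` and serialises to JSON
node-link or GraphML; both roundtrip exactly (numbers use shortest
round-trippable decimals).

## Diversity conventions

Named diversity indices are ambiguous without stated conventions; the
ones used here are:

| metric | definition | range |
|---|---|---|
| Shannon | `H = −Σ p ln p`, natural log (nats) | `[0, ln S_obs]` |
| Inverse-Simpson | `1 / Σ p²` | `[1, S_obs]` |
| Chao1 | `S_obs + F1²/(2F2)`; if `F2 = 0`, bias-corrected `S_obs + F1(F1−1)/2` | `≥ S_obs` |
| Bray-Curtis | `Σ|x−y| / Σ(x+y)` | `[0, 1]` |
| Jaccard | binary, `1 − |A∩B|/|A∪B|` over supports (not abundance-weighted Ružička) | `[0, 1]` |
| Jensen-Shannon | divergence (not its square root), natural log, on row-normalised proportions | `[0, ln 2]` |

All six are validated against an independently coded brute-force
implementation and (where applicable) against scipy/scikit-bio. The
entropy bound asserted is the direct one, `shannon ≤ ln(S_obs)`; no
relation between Shannon and the Chao1 *estimate* is assumed.

## Layout

The simulation follows the cooled, velocity-damped contract of the
familiar web force engines. Per tick:

1. `alpha ← alpha + (0 − alpha)·alpha_decay_rate` (geometric cooling);
2. each force adds velocity increments scaled by `alpha`:
   * repulsion between all pairs, magnitude `|k_r|/d` along the
     separating direction (`d` clamped below by 1 px; coincident pairs
     split by a seeded sub-pixel jitter);
   * a spring per edge toward `link_distance`, applied half to each
     endpoint, using lookahead positions `p + v`. Springs are
     unweighted by default (edge weights carry no agreed visual
     semantics in the layout); `weight_scaled_links=True` multiplies
     each spring by its edge's `weight_relative`;
   * radial: increment `(r_target − |p − c|)·k_rad` along the radial
     direction. `r_target = R_s` for samples;
     `r_target = r_max·(n−k)/(n−1)` for a taxon of prevalence `k`
     (linear in `k`; `k = n → 0`, `k = 1 → r_max`); the intended
     geometry — samples on a ring, core microbiome at the center —
     follows directly. A rank-based alternative
     (`radial_mapping="rank"`, distinct prevalence values spaced
     evenly) is available for tables whose prevalences bunch up;
   * group separation: `vx += (x_g − x)·k_g` toward the group's target
     x (and y when three or more groups use 2-D polygon targets).
     Default targets: two groups at `∓0.75·R_s`; `≥3` groups at the
     vertices of a regular polygon of that radius;
   * centering: a rigid translation keeping the mean position at the
     configured center (not alpha-scaled, so it is exactly rigid);
3. `v ← v·(1 − velocity_decay)`; `p ← p + v`.

Defaults: `alpha_initial = 1`, `alpha_min = 0.001`,
`alpha_decay_rate = 1 − 0.001^(1/300)` (~300 ticks), `velocity_decay =
0.4`, `repulsion = −30`, `link_distance = 30 px`, `link_strength = 0.1`,
`radial_strength = 0.8`, `R_s = 250 px`, `r_max = 200 px`,
`group_strength = 0.25`. The radial and group strengths are set high
relative to the link springs because the design intent is that the
radial/cohort geometry dominates the final picture; all are
configurable. Repulsion is exact (O(n²)) up to 2,000 nodes and switches
to a Barnes–Hut quadtree above (opening angle `theta = 0.9`,
parameterised); the method targets small curated subsets, so the exact
path is the norm.

Determinism: initial positions are drawn from a seeded uniform disk;
every other step is deterministic, so identical (graph, config) give
bit-identical trajectories. The update is equivariant under reflection
and under translation of the center (verified by property tests).

## Color

* Categorical: ≤ 12 classes, evenly spaced hues at fixed
  saturation/lightness; the class→hue map depends only on the sorted
  class set. More than 12 classes raises and points to small multiples.
* Saturation scale: min-max normalised value → saturation in
  `[0.12, 1]` at a fixed hue (default 210°) and lightness 0.5. Constant
  inputs collapse to mid saturation with a warning.
* Binned multi-hue: equal-width integer bins (domains smaller than the
  bin count collapse to distinct values), steps sampled from a
  perceptually ordered ramp (default viridis; configurable). Bin edges
  are reported for the legend.
* MDS→CIELAB: classical (Torgerson) scaling of the distance matrix —
  double-center `−½D²`, eigendecompose, keep the top-3 non-negative
  eigenpairs scaled by `√λ`, fix each axis's sign so its
  largest-magnitude loading is positive. Axis 1 (most variance) drives
  L* in `[30, 85]` (the most salient channel); axes 2–3 drive a*, b* in
  `[−60, 60]`, each min-max scaled. An axis whose spread is below 10⁻⁶
  of the dominant axis's spread carries only eigendecomposition noise
  and is collapsed to the channel midpoint — this also makes a fully
  degenerate (all-zero) matrix render as uniform mid-grey. Lab→sRGB uses
  D65/2° through an explicit linear-RGB stage so out-of-gamut colors are
  detected, counted in a warning, and clamped. In-gamut roundtrip error
  is at numerical precision (ΔE ≪ 0.01); quantisation to 8-bit hex adds
  at most ~0.7 ΔE.
* Highlight: the focal node's neighbors are colored by a saturation
  scale over their connecting edges' `weight_relative` (for both sample
  and taxon focal nodes — the symmetric row-relative choice); all other
  nodes fade to opacity 0.15. Taxonomy highlight paints matching taxa
  red (`#e41a1c`), keeps linked samples at full opacity, fades the rest;
  the unassigned-rank sentinel (empty string) never matches a query.

## Matrix view

Rows are seriated by hierarchical clustering of the sample beta-diversity
matrix (default Bray-Curtis, average linkage), columns by binary Jaccard
on column presence profiles (a correlation option exists); leaf orders
are refined by optimal leaf ordering, which minimises the summed
adjacent-leaf distance. Defaults were chosen as the least surprising for
compositional data; the distance/linkage used by any particular upstream
tool is not normative. Cells are drawn only for positive entries, with a
fixed fill (`presence`) or saturation by row-relative weight
(`relative_abundance`); the barcode strip encodes
`prevalence/n_samples` as darkness; the brush takes a half-open range of
*ordered* columns and returns a sub-table with original identifiers.

## Synthetic cohorts

The generator plants the structure the visualization is meant to expose:
`n_core` taxa in every sample, `n_group_shared` taxa per group present
only in that group's samples (groups assigned round-robin), and
`n_unique_per_sample` taxa per sample. Within a sample, eligible taxa
get i.i.d. log-normal weights (`μ = 0`, `σ = 1` by default — a typical
heavy-tailed rank-abundance profile); counts are a floor of 1 read per
eligible taxon plus a multinomial draw of the remaining depth. Row sums
therefore equal `depth` exactly and planted prevalences are exact, at
the cost of slightly flattening the log-normal tail at low depth.
Defaults (10 samples, 2 groups, 15 core + 10 group-shared + 5 unique per
sample, depth 10,000) mirror a small 16S cohort subset.

Not emulated: sequencing error/chimeras, biological overdispersion,
phylogenetic correlation, compositional cross-group leakage. Passing
tests on these tables demonstrate the *mechanics* (lossless transform,
force behaviour, encoding contracts) — not robustness to real-data noise.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the scale the method is
designed for: tables up to 50×500 for fidelity checks, 10-sample cohorts
(~85–210 nodes) for layout and seriation, 40 seeds for the statistical
rates. Distance matrices assert symmetry to 1e-12 and an exactly zero
diagonal; per-sample relative weights sum to 1 within 1e-9; MDS
roundtrips on Euclidean inputs hold to 1e-8. Seriation ties break by
index order inside scipy's linkage, making all orders deterministic.

## Known limitations

* The layout is a heuristic optimisation: geometric distance between
  unlinked nodes is not a calibrated similarity measure.
* The MDS→CIELAB map scales axes independently, so ΔE is monotone in
  embedding distance per axis but not exactly proportional overall;
  gamut clamping can further compress extremes (collisions are logged).
* Binary Jaccard ignores abundance; Jensen-Shannon is reported in nats —
  comparisons against base-2 implementations need a `ln 2` factor.
* Static SVG only: hover/brush states are computed as data, the
  interactive wiring belongs to a front-end.
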