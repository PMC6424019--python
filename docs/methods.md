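# Methods

## Silhouette geometry

A silhouette is the 2D outline of one primary olfactory lamella with its
secondary folds, sectioned near the raphe level. It is held both as a binary
raster (foreground = tissue) and as a simple, counter-clockwise polygon in mm.
Ingestion normalizes either representation:

- **Raster → polygon.** Marching squares at the 0.5 level on the padded mask,
  followed by polygon simplification with tolerance 1 px. The simplification
  matters: an unsimplified pixel-staircase boundary inflates the perimeter by
  up to ~40%, which biases the amplitude of vibration upward for every shape.
  Masks must contain exactly one foreground component; interior holes
  (detached epithelium in sections) are filled with a warning, since the
  indexes concern the outer epithelial boundary only.
- **Convention.** Pixel centres at integer coordinates, y increasing downward
  in rasters, physical scale in mm/px; polygons are stored CCW with implicit
  closure.

**Convex hull.** Boundary lengths and areas of the silhouette and its hull
come from the polygon representation (shapely), so the invariants
`P_h ≤ P_s` and `A_s ≤ A_h` hold exactly on polygon input, with equality
precisely for convex shapes.

**Skeleton.** Topology-preserving thinning of the mask (8-connectivity),
then a graph with endpoints (1 skeleton neighbour) and junctions (≥3
neighbours) as nodes; 8-adjacent junction pixels are merged into one node.
The branch count is the number of node-to-node edges. Spur edges shorter
than 3 px (configurable) are pruned iteratively: unpruned rasterization
spurs double-count as secondary-fold branches. An isolated cycle counts as
one branch.

**Corners.** Corner detection runs on the polygon with a turning-angle
criterion: a vertex is a corner when the boundary direction changes by more
than 30° (configurable) there, and it is a *notch* when the interior angle
exceeds 180°. Raster-traced boundaries are first Gaussian-smoothed along the
vertex chain (σ = 2, configurable) to control sensitivity; exact polygon
inputs are used as-is. A raster corner-response detector would only localize
corners, not give interior angles, which the classification needs; the
original workflow also finished its corner counts manually, so the exact
per-specimen counts are not recoverable anyway and the polygon criterion is
the reproducible choice.

## Complexity indexes

With `ν = n_notches/(n_vertices − 3)`:

```
F = 16(ν − ½)⁴ − 8(ν − ½)² + 1          frequency of vibration
A = (P_s − P_h)/P_s                      amplitude of vibration
D = (A_h − A_s)/A_h                      deviation from the convex hull
B = 0.8·A·F + 0.2·D                      Brinkhoff index
I_br = n_branches / n_secondary_folds    branching index
```

`F` is the quartic `(4(ν−½)² − 1)²` restricted to [0, 1] on ν ∈ [0, 1]: zero
at ν ∈ {0, 1}, one at ν = ½, symmetric about ½. Detected corner sets can
yield ν > 1 (more notches than `n_v − 3`), which cannot happen in the
polygonal-GIS setting the formula assumes; the value is still computed and a
warning raised. Corner sets with fewer than 4 corners (near-circular convex
shapes) leave `F` undefined; the composite is then reported with the
vibration term set to 0, which is exact in the convex limit where `A = 0`.
`n_vertices` counts notches among the vertices (notches are a subset), and
all reported values are rounded half-up to 2 decimals only at report time.

`n_secondary_folds` comes from annotation or from the synthetic generator's
ground truth. A skeleton-endpoint estimator is provided
(`count_folds_from_skeleton`) but is labelled an extension — it is rough for
branched folds.

**Branching classes.** The three fold morphologies — unbranched, a few
branches, highly branched — sit near index values 2, 3–4 and 7. Class cut
points are 2.75 and 5.5, the midpoints between those cluster centres; no
published thresholds exist.

**A caveat on the published index table.** Recomposing `B` from the published
(rounded) sub-index columns reproduces the published index within ±0.01 for
15 of 16 specimens. Row Sb is internally inconsistent: its published 0.62 is
unreachable from its published sub-indexes even at full rounding slack
(maximum 0.617); the tests pin the actual 0.0106 discrepancy. Likewise the
published claim that the Brinkhoff and branching indexes are uncorrelated
does not hold on the published columns (Pearson r = 0.548, p = 0.028,
n = 16), though it would under a Bonferroni correction for the three
correlations examined; the two non-correlations against normalized area do
hold and are asserted.

## Surface areas

- Round raphe (homogeneous lamellae): `S_gross = 2·a_L·LN`.
- Elongated raphe: `S_gross = 2·a_L·w_max·LN + 2·a_S·(1−w_max)·LN` with
  `w_max = 0.7` by default — the average of the bent-raphe (0.6) and
  linear-raphe (0.8) presets, both of which remain available per specimen.
  The estimate underestimates linear and overestimates bent raphes.
- Percentage increase: measured on four sectioned lamellae per specimen as
  the excess of the epithelial semi-boundary over the straight lamellar
  length; the semi-boundary is read along one face, and since both faces
  carry folds the one-face ratio applies to the two-faced gross area. Mean
  and *sample* (n−1) standard deviation are reported; the published tables do
  not state which sd convention they use.
- Fold-inclusive area: `S_folds = S_gross·(1 + p/100)`.
- Normalization: `100·S/size²` with S in mm² and size in cm — the source's
  mixed-unit convention, preserved deliberately. Batoids are normalized by
  disk width, all others by body length; the two kinds are carried as
  metadata and mixing them raises a warning.

Smallest-lamella areas for the elongated-raphe specimens were never
published, so their gross areas cannot be re-derived independently; only the
two round-raphe rows are exactly checkable, and the pipeline refuses to
fabricate the missing inputs.

## Group statistics

Per specimen, the fold-driven length increase is tested by one-way ANOVA of
the linear-length group against the semi-boundary group (2 × 4 design; with
two groups this equals the unpaired t-test, `F = t²`). A paired t-test is
offered as an option since the published design is not stated; unpaired
matches the "ANOVA" description. Across specimens, per-lamella percentages
enter a one-way ANOVA followed by Tukey HSD on all pairs (Tukey–Kramer when
unbalanced). Star codes use a decade scheme — `.` p<0.1, `*` p<0.05, `**`
p<0.01, `***` p<0.001, `****` p<1e−4, `*****` p<1e−5 — because the published
5-star scale is never defined. The published star matrix cannot be
reproduced cell-for-cell (the raw per-lamella lengths are unpublished); it
is exercised on synthetic data.

## Phylogenetic PCA

Traits: normalized largest-lamella area, lamellar number, percentage
increase, branching index, Brinkhoff index — 14 specimens after keeping the
larger specimen of each doubly-sampled species. The tip covariance `C` has
`C_ij` = shared root-to-MRCA path length with every branch set to 1; the
three-species *Raja* polytomy is kept as-is (no arbitrary resolution), and a
1e−10 ridge is added only on numerical singularity (not needed here). The
fit computes the GLS phylogenetic mean `a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X`, the
evolutionary covariance `V = (X−1a)ᵀC⁻¹(X−1a)/(n−1)`, rescales to a
correlation matrix in the default mode (the traits mix counts, percentages
and unit-interval indexes, and the published loadings all lie in [−1, 1]),
and eigendecomposes. Scores are centred traits times eigenvectors; loadings
are trait–score correlations; each component is oriented so its
largest-|loading| trait is positive, which reproduces the published loading
signs. With `C = I` the whole procedure reduces to ordinary PCA
(asserted to 1e−10). The implementation agrees with the R `phytools`
`phyl.pca` reference to ≥4 decimals on the bundled data (frozen cross-check
values in the test suite).

Correlation mode reproduces the published variance split — 57.44/23.71 vs
published 57.8/23.5, cumulative 81.15 vs 81.3 — within the stated one-point
tolerance, so the undocumented mode choice is resolved in favour of
correlation (covariance mode yields 97/3 and is clearly not what was run).
The published Newick string is not syntactically valid (missing commas,
bracketed); the bundled tree is its reconstruction with the shark clades
grouped as in the phylogeny the source follows. Both this reading and the
literal basal-trichotomy reading give the same variance split to within
0.02 points.

## Synthetic generators

**Lamellae.** A lamella is a stadium-shaped body (default 10 × 1.2 mm, long
axis horizontal) with rectangular secondary folds normal to the axis on both
faces (default 8 per side, 1.2 × 0.25 mm), the bottom row offset by half a
pitch so every fold base meets the central axis at its own junction. Branch
depth 0/1/2 adds nothing / a lateral arm pair at each fold tip / a second
pair at mid-stem; arm length is capped by the fold pitch so neighbouring
folds never touch, and layouts that would violate this (under positional
jitter) are regenerated from a fresh substream, up to 100 times. The body
defaults were chosen so that depth-2 arm pairs remain feasible at the
default pitch; the three depths then land at branching indexes ≈2.1, ≈4.1
and ≈7.1 — the three observed fold morphologies. Every lamella carries a
ground-truth record (exact polygon area/perimeter, fold count, expected
branch and notch counts derived from the construction), so pipeline outputs
are checked against construction rather than against themselves. Rasters
default to 20 px/mm, where raster area agrees with polygon area within 2%.

What the generator does *not* emulate: curved or tapering folds, fold
overlap in projection, section-plane obliquity, staining artefacts, or any
histological texture. Passing tests therefore demonstrate correctness of the
geometry/graph pipeline on clean outlines, not robustness to segmentation
noise in real micrographs.

**Measurement tables.** Specimen sizes and largest-lamella areas are
lognormal, lamellar numbers normal (clipped ≥ 20), the true percentage
increase uniform over 70–495 with per-lamella sd uniform over 8.5–93 — the
ranges printed for the 16 studied specimens. Per-lamella linear lengths are
3.0 ± 0.15 mm: the 5% coefficient of variation reflects the protocol of
sectioning all lamellae at a similar level, and is required for consistency
with the published per-specimen significance verdict — with the largest
printed sds and four lamellae per specimen, the all-16-specimens p < 0.001
conjunction holds for most but not all seeds, and is asserted as a majority
over seeds. A study-matched variant (`make_study_like_table`) draws
per-lamella pairs at each specimen's published mean and sd.

**Brownian traits.** `X = L_C Z L_Σᵀ` — a matrix-normal draw with row
covariance from the tree and a chosen trait covariance, via PSD square
roots, so rank-deficient trait covariances are allowed. One global integer
seed drives counter-based per-object substreams (`SeedSequence(seed,
spawn_key)`), so extending a table never perturbs earlier rows.

## Problem sizes and numerics

Stochastic suites use 100 paired seeds for the branch-depth ordering, 200
synthetic specimens for percentage-increase coverage, 200 Brownian
replicates at n = 14 for spectrum recovery, 1000 random star polygons for
the hull bounds, and 12–15 seeds for the majority-of-seeds group-statistics
patterns — sizes at which the asserted margins are stable well beyond their
thresholds. Reported numbers are rounded half-up (ties away from zero) at
report time only; all internal computation is double precision.

## Known limitations

- The indexes describe 2D sections; the lamellae are 3D objects, and no 3D
  complexity measure is attempted.
- Gross surface areas are order-of-magnitude proxies by construction (the
  source disclaims quantitative inter-species comparison, and so does this
  package).
- Exact per-specimen vertex/notch counts, the published star matrix, and
  elongated-raphe gross areas are unrecoverable from published data; the
  corresponding code paths are validated on synthetic ground truth instead.
- Micrograph segmentation (image → mask) is out of scope; masks or polygons
  are the expected input.
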