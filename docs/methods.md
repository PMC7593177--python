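# Methods

## Problem and overall procedure

`florizone` delineates floristic zones — regions whose plant assemblages
are internally homogeneous and distinct from their neighbours — from
georeferenced specimen records. The chain is:

1. **Rasterization.** Records are binned into a user-supplied rectangular
   grid (half-open cells, row-major from the south-west corner; points on
   the grid's maximum edges fold into the last row/column). The result is
   a binary cell × taxon presence–absence matrix plus a surveyed mask: a
   cell is surveyed iff at least one record fell in it, and unsurveyed
   rows are all-zero by construction. Taxon identity is the exact name
   string after whitespace trimming; no synonymy resolution is attempted,
   and no projection is ever inferred — the grid is explicit input.
2. **Self-organizing map.** The surveyed rows train a Kohonen SOM: a
   rectangular lattice of nodes whose weight vectors (the codebook) live
   in taxon space. Presence–absence rows are used as real vectors without
   scaling.
3. **Zone delineation.** The codebook vectors are clustered by
   complete-linkage agglomeration on Euclidean distances; the number of
   zones k maximizes the mean silhouette of the node partition over a
   candidate range (default 2–15). Each surveyed cell inherits its
   best-matching unit's cluster.
4. **Spatial cleaning.** Unsurveyed cells are filled with the modal label
   of their eight neighbours, in synchronous passes iterated to a fixed
   point; named island groups are homogenized to their own modal observed
   label. Every cell carries a provenance flag
   (observed / imputed / island-rule / unassigned).
5. **Diagnostics.** Per-zone areas and richness, the Venn partition of
   taxa over zone subsets, family composition of zone-specific taxa, Kira
   warmth/coldness indices, one-way ANOVA with Tukey HSD letters for
   continuous environmental variables, and composition ratios for
   categorical ones.

## SOM model and defaults

Online training presents every surveyed row once per epoch in a
seeded-shuffled order. At presentation *s* of *S* total, the update is

    w_j ← w_j + α(s) · h(j, bmu, ρ(s)) · (x − w_j)

with α and ρ interpolated linearly from their start to end values over
all *S* presentations. `h` is either a bubble kernel (1 if the lattice
distance to the BMU is ≤ ρ) or a Gaussian `exp(−d²/2ρ²)`. Lattice
distance is Euclidean on (row, col) node coordinates (square lattice, not
hexagonal). Defaults follow the classical settings of the widely used R
implementation of Kohonen maps:

| parameter | default | note |
|---|---|---|
| lattice | 9 × 9 (81 nodes) | square lattice |
| α (learning rate) | 0.05 → 0.01 | linear decay |
| ρ (radius) | 2/3-quantile of node-to-node lattice distances → 0 | linear decay |
| epochs | 100 | full passes over the data |
| neighbourhood | bubble | gaussian available |

Initialization samples `n_nodes` distinct surveyed rows without
replacement (seeded); with fewer rows than nodes it falls back to uniform
random weights in [0, 1]. Because each update is a convex combination
(α·h ≤ 1), codebook entries remain coordinate-wise inside the hull of the
initial codebook and the data. Training is bit-reproducible given
(seed, schedule, data); all tie-breaks (BMU, linkage merges, imputation
modes, island modes) resolve to the smallest index or label.

Quantization error (mean Euclidean distance of rows to their BMU) is
recorded per epoch as a training diagnostic; the U-matrix (mean codebook
distance to 4-connected lattice neighbours) visualizes cluster
boundaries.

## Cluster-number selection

The silhouette is computed **on the codebook vectors** (the 81 nodes),
the same objects that are clustered, not on the original cells: model
selection then operates in the space where the partition is defined, and
the score is independent of how many cells map to each node. Singleton
clusters contribute silhouette 0 (the standard convention); ties in the
silhouette profile resolve to the smallest k. Complete linkage is
implemented naively (O(n³), exact for ≤ 100 nodes) so that merge heights
and tie behaviour are fully specified; scipy's implementation serves as
an independent cross-check in the tests, never as the implementation.

For reporting, zone labels are renumbered 1..k by descending assigned
area, a stable data-driven ordering.

## Zone statistics and the Venn partition

Zone membership for area statistics uses all assigned cells (observed +
imputed + island-rule). Richness and per-cell richness use only each
zone's *surveyed* cells: unsurveyed rows are all-zero by construction, so
including them would deflate the mean without adding information. The
standard error of mean per-cell richness uses the sample standard
deviation (ddof = 1) divided by √n. The Venn partition assigns each taxon
to the exact subset of zones whose surveyed cells contain it; regions are
disjoint and cover every taxon present in at least one assigned cell.

## Climate indices and group comparisons

Kira's warmth index WI = Σ (t − 5) over months with t > 5 °C and coldness
index CI = −Σ (t − 5) over months with t < 5 °C (both in °C·month) use
strict inequalities: a month at exactly 5 °C contributes to neither.
One-way ANOVA is computed from sums of squares (zero within-group
variance is a hard error, since F is undefined). Tukey HSD uses the
Tukey–Kramer statistic q = |m_i − m_j| / √(MS_w/2 · (1/n_i + 1/n_j)) with
p-values from the studentized-range distribution, appropriate because
zone cell counts differ; the compact letter display is built by
insert-and-absorb over the nonsignificance graph. Composition ratios are
per-zone class percentages with missing values excluded from the
denominator.

The module consumes pre-gridded per-cell environmental values;
interpolating station data onto the grid (a GIS exercise that depends on
topography, altitude and the toolchain) is deliberately out of scope.

## Synthetic landscapes

The generator emulates the structure of a dense national specimen survey
over ~780 grid cells. Defaults (chosen once, used by the tests and the
acceptance script):

- 26 × 30 grid, four contiguous latitudinal bands (seeded Voronoi patches
  available as the irregular alternative; optional island groups get
  their own zone);
- 200 core species at occupancy 0.5 everywhere, 40 zone-specific species
  per zone at 0.8 inside / 0.02 outside their home zone, and 30 gradient
  species with logistic responses (slope 0.5 per row, midpoints spread
  along the south–north axis) that create smooth assemblage turnover not
  aligned with any single boundary;
- 10 % of cells unsurveyed; each surveyed cell yields N ~ Poisson(400)
  specimen records drawn uniformly with replacement from its occupying
  species — about the per-site sampling intensity of a dense herbarium
  survey — with coordinates uniform within the cell;
- monthly temperatures as a seasonal sinusoid (amplitude 12 °C, peak in
  July/August) around a mean annual temperature falling from ~14 °C in
  the south to ~8 °C in the north, plus noise; an opposing precipitation
  gradient; categorical substrate/terrain classes correlated with zone
  (60 % signature class).

Everything is deterministic under the configured seed.

What the generator does **not** emulate: spatially autocorrelated
sampling effort, taxonomic error and synonymy, range boundaries that cut
across the zone geometry, dispersal limitation, and detection differences
between species. Passing recovery tests therefore show that the pipeline
recovers zonal structure under honest sampling noise and overlapping
species pools — not that it is robust to every pathology of real
specimen data.

A note on detectability: with N specimen draws from n locally occupying
species, per-species detection is 1 − (1 − 1/n)^N. Near-complete
(≥ 99 %) per-cell detection therefore requires N to exceed n·ln(100); at
the default pool (~150 occupants per cell) effort 400 detects ~93 % of
occupants per cell, which is ample for zone recovery but not exhaustive.
Relatedly, because zone-specific species still occur outside their home
zone at p_out = 0.02, almost every one of them is eventually detected in
a second zone under dense sampling, so the *strictly* single-zone regions
of the Venn partition are typically small — as in real floras, where
exclusivity is rarer than preference.

Recovery is scored by the adjusted Rand index on cells assigned in both
maps, with a greedy diagonal-maximizing matching for the confusion table.

## Pipeline and reproducibility

A single top-level seed is expanded (via one RNG draw per stage) into
seeds for simulation, SOM initialization/training, and island handling;
the run manifest records the config snapshot, the per-stage seeds, the
package version and a SHA-256 hash of every artifact. Two runs with the
same config and seed produce byte-identical artifacts.

Problem sizes in the test-suite and acceptance runs: ten replicate
landscapes of 780 cells × ~390 taxa, 81-node SOMs trained for 100 epochs
— small enough to run comfortably on one CPU while matching the scale of
the motivating survey (771 cells).

## Known limitations

- The grid is axis-aligned rectangular; no support for projections,
  curved graticules or unequal-area cells beyond a user-supplied cell
  area.
- Complete linkage is O(n³): fine for codebooks (≤ ~100 nodes), not meant
  for clustering thousands of cells directly.
- The silhouette-over-nodes choice weights each node equally regardless
  of how many cells it represents; a silhouette over cells would weight
  by cell counts and can select a different k on unbalanced data.
- The island rule requires the user to name island cell groups; nothing
  is inferred from geometry.
- ANOVA/Tukey assume independent cells; spatial autocorrelation of
  climate within zones makes the reported p-values optimistic, as usual
  for gridded data.
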