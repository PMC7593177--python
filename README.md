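# florizone

Floristic regionalization from georeferenced plant occurrence records.

Biogeographers delineate *floristic zones* — regions whose plant
assemblages are internally homogeneous and distinct from neighbouring
regions — to understand how climate, substrate and history structure
regional floras, and to target conservation. `florizone` implements a
complete, reproducible pipeline for deriving such zones from specimen
data:

1. **occurrence records → grid**: specimens (taxon, family, x, y) are
   binned into an explicit rectangular grid, producing a binary
   cell × taxon presence–absence matrix with a surveyed-cell mask;
2. **self-organizing map**: a from-scratch online Kohonen SOM (default
   9 × 9 square lattice) compresses the cell assemblages into 81 codebook
   vectors w_j via w_j ← w_j + α·h(j, bmu, ρ)·(x − w_j), with α and ρ
   decaying linearly over training;
3. **zone delineation**: complete-linkage hierarchical clustering of the
   codebook on Euclidean distances, with the number of zones k* chosen to
   maximize the mean silhouette s̄ = mean_i (b_i − a_i)/max(a_i, b_i)
   over k ∈ [2, 15]; cells inherit their best-matching unit's cluster;
4. **spatial cleaning**: unsurveyed cells take the modal label of their
   eight neighbours (synchronous passes to a fixed point); named island
   groups are homogenized to their own modal observed label;
5. **diagnostics**: per-zone areas and species richness, the Venn
   partition of taxa across zone subsets (common vs zone-specific taxa),
   family composition of specific taxa, Kira's warmth/coldness indices
   (WI = Σ_{t>5}(t − 5), CI = −Σ_{t<5}(t − 5)), one-way ANOVA with
   Tukey–Kramer HSD and compact letter displays, and composition ratios
   of categorical site factors.

A synthetic-landscape generator with known zone structure (contiguous
bands or Voronoi patches, shared core species, zone-specific species,
gradient-responding species, heterogeneous sampling effort) makes every
stage testable end-to-end, scored by the adjusted Rand index against the
generating truth. See `docs/methods.md` for the model details and design
choices.

## Worked example

Run the full pipeline on a default synthetic landscape (26 × 30 grid,
four latitudinal zones, 390 species, 10 % of cells unsurveyed):

```bash
florizone run-all --config config.yaml --seed 42 --out run/
```

where `config.yaml` can be as small as `seed: 42` (no `occurrences:` path
means: simulate). The run writes the presence–absence matrix, the trained
SOM, the merge tree, the silhouette profile, the zone map and all
diagnostic tables, plus `summary.json`:

```json
{
  "k_selected": 4,
  "max_mean_silhouette": 0.42123585954835074,
  "n_zones": 4,
  "common_taxa": 361,
  "recovery_ari": 0.9965898616060263,
  "k_true": 4
}
```

Four zones are selected (silhouette peaks at k = 4 with s̄ ≈ 0.421,
against 0.319 at k = 3 and 0.315 at k = 5), the recovered map agrees with
the generating truth at ARI ≈ 0.997, and 361 of 390 taxa occur in all
four zones — the core flora shared across zones, as expected when zone
preference, not strict endemism, drives the signal. `zone_stats.csv`
gives the per-zone areas and richness:

```
 zone  n_cells  area_km2   area_pct  richness  mean_cell_richness  se_cell_richness
    1      210  32692.80  26.923077       380          139.048387          0.491502
    2      209  32537.12  26.794872       381          139.173913          0.468997
    3      181  28178.08  23.205128       382          139.680473          0.533756
    4      180  28022.40  23.076923       383          138.981595          0.484906
Total      780 121430.40 100.000000       390          139.217949          0.247185
```

The same stages are available as composable subcommands
(`simulate`, `rasterize`, `train`, `regionalize`, `diagnose`, `env`) and
as a plain Python API:

```python
import florizone as fz

records, truth = fz.generate(fz.SyntheticConfig(seed=42))
pa = fz.rasterize(records, truth.grid)
fit = fz.train(fz.init_codebook(pa, 9, 9, seed=1), pa)
```

To analyse real data, point `occurrences:` at a delimited text file with
taxon/family/longitude/latitude columns (names configurable), supply the
grid geometry under `grid:`, and optionally a per-cell environment table
(`t01..t12` monthly temperatures, precipitation, categorical site
factors) under `environment:`.

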