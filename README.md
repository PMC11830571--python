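# structura

Structural complexity metrics from LiDAR-derived rasters and their
association with multi-trophic biodiversity.

Forest managers increasingly need landscape-scale biodiversity
assessments that do not require exhaustive field surveys. `structura`
implements a remote-sensing route to that goal: it derives terrain and
canopy structural complexity metrics from gridded LiDAR products
(digital terrain and surface models), combines them into two composite
complexity indices, condenses plant/beetle/bird survey tables into a
single multi-trophic diversity index, and quantifies the association
between the two with a reproducible statistical pipeline. A synthetic
landscape-and-community generator makes every stage testable end to
end without any external data downloads.

## The model in brief

From a DTM/DSM pair the canopy height model is CHM = DSM − DTM
(clamped at ≥ 0; heights < 0.5 m count as gap). Rasters are aggregated
to a sweep of pixel sizes (grains, 1–100 m edge); per grain-pixel *i*
the maximum h_i and mean μ_i are recorded over the *s* pixels of a
site. The metric suite:

| kind | metrics |
|---|---|
| canopy | Q0.95(h_i), MOCH = mean(h_i), CR = sd(h_i), entropy E′ = −Σ p_i ln p_i over 1-m height bins, VCI = E′/ln(bins), VAI (summed leaf-area density), rumple (3-D/2-D surface ratio), deep-gap and cover fraction |
| terrain | mean/max elevation, Horn slope, TRI (mean \|Δe\| to 8 neighbors), roughness (3×3 range), TR = sd(elevation) |
| combined | RuC = CR_scaled / TR_scaled, RoC = RuC × h_scaled |

Site metrics are min-max scaled to [0.1, 1] across sites (the 0.1
floor keeps the reciprocal of terrain rugosity finite). Per trophic
level *j*, Shannon diversity is scaled the same way into I′_j, and the
multi-trophic diversity index is

    MDI = (1/n) Σ_{j=1..n} I′_j  ∈ [0.1, 1].

The association stage selects, per metric, the grain most rank-
correlated with MDI (Spearman, p ≤ 0.05), filters collinear metrics
(|ρ| ≥ 0.7), ranks predictors with a 600-tree random forest (2
predictors per split, leave-one-out RMSE), fits polynomial models with
and without complexity, and tests community dissimilarity between
forest types with Bray–Curtis distances, ANOSIM and PERMANOVA
(exhaustive permutation enumeration on small designs).

See `docs/methods.md` for assumptions, parameter defaults and
numerical conventions.

## Worked example

Simulate a 34-site study with the default planted complexity effect,
compute diversity and the combined index, and test the association:

```python
from structura import simulate as sim, pipeline
from structura.diversity import diversity, mdi

res = sim.simulate_sites(n_sites=34, seed=1)
print(res.metrics.head(3)[["site", "cr", "tr", "q95", "ruc", "roc"]])

m = mdi(diversity(res.counts), ["plant", "beetle", "bird"]).set_index("site")
sites = list(res.metrics["site"])
rho, p = pipeline.spearman(res.metrics["ruc"], m.loc[sites, "mdi"])
print(f"Spearman(MDI, RuC): rho={rho:.3f}, p={p:.2e}")
```

prints

```
site       cr       tr       q95      ruc      roc
 S01 1.914240 5.586670 33.926059 1.413191 1.016777
 S02 2.025675 8.315207 31.839216 1.057778 0.694562
 S03 2.589666 2.358633 28.464975 3.920971 2.176032
Spearman(MDI, RuC): rho=0.720, p=1.60e-06
```

Each row is one site: canopy rugosity CR and 95th-percentile height in
meters, terrain rugosity TR in meters, and the unitless combined
indices. The Spearman test recovers the planted effect — the community
generator was calibrated so the population correlation between MDI and
combined rugosity is ≈ 0.7 at 34 sites, and this realization lands at
0.72 with p ≪ 0.05.

The same stages are available from the shell and compose into a
pipeline:

```sh
structura simulate --sites 34 --seed 1 -o run/
structura chm --dsm run/dsm_S01.tif --dtm run/dtm_S01.tif -o run/chm_S01.tif
structura canopy --chm run/chm_S01.tif --site S01 -o run/canopy_S01.csv
structura terrain --dtm run/dtm_S01.tif --site S01 -o run/terrain_S01.csv
structura combine --metrics run/metrics.csv -o run/combined.csv
structura diversity --counts run/counts.csv -o run/diversity.csv
structura mdi --diversity run/diversity.csv -o run/mdi.csv
structura grouptest --counts run/counts.csv --sites run/sites.csv -o run/tests.json
```

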