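# isozone

Mapping a plant invader's **zone of influence** from multi-tracer foliar
isoscapes.

When an N₂-fixing invader (think *Acacia longifolia* in a dune system)
establishes inside native vegetation, it alters nitrogen supply, water
relations and carbon gain of its neighbours. Foliar tracers of a native
indicator species record this: N concentration and δ¹⁵N rise towards the
invader canopy, and δ¹³C (a proxy for intrinsic water-use efficiency)
responds non-monotonically — enriched just outside the canopy, depressed
within it. `isozone` turns georeferenced samples of these three tracers
into an objective, unsupervised map of influence zones:

1. **Isoscapes** — each tracer is interpolated per plot by ordinary
   kriging; the variogram model and lag segmentation are chosen by
   leave-one-out cross-validation (min RMSE, ties by R²) over six models
   × six segmentations, with the cutoff at ⅓ of the plot diagonal.
2. **Zoning** — the stacked surfaces are clustered with Gaussian
   mixtures under the ten standard covariance constraints
   (Σₖ = λₖDₖAₖDₖᵀ; EII … VVV), fitted by EM from a deterministic
   Ward initialisation; the number of zones is the start of the BIC
   plateau. Zones are compared by Kruskal–Wallis plus a corrected
   mean-rank post-hoc test with compact letters.
3. **Harmonization** — zone medians from all plots are clustered by
   UPGMA on Euclidean distances and cut at the silhouette-optimal k,
   yielding final clusters comparable across plots; the highest-N,
   δ¹⁵N-enriched final cluster is the invader's zone of influence.

A synthetic-data module generates whole plots (autocorrelated Gaussian
random fields plus canopy-distance influence kernels, sampled on the
2 × 5 m subplot lattice) with known truth zones for validation.

## Worked example

```sh
python examples/01_kriging_an_isoscape.py
```

```
cutoff = 17.95 m (one third of the plot diagonal)
selected: spherical variogram, uniform_3m lags (LOO RMSE 0.985 permil, R^2 0.933)
  nugget 0.000, partial sill 21.503, range 19.3 m
kriged d15N surface: -13.1 to 1.0 permil
```

The cutoff is the standard ⅓-diagonal rule for a 20 × 50 m plot. The
LOO-selected spherical variogram captures the invader-induced spatial
structure (a large partial sill, range ≈ 19 m spanning the influence
gradient); the kriged surface runs from dune-background values (≈ −13 ‰)
up to ≈ 0 ‰ — the signature of atmospheric N₂ fixed by the invader —
under the canopy. `examples/02_mixture_zoning.py` prints the BIC surface
over all ten covariance codes and the plateau choice (on its
three-cluster demo data: EEI, k = 3, component means at the background /
halo / core tracer levels). `examples/03_full_study.py` runs the whole
three-plot pipeline; on the default synthetic study it reports 6–8 zones
per plot, k = 2 final clusters, and

```
highest-N final cluster 2 occurs in plots: ['1', '2']
  plot 1: median distance to canopy by final cluster: 1: 2.0 m, 2: 0.0 m
```

— the highest-N cluster appears only in the invaded plots and sits on
the canopy, which is the invader's mapped zone of influence.

The same pipeline is scriptable from a shell:

```sh
isozone simulate --out study/ --seed 1
isozone run --config study/run_config.yaml
isozone interpolate --samples my_plot.csv --out out/   # single stages
isozone cluster --isoscapes out/ --out zones/
isozone harmonize --summaries a.csv --summaries b.csv --out final/
```

Every run writes a manifest (selected variogram per tracer, mixture code
and k per plot, final k, τ, resolution, checksums) sufficient to re-run
bit-identically.

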