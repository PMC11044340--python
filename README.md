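# chromadapt

Quantifies dorsal colour-pattern variation of small lacertid lizards from
georeferenced field photographs and tests what drives it: phylogenetic
inertia or island environment.

Mediterranean wall lizards (*Podarcis*) are mostly cryptic green/brown, but
some small-island populations turn uniformly dark or blue. `chromadapt`
implements an end-to-end analysis of that phenomenon:

1. **Colour extraction** — quality-filter photograph metadata (five
   criteria, including ≤ 1000 m georeferencing error), sample 10 random
   pixels inside a dorsal region-of-interest polygon, and convert them from
   sRGB to CIELAB (D65, 2° observer), giving each individual the axis means
   (l̄, ā, b̄).
2. **Derived colour statistics** — a robust (trimmed) K-means fit to the
   pooled colour table finds the two genus "basic colours" (green, brown);
   an individual's *distance to centroids* is the minimum over centroids of
   the mean Gower dissimilarity, Σ|xᵢ−yᵢ|/rangeᵢ/3, between its mean colour
   and the 200 pool colours nearest that centroid. *Colour contrast* is the
   mean CIEDE2000 ΔE₀₀ over the 45 pairs of its 10 samples, so uniform
   animals score lower than disruptively patterned ones. A PERMANOVA on
   stratified resamples checks colour fidelity between photograph sources.
3. **Phylogenetic signal** — Pagel's λ per chromatic variable by maximum
   likelihood under λ-transformed Brownian motion (off-diagonal of the BM
   covariance scaled by λ), resampling one individual per species per
   iteration; significance is a likelihood-ratio test against λ = 0 (χ²₁).
4. **Environmental drivers** — generalized least squares regressions of each
   chromatic variable on island/climate covariates with spatially
   correlated errors, corr(d) = (1−nugget)·ρ(d/range), ρ one of five
   families (exponential, Gaussian, linear, spherical, rational quadratic);
   candidates ranked by AICc and coefficients Bonferroni-adjusted over the
   full family of m = 16 tests.
5. **Ordination** — log-transform PCA of colour means and environment.

Community-science photograph collections are rarely redistributable, so the
package ships a first-class synthetic-data generator (`chromadapt.simulate`) producing
rendered lizard-like scenes, Yule phylogenies, λ-structured traits and
spatially autocorrelated covariates with known ground truth, so every stage
is testable end to end.

## Worked example

```python
import chromadapt as ca

ds = ca.simulate_dataset(seed=11)          # 200 individuals, 20 species
data_dir = ds.write("bundle")
cfg = ca.PipelineConfig(data_dir="bundle", out_dir="out",
                        seed=5, n_resamples=200)
results = ca.run_pipeline(cfg)
print(results["table1"].round(4).to_string(index=False))
```

prints the resampled phylogenetic-signal summary (the bundle was planted
with weak signal, λ = 0.1):

```
     variable  mean_lambda  se_lambda  pct_significant  n_resamples
       mean_l       0.0508     0.0121              1.0          200
       mean_a       0.0035     0.0016              0.0          200
       mean_b       0.0718     0.0143              3.5          200
dist_centroid       0.0914     0.0165              2.5          200
     contrast       0.0703     0.0132              2.0          200
```

`mean_lambda` near 0 with few significant resamples says colouration is not
phylogenetically constrained here, so the spatial GLS stage proceeds without
a phylogenetic correction. `results["table2"]` then lists the AICc-selected
spatial structure per response and `results["table3"]` the coefficients:
the planted island-syndrome effect appears as a positive log-area
coefficient on lightness and a negative one on distance-to-centroids
(smaller islands → darker, more atypically coloured animals).

The same pipeline is scriptable from a shell:

```bash
chromadapt simulate --seed 11 --out bundle
chromadapt run --config run.json
```

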