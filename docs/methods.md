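# Methods

## Colour measurement

Each photographed individual contributes 10 pixels drawn uniformly at random,
without replacement and at pixel resolution, from a polygonal dorsal region
of interest (ROI). Pixel colours are converted sRGB → linear RGB → XYZ →
CIELAB assuming the D65 white point and the 2° standard observer — the
de-facto interpretation of consumer photographs; no cross-camera colour
calibration is attempted, and the PERMANOVA source-fidelity check (below) is
the control for that. The conversion is delegated to scikit-image; the test
suite verifies it against an independently coded reference conversion and a
full 16³-lattice round trip.

Metadata rows pass quality control only if four curator-verified flags hold
(taxonomic identifiability, acceptable exposure, sharpness, live animal) and
the computed georeferencing-error criterion is met (≤ 1000 m; a missing
error fails as unverifiable).

## Derived chromatic statistics

**Genus colour centroids.** All sampled colours are pooled and clustered
with trimmed K-means, k = 2: at each iteration the `trim` fraction (default
0.05) of points farthest from their nearest centroid is excluded before the
update, making the centroids robust to over/under-exposed samples. Defaults:
50 random restarts, convergence tolerance 1e-6, seed-deterministic;
centroids are sorted by (l, a, b) so the fitted set is stable across seeds.
Each centroid keeps its 200 nearest pool colours (Euclidean distance in
CIELAB by default; ΔE₀₀ ranking is a config option).

**Distance to centroids.** An individual is represented by its per-axis mean
colour (l̄, ā, b̄). Its distance to one centroid is the mean Gower
dissimilarity to that centroid's 200-colour neighbourhood, where the Gower
dissimilarity of two colours is the mean over the three axes of
|xᵢ−yᵢ|/rangeᵢ with ranges taken from the full untrimmed pool. The reported
statistic is the minimum over the two centroids — distance to the nearest
basic colour — so large values mean "atypically coloured" regardless of
which basic colour the animal resembles least. Averaging over both centroids
instead is a switchable aggregation.

**Colour contrast.** Mean CIEDE2000 ΔE₀₀ (kL = kC = kH = 1, full hue-rotation
and compensation terms) over the 45 unordered pairs of the 10 samples. Zero
iff all samples are identical; a disruptive pattern mixing two distinct
colours raises it monotonically with the ΔE₀₀ of the mixture. CIEDE2000 is
implemented here and validated against the published 34-pair verification
dataset (max |error| < 1e-4) and against scikit-image on random pairs.
ΔE₀₀ is not a metric; the triangle inequality is neither used nor asserted.

**Source fidelity.** For one species with material from both sources, a
PERMANOVA (pseudo-F on Euclidean distances of CIELAB coordinates, group
labels permuted; scikit-bio implementation) is run on stratified resamples
(n = 100, 50% per source; defaults 999 permutations, 500 resamples) and the
fraction of non-significant resamples is reported. Note that resampled
p-values from one fixed pool are dependent; calibration statements about the
test refer to independent datasets.

## Phylogenetic signal

Under Brownian motion the species values are N(μ·1, σ²V) with V[i,j] the
shared root-to-MRCA path length. Pagel's λ multiplies the off-diagonal of V;
V(λ) interpolates between a star phylogeny (λ = 0) and full BM (λ = 1). For
fixed λ, μ̂ and σ̂² have closed GLS/ML forms, so the profile likelihood is
maximised over λ alone (bounded scalar optimisation, tolerance 1e-8, with
the interval endpoints evaluated explicitly so boundary optima are exact).
The upper bound λ_max = min over pairs of min(Vᵢᵢ, Vⱼⱼ)/Vᵢⱼ, backed off by a
relative 1e-6 because the bound itself is a singular matrix when two tips
are near-identical cherries. Significance is the likelihood-ratio test of λ̂
against λ = 0 with a χ²₁ reference — the convention of the standard R
implementation, against which this fitter agrees to 1e-5 in λ, log-likelihood
and p on fixed data. Because λ = 0 lies on the boundary of the parameter
space, this test is conservative: in the package's own 500-replicate null
study the empirical size at α = 0.05 is below 1%, not 5%. This is a property
of the convention, not of the code, and users should read the resampled
"percent significant" as a conservative quantity.

With many individuals per species, λ is summarised by resampling: each
iteration draws one individual per species uniformly at random (the only
resampling that keeps a species-level λ computable; bootstrapping
individuals within species and using species means is a config switch), fits
λ, and records (λ̂, p). The summary reports mean λ̂, its standard error over
resamples (the standard error of the mean, sd/√n_resamples), and the
percentage of resamples with p < α. Default
n_resamples = 10,000; the pipeline runs used in tests use 50–200 for desk
speed with recorded seeds.

## Spatial GLS

Responses are the five chromatic variables; predictors are environmental
covariates log-transformed (log(1+x); sign(x)·log(1+|x|) where negatives
occur) and z-scored, so coefficients are in standardized units. Errors are
zero-mean Gaussian with corr(εᵢ, εⱼ) = (1−nugget)·ρ(dᵢⱼ/range) for i ≠ j,
d the haversine great-circle distance in km; ρ is exponential e⁻ᵘ, Gaussian
e⁻ᵘ², linear max(0, 1−u), spherical 1−1.5u+0.5u³ (0 beyond u = 1) or
rational quadratic 1/(1+u²). Duplicate coordinates are allowed — the nugget
absorbs them. Fitting is maximum likelihood (not REML) so AICc is comparable
across candidates sharing fixed effects: β and σ² are profiled analytically
given (range, nugget); those two are optimised on (log range,
logit nugget) with a coarse grid start followed by bounded L-BFGS-B, the
range bounded between the 1% quantile and twice the maximum of observed
distances. Numerically singular correlation assemblies (e.g. a long-range
Gaussian without nugget) are rejected inside the search rather than fitted.
t statistics use the unbiased residual variance and n − p degrees of freedom
(structure parameters not subtracted, the common GLS-software convention).

Model selection fits 5 families × nugget on/off plus an iid model, ranks by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting intercept, slopes, σ²,
range and nugget, and reports ΔAICc and Akaike weights. Coefficient p-values
are Bonferroni-adjusted with family size m = the total predictor count over
all models (16 under the default five-model design), configurable.

## Synthetic data

The generator emulates the study inputs with known truth:

* **Phylogenies** — pure-birth (Yule) trees rescaled to unit depth; tip
  edges are extended by one shared exponential waiting time so branch
  lengths are strictly positive and the tree stays ultrametric.
* **Traits** — species means drawn from N(μ, σ²V(λ)); individuals add iid
  noise. Monte-Carlo tests confirm element-wise convergence of the tip
  covariance to σ²V(λ).
* **Spatial fields** — zero-mean Gaussian-process draws over (lon, lat)
  sites from the same correlation families used in fitting (Cholesky, with
  an eigen square root for the exactly-singular duplicate-site case).
* **Scenes** — a background, a rectangular dorsal ROI filled with a base
  colour, an optional spotted (thresholded smooth noise) or striped
  (thresholded longitudinal wave) pattern placed on an exact pixel fraction
  of the ROI, and iid CIELAB photometric noise; conversion to 8-bit sRGB
  counts gamut-clipped pixels. Planted colours outside the sRGB gamut are
  rejected at specification time (analytically, via linear-RGB bounds) so
  ground truth stays exact.
* **Dataset bundles** — ~200 individuals / 20 species by default on 60
  sites in a Mediterranean-scale window; islands (default 60% of sites)
  carry log-uniform areas 10⁻²–10⁵ km² (mainland rows get continental
  areas and zero distance/depth, matching the data convention). The planted
  island syndrome: individual lightness rises with z-scored log area (slope
  2 CIELAB units/SD), and a mixing weight toward a dark-blue atypical
  colour falls with log area (slope 0.15/SD from a 0.15 baseline), so
  distance-to-centroids falls and uniform patterning fades with island
  size. Effect sizes are the package's own choices, set once so recovery
  experiments are well powered. Residual site effects are
  exponential-family fields (range 100 km, nugget 0.2, sill 4).

What the generator does **not** emulate: real camera pipelines (white
balance, compression), lizard body geometry and scale texture, observation
effort gradients, or collinearity structure among real environmental
covariates. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated models, not robustness to those real-data
complications.

**Sampling geometry for the spatial recovery studies.** Family
identifiability depends on the distance design, so the standalone GLS
experiments use clustered localities (15 centres in a 14° × 10° window,
0.7° within-cluster scatter), chosen by an identifiability study across six
candidate geometries (uniform windows, cluster counts 8–25, hierarchical
clusters, transects) as the design under which AICc keeps the generating
exponential family closest to the best candidate. Even so, with one field
realization per replicate at n = 300 the generating family stays within
ΔAICc ≤ 2 of the winner in only ≈75–80% of replicates — an honest ceiling
of single-realization model selection at this size, worth knowing before
reading Table-2-style outputs as evidence for a particular correlation
shape.

## Pipeline

Stages run QC → extraction → centroid model + statistics → λ resampling →
spatial GLS suite → log-PCA, writing display tables rounded to 4 decimals
plus full-precision twins, and a manifest (seeds, input SHA-256 hashes,
stage records) sufficient to reproduce a run bit-for-bit. The λ gate
mirrors the study logic: if mean λ̂ < 0.25 for every variable the signal is
recorded as negligible and the GLS stage proceeds without phylogenetic
correction (the gate threshold is config). The PCA log-offset is +1 for
non-negative variables (zeros are legal for mainland distance/depth);
opponent axes use the signed log. Which variables enter the PCA (colour
means only, or colour + environment) is a config choice; the default joins
both.

## Known limitations

* The λ LR test is conservative at the boundary (see above); resampled p%
  under-counts true signal at small effect sizes.
* AICc structure selection at n ≈ 300 frequently rates a neighbouring
  family within a few AICc units of the truth; families should be read as
  "plausible shapes", not identified truths.
* Gower ranges come from the analysed pool, so centroid distances are not
  comparable across datasets with different pools.
* The PERMANOVA check inherits the dependence of overlapping resamples from
  one photograph pool; it is a fidelity screen, not an inference procedure.
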