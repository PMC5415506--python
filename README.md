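# aviantrends

Tools for asking whether century-scale changes in avian body size are
linked to changes in food availability, using carotenoid-based plumage
colour as a dietary proxy measurable on museum specimens. Birds cannot
synthesize carotenoids — the yellow pigment in their plumage tracks what
they ate — so if shrinking (or growing) bodies were driven by changing
food supply, size trends and colour trends should move together across
species. The package implements the full analysis chain for testing
that prediction on specimen series like the 15 Australian honeyeaters,
thornbills and allies (Meliphagoidea) studied over 1900–2008, and ships
a synthetic-data generator with known ground truth for every stage.

## The analysis

**1. Colour scoring.** Reflectance spectra R(λ) (300–700 nm, five
replicates per plumage patch) are run through the receptor-noise
limited model of avian tetrachromatic vision. Cone quantum catches

&nbsp;&nbsp;&nbsp;&nbsp;Q_i = ∫R(λ)I(λ)C_i(λ)dλ / ∫I(λ)C_i(λ)dλ,&nbsp;&nbsp;f_i = ln Q_i,&nbsp;&nbsp;i ∈ {VS, S, M, L}

are mapped to chromatic coordinates (x, y, z) whose Euclidean distance
equals the Vorobyev–Osorio discriminability ΔS in just-noticeable
differences (jnd) — an exact isometry, verified to 1e−9. Per species, a
covariance-matrix PCA condenses the coordinates to one score, PC1, sign-
anchored to carotenoid chroma (R₇₀₀ − R₄₅₀)/R₇₀₀ so that higher PC1 =
more carotenoid-coloured plumage.

**2. Per-species trends.** For each species and trait (wing length in
mm, PC1 in jnd), a linear mixed model estimates the temporal slope β
(per year) with sex, altitude, a residual autocovariate (RAC) absorbing
spatial autocorrelation, season + season² terms for colour (feather
abrasion since molt), a subspecies random intercept, and optional
sex-stratified residual variances selected by AIC. A penalized-spline
GAMM on year screens for nonlinearity: effective degrees of freedom
(EDF) ≈ 1 means linear, EDF > 3 flags a nonlinear trend.

**3. Across-species meta-analysis.** The per-species slopes y_i with
sampling variances SE_i² enter a Bayesian phylogenetic random-effects
meta-analysis, y_i = μ (+ b·x_i) + a_i + u_i + m_i with a phylogenetic
effect a ~ N(0, σ²_p A) and independent species effect u ~ N(0, σ²_s),
sampled by a parameter-expanded Gibbs sampler chained across candidate
trees. It reports the meta-analytic mean μ, the size-on-colour
meta-regression slope b, heterogeneity I², and phylogenetic signal.

## Worked example

Run the whole chain on a synthetic study (8 species here for speed):

```bash
aviantrends run-all --seed 1 --n-species 8 --n-trees 130 --out scratch/demo
```

The per-species trend table (`scratch/demo/species_trends.csv`) holds
one row per species with EDF, β, SE, df, t, p for both traits. The meta
summaries printed at the end begin:

```
== wing ==
posterior sample size: 100
  intercept    -0.00814  95% CI [-0.03393, +0.01587]  pMCMC 0.5
  I^2          0.966  95% CI [0.909, 0.992]
  phylo signal 0.239  95% CI [0.000, 0.786]
```

Read: across species, wing length changed by −0.008 mm/year on average
(the planted meta-mean in this simulation is −0.01), the credible
interval spans zero (no consistent trend claim at k = 8, where the weak
variance priors keep intervals wide), most between-species variance is
not attributable to sampling error, and the phylogenetic signal is
weakly identified — exactly what a small study should say.

The meta-analytic stage can also be run directly on a published-style
trend table (species, wing_beta, wing_se, colour_beta, colour_se); a
table of the 15 Meliphagoidea species' published slopes is bundled:

```bash
aviantrends meta --n-trees 1030 --burnin-trees 30 --seed 1
```

which prints, for the wing model:

```
== wing ==
posterior sample size: 1000
  intercept    -0.00767  95% CI [-0.01969, +0.00573]  pMCMC 0.208
  I^2          0.907  95% CI [0.819, 0.966]
  phylo signal 0.145  95% CI [0.000, 0.597]
```

i.e. a weak, non-significant average decline in wing length of about
0.008 mm/year with very high heterogeneity: species disagree strongly
about both direction and magnitude of change, so no common driver —
dietary or otherwise — explains the size trends, and the wing-on-colour
meta-regression slope (`== regression ==` block) is likewise null.

## Layout

| module | role |
|---|---|
| `specimen_data` | specimen table / spectra IO, curation, repeatability |
| `visual_model` | receptor-noise model: catches, ΔS, jnd coordinates, chroma |
| `chromatic_pca` | per-species PC1 colour score with chroma sign anchor |
| `temporal_models` | mixed models, RAC, Moran's I, variance structures, GAMM EDF |
| `phylo_meta` | Bayesian phylogenetic meta-analysis, I², signal, meta-regression |
| `synthetic_data` | ground-truth study generator (trees, slopes, specimens, spectra) |
| `pipeline` / `cli` | orchestration and the `aviantrends` command |

See `docs/methods.md` for the models, defaults, numerical choices and
limitations.
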