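# Methods

`moundscape` reimplements, as a tested library, an analysis chain that links
satellite-derived environmental measurements to individual fitness,
population fitness, and population size in a near-exhaustively sampled
population of banner-tailed kangaroo rats (*Dipodomys spectabilis*).  This
note documents the models, the defaults and their units, what the synthetic
data generator does and does not emulate, and the numerical and design
choices a maintainer would want spelled out.

## The analysis chain

**Scenes.** Inputs are Landsat-5-TM-like Collection 2 Level 2 products on a
30 m grid: six surface-reflectance bands (b1–b5, b7) and one surface
temperature band, all stored as digital numbers.  DNs are converted with
the published affine scalings (reflectance = DN·0.0000275 − 0.2;
Kelvin = DN·0.00341802 + 149), the fill sentinel (DN 0) is masked first,
and scaled reflectance outside a plausibility interval (default
[−0.2, 1.6]) is masked with a warning.  Scenes are cropped to the site
extent with edges snapped *outward* to whole cells, so a 2100 m × 2750 m
request yields 70 × 92 cells — never discarding a cell that intersects the
request.  Manual cloud screening is replaced by an exclusion list in the
scene catalog (`excluded` flag + mandatory reason), and a per-path scene
mean series supports the bias diagnostic that motivates restricting the
series to one WRS path.

**Indices.** The Tasseled Cap transformation recombines the six reflectance
bands into brightness (bare-soil albedo), greenness (photosynthetic
vegetation) and wetness (soil/vegetation moisture).  Coefficients are the
Crist (1985) reflectance-factor set for TM bands 1, 2, 3, 4, 5, 7,
transcribed into `tc_coefficients.py` and guarded by sign-structure tests
(brightness all positive; greenness negative on visible, positive on NIR).
Each index is z-transformed by pooling **all** non-masked cells of the
cropped extent across **all retained scenes** (sample SD, n−1).  Pooling
over the full crop is the most literal reading of "all cell values across
all years"; the normalization constants are recorded on the stack so the
transform is invertible.  Surface temperature stays in physical units —
models report °C, and `scale_temperature` exposes a Kelvin switch.

**Geolinking.** Mounds with GPS coordinates drop directly into cells via a
half-open convention (row 0 north, col 0 west; a point on a shared corner
belongs to the cell whose north-west corner it is).  Mounds mapped only in
the historical meter-based site frame are registered by a least-squares
similarity transform (Umeyama; translation + rotation + optional uniform
scale — a surveyed meter grid should preserve angles, so shear is excluded
by default) fitted on the mounds carrying both systems, with a manual
override table for corrections.  Registration RMS above 15 m (half a cell)
warns.  A female's home range is the 3×3 block centered on her mound cell
(center-to-outer-corner distance 45·√2 ≈ 63.6 m); the active landscape of
a year is the deduplicated union of 3×3 blocks over all cells holding a
mound where an adult female was captured.  Edge-truncated blocks keep
whatever cells exist.

**Temporal aggregation.** Covariates are lag-aligned by six months: the
annual window predicting offspring produced in year *t* runs July 1 of
*t*−1 through June 30 of *t*; survival windows for year *t* equal offspring
windows for *t*+1.  Within an annual window, per-scene unit means are first
averaged within each meteorological season (DJF/MAM/JJA/SON; July–August at
the window start pools with June at its end into one summer bucket — a
`split_summer` variant was considered and rejected as a second knob with no
data to pick between them) and the season means are then averaged, so
unevenly timed scenes cannot bias the annual covariate.  Seasons with no
scenes are *omitted* from the outer mean, never imputed, and the summary is
flagged.  Rainy-season windows are plain means over July–August (summer)
and December 1 – March 31 (winter; the inclusive March boundary matches the
"December–March" convention).  The daily climate series (site-level
precipitation and air temperatures, PRISM-like) is summarized the same
three ways so predictor tables are structurally uniform, and enters only
population-level models — a single site-wide value carries no
individual-level signal.

**Demography.** An adult female is "alive in year t" iff captured as an
adult in year t (justified by the near-exhaustive sampling design, ~98%
adult capture probability).  Her offspring count is the number of pedigree
entries naming her as dam with that birth year — zero counts included,
which is the pedigree's key advantage over abundance proxies.  Survival to
age one is operationalized as recapture in any session of year t+1 and is
defined only for females with ≥ 1 offspring; if year t+1 has no capture
data the value is missing.  The primary mound is the modal capture mound
(ties: earliest capture date, then lexicographic id).  "Active mound" has
two deliberate senses, both computed: any-resident mounds (the
population-size proxy) and female-occupied mounds (the seed of the active
landscape).  Census size is distinct individuals captured; change in
population size is ΔN = N_t − N_{t−1} and ΔN/N_{t−1}.

**Inference.** Individual fitness uses log-link Poisson and NB2 GLMs
(`statsmodels`; θ = 1/α estimated by ML, AIC counts it as a parameter).
Backward stepwise elimination removes the single largest-Wald-p predictor
while any p ≥ α (default 0.05), never the intercept; AIC is recorded at
every step but selection is p-driven.  Ties within 1e-12 remove the later
column so builds are deterministic.  Final Poisson and NB fits are compared
by likelihood-ratio test with df = 1 and no boundary correction (a
halved-p option exists), matching common practice for this comparison.
Pearson χ²/df is reported as the dispersion diagnostic, never auto-acted
on.  GVIF is computed from determinants of the predictor correlation
matrix and reduces to classical VIF for single-column terms.  Repeated
measures use an NB2 random-intercept model written in-package (no Python
library provides one): marginal ML by fixed-node Gauss–Hermite quadrature
(25 nodes), optimized over (β, log α, log σ) with L-BFGS-B, standard errors
from a numerical Hessian.  It was validated against `glmmTMB` on a frozen
fixture (coefficients to 3–4 decimals).  Convergence reporting is honest:
optimizer failure, a non-positive-definite or ill-conditioned Hessian, a
collapsed random-intercept SD (σ < 0.01 or no likelihood gain over the
fixed-only fit), or the dispersion parameter running to the Poisson
boundary (α < 0.002, which leaves σ² and α on an unidentifiable ridge) all
set the `singular`/`converged` flags.  Population-level responses (≈13
annual points) use single-predictor OLS with two-sided permutation
p-values on the slope: the response is shuffled n_perm (default 1000)
times and p = (1 + #{|β_perm| ≥ |β_obs|})/(1 + n_perm), the add-one form
that can never return zero; a t-statistic variant is available by flag.
Effect displays hold non-focal predictors at their sample means and use
Wald intervals on the link scale, exponentiated.

Missing covariates are handled by listwise deletion with a logged count.
All randomness flows from explicit seeds; permutation results record
theirs.

## The synthetic study generator

The generator exists so every stage is verifiable against known truth
without downloads.  Its defaults are the study's dimensions: 13 July–June
scene-years from July 1993, 13 scenes/year (169 total, approximating the
167-scene series), a 70 × 92-cell 30 m grid, 214 mounds of which 188 carry
GPS (the rest only site-frame coordinates under a known 12° similarity
transform), ~37 adult females per year (~476 female-years), and offspring
counts drawn from the exact NB2 log-link model the inference layer assumes,
with true β = 0.36 (brightness, per pooled-z unit), 0.04 (surface
temperature, per °C), 0 (greenness, wetness), intercept −0.72 and θ = 2 —
effect magnitudes and intercept chosen to match the scale of the
individual-fitness estimates this kind of data yields.  A `frailty_sd`
switch adds lognormal frailty for misspecification experiments.

Scene fields: surface temperature is an annual sinusoid (default mean
20 °C, amplitude 15 °C, peaking early July) plus a persistent spatial
field, a per-scene anomaly, and pixel noise, each with its own SD knob;
brightness and wetness share a common latent component sized so their
pooled correlation is the 0.9 target; greenness is a weak, slightly
counter-seasonal signal.  Index targets are mapped to six reflectance
bands through the Tasseled Cap pseudo-inverse (the least-norm band vector
reproducing the target indices), quantized to integer DNs, and emitted as
multiband TIFFs with world files — so ingestion, rescaling and the
transform are exercised end to end, and the round trip recovers the fields
to one DN of quantization.  The population simulator gives each adult a
mound (one resident per mound, females philopatric across years), draws
per-female offspring from her own 3×3-window annual covariates, survives
offspring to the next year by a logistic rule (default intercept −0.4,
i.e. ~40% survival), and emits captures (two adult sessions/year, juvenile
capture in the birth year, survivor capture the following year) and the
pedigree.  Annual recruitment targets are Poisson-distributed around the
configured means, so adult numbers, census size and active-mound counts
fluctuate between years — without that variation the population-level
regressions would face a degenerate (constant) predictor.  Capture thinning (0.98 adult / 0.93 juvenile, mirroring the
field protocol) is available but defaults to off so bookkeeping round
trips are exact.  The daily climate series is bimodal: July–August carries
~50% of annual precipitation, December–March ~30%, with sinusoidal air
temperatures satisfying tmin ≤ tmean ≤ tmax by construction.  One seed
reproduces every table and scene byte-for-byte.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: cloud contamination and scene-quality
heterogeneity, atmospheric and sensor artifacts, spatial autocorrelation
between neighboring home ranges beyond the smooth latent fields, density
dependence, dispersal behavior, pedigree errors, and any mismatch between
recapture and true survival.  Recovery results certify the *pipeline*, not
the ecology.

## The recovery experiment

Each replicate simulates a full study, then re-derives everything through
the analysis path itself — rescaling the DN scenes, recomputing and
re-z-scoring indices, re-registering mounds from coordinates, recounting
fitness from captures + pedigree, rebuilding the covariate table — and
fits the four-predictor NB model plus the stepwise reduction.  Coverage
and bias are evaluated on the full (pre-selection) fit: confidence
intervals conditioned on a term surviving stepwise selection are distorted
by the selection event itself, so the stepwise run exercises the selection
machinery while the recovery verdict comes from the well-defined
estimator.  At the default scale (100 replicates, ~480 female-years each)
the 95% Wald intervals for the brightness and temperature effects cover
truth in ≥ 90/100 replicates and the absolute bias is far below half a
standard error.  The whole experiment runs in about two minutes on one
CPU; the acceptance script (`scripts/acceptance.py`) repeats it from
scratch at exactly these sizes.

## Numerical notes and limitations

* Masked cells propagate: a cell masked in any reflectance band is masked
  in every index, and unit means use non-masked cells only.
* The z-transform is computed in float64 even when scene arithmetic is
  float32, so pooled output moments are 0/1 to ~1e-12.
* An all-zero count response is a boundary case (log-link mean → 0): the
  GLM returns a flagged degenerate result (−∞ intercept, `converged=False`)
  with a warning instead of iterating.
* The Gauss–Hermite quadrature (25 nodes) is accurate for random-intercept
  SDs well past anything these data produce; it is not adaptive, so very
  large σ with very large group counts would need more nodes.
* The 2750 m site height is not a multiple of 30 m; outward snapping makes
  the 92-row choice explicit rather than recovering whichever convention
  the original crop used.
* Permutation p-values are Monte-Carlo estimates; with 1000 shuffles the
  smallest attainable value is 1/1001.
* No atmospheric correction, cloud-mask algorithmics, reprojection,
  resampling, other spectral indices, pedigree inference, mark–recapture
  modeling, spatial autocorrelation modeling, or model averaging: all are
  out of scope by design.
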