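# Methods

## The model

Every imaging feature — a functional connection (Fisher-z FC), a node's
D1 binding potential (BP), or a node's gray-matter density (GMD) — is
modelled independently across subjects with a location-scale
("heteroscedastic") age model:

    y_sj = z_sj + ρ_j · FD_s
    z_sj ~ Normal( μ_j(a_s), σ_j(a_s) )
    μ_j(a)       = α_μ + β_μ · a
    log σ_j(a)   = α_σ + β_σ · a

where `a_s = age_s − 20` years and `FD_s` is the subject's mean
framewise displacement (mm). β_μ is the change per year of age in the
feature's mean; β_σ is the change per year in its log standard
deviation, so the between-person SD changes by a factor exp(β_σ) per
year. ρ absorbs a linear motion effect on the measured value. The model
is cross-sectional by construction: "aging effects" are age-group
differences, not within-person change.

Parameters vary per feature, not per subject — a per-subject parameter
set would not be fittable from one observation per subject.

### Estimation

Per feature, maximum a posteriori with independent normal priors
centered at 0. The study design this mirrors constrains only the priors'
shape and centering ("weakly informative, normal, symmetric around 0"),
so the scales are package defaults, configurable and recorded in run
metadata:

| parameter | prior SD | rationale |
|---|---|---|
| α_μ, α_σ  | 10   | effectively flat on plausible intercepts |
| β_μ, β_σ  | 0.1  | per-year slopes beyond ±0.3 are not credible |
| ρ         | 0.1  | z-units per mm mean FD |

The negative log posterior (additive constants dropped) is

    Σ_s [ (α_σ + β_σ a_s) + (y_s − ρ FD_s − α_μ − β_μ a_s)² / (2 e^{2(α_σ+β_σ a_s)}) ]
    + Σ_p p² / (2 s_p²)

minimized by L-BFGS-B with analytic gradients, initialized at the OLS
intercept/slope, the log ML residual SD, and β_σ = ρ = 0. `fit_map`
adds 4 jittered restarts (seeded; best objective wins, ties to the
first found); `fit_all` uses a single start per feature because the
objective has proven unimodal in practice at cohort sizes of interest,
and fits ~1,800 features in under 20 s. Parameters can be pinned
(`fixed={"beta_sigma": 0, "rho": 0}`), which reduces the flat-prior MAP
exactly to OLS — the main analytic oracle in the tests. Features with
zero variance or a single distinct age are fitted but flagged
unidentifiable and excluded from sign-fraction summaries. Non-finite
parameter proposals return a large finite objective so the optimizer
can retreat.

`FD_s` enters as the post-scrub mean FD (configurable to pre-scrub): it
is the motion summary that describes the frames actually used. ρ is
estimated per feature; a single global ρ would require a joint fit
across tens of thousands of features that nothing here needs.

## The synthetic cohort

The generator emulates a two-age-group cross-sectional design: 30
younger (age ~ N(24.2, 3.4²) y) and 30 older (N(70.8, 2.7²) y)
subjects, ages truncated below at 18 so that `a = age − 20` stays
interpretable. Per-group mean-FD motion traits are log-normal (medians
0.08 / 0.14 mm, log-SD 0.3; older adults move more). These motion
levels make the ≥300-volume inclusion rule exclude a handful of
subjects per run — the same order as the design being emulated — rather
than a third of the cohort.

Ground-truth edge parameters are drawn per connection:
α_μ ~ N(0.3, 0.25), β_μ ~ N(−0.001, 0.002) plus a shared node
component (see below), α_σ ~ N(log 0.15, 0.2), β_σ ~ N(0.004, 0.005)
plus a node component, ρ ~ N(0, 0.15). The signs are the point: most
connections lose mean FC with age, and most gain between-person
variance. ρ is centered at zero because residual motion effects on FC
in real data are bidirectional (sign depends on edge length); a
zero-centered ρ also keeps the β_μ estimator unbiased under the
prescribed priors, since FD is confounded with age in this design and
any systematic ρ would leak into β_μ through prior shrinkage of the
weakly identified motion coefficient.

A standard-normal node latent `u_n` couples modalities: edge slopes get
`0.5·(u_i + u_j)` times a coupling scale (β_μ: 0.0015, β_σ: 0.003), BP
slopes get `+0.002·u_n`, GMD slopes `−0.0005·u_n`. This makes average
nodal FC aging effects correlate positively with BP aging effects and
negatively (more weakly) with GMD effects — the qualitative cross-modal
pattern of interest — while the two pathways remain separable in a
joint regression.

### Time series

Each subject's target Fisher-z matrix is drawn from the edge model
(without the ρ·FD term — motion enters the series as actual artifact,
below), mapped through tanh, and projected to a valid correlation
matrix. Edge-marginal targets are generally *not* jointly realizable;
the projection (one-shot eigenvalue clipping by default, iterative
nearest-correlation optional) is applied before sampling and its
Frobenius distance is reported on the output. BOLD-like series are then
multivariate normal with that population correlation, plus AR(1) WM and
CSF signals leaking into every ROI, plus motion: a random-walk jitter
trace calibrated so the expected FD equals the subject's motion trait,
and Bernoulli spike events that add step displacements to the trace and
a shared artifact burst to every ROI — giving scrubbing and confound
regression something real to remove.

### PET and GMD

Target TACs follow the simplified reference tissue model (SRTM) with a
bi-exponential bolus reference curve (amplitude 10, uptake 4/min,
washout 0.05/min), R1 = 1, k2 = 0.15/min, and per-subject DVR = 1 + BP
drawn from the nodal age model (clipped at BP ≥ 0; rare under the
defaults). The SRTM solution is a sum of exponentials, so frame
averages are computed in closed form; the tests check it against an
independent ODE integration. Frame noise is Gaussian with SD
∝ √(activity/duration), the usual count-statistics scaling. GMD tables
are drawn directly from the nodal model.

### What the generator does not emulate

No hemodynamic response, no spatial structure or distance-dependent
motion artifact, no task regressors, no voxel level, no scanner drift
beyond what the band-pass removes, no attenuation/decay physics in PET,
and edge targets are realizable only after projection. Passing tests
therefore demonstrate that the estimators recover the stated generative
structure under realistic noise and motion — not that real data meet
these assumptions.

## Pipeline choices

- Order of operations: confound regression → band-pass → correlation on
  scrubbed frames (scrubbing as frame selection at the correlation
  step). The underlying toolchains differ on the internal order; this
  one is a documented package decision.
- FD per Power: Σ|Δtranslation| + 50 mm · Σ|Δrotation|, FD₀ = 0;
  rotations are radians in motion files.
- Scrubbing removes flagged frames, 1 before and 2 after, windows
  clipped at series ends. Inclusion comparisons are exactly "≥ 300"
  (task rule) and "> 130" (resting-state rule).
- Confounds: intercept + 6 motion parameters + backward-difference
  derivatives (first row 0) + squares of those 12 + WM + CSF, plus the
  plain global mean under GSR (no GSR derivative/square — unstated in
  the source procedure, minimal reading used). Collinear columns are
  dropped with a warning.
- Band-pass: zero-phase ideal frequency-domain mask over 0.009–0.1 Hz,
  DC removed; the contract is stated in passband/stopband terms so an
  IIR implementation would be equally conformant.
- r is clamped at ±(1 − 1e−7) before arctanh; the diagonal is stored as
  0 and excluded everywhere downstream.

## Similarity and MDS

Similarity is Pearson r over the n(n−1)/2 upper-triangle z values.
Dissimilarity for classical MDS is 1 − similarity — the source
procedure does not state its transform; 1 − r is the minimal monotone
choice and is configurable by passing any dissimilarity matrix.
Negative eigenvalues of the double-centered matrix are truncated; if
fewer than the requested dimensions are positive, the available ones
are returned with a warning. Group t tests are Welch tests on pair
similarities; pairs sharing a subject are not independent, so those
p values reproduce the mirrored procedure and should be read as
descriptive. Removal rankings break ties by edge index for
reproducibility; the fraction grid and random baseline are parameters.

## Logan analysis

Non-invasive Logan without the k2′ intercept-correction term by
default (the plain graphical method is the one mirrored); passing a
reference efflux constant `k2_ref` switches to the corrected abscissa
for sensitivity analyses. Frame activities are treated as
frame-averaged values located at midpoints; integration is trapezoidal
from an activity-0 anchor at t = 0; window membership is by midpoint ∈
[18, 55] min. The default 18-frame schedule (9×2, 3×3, 3×4.2, 3×5 min)
totals 54.6 min; "4.20 min" frames are read as decimal minutes. On
noiseless SRTM curves with BP = 1.5 the Logan slope sits within 2% of
the true DVR 2.5 (the late-time linearity is not yet exact at k2a ≈
0.06/min), and it is exact to machine precision for proportional
curves. DVR is invariant to common rescaling of both curves and linear
in rescaling of the target. Cerebellar ROIs never appear in BP tables —
the reference region cannot be its own target.

## Cross-modal association

Average nodal β is the arithmetic mean of an edge parameter over the
n−1 edges incident to the node (nodes weighted equally; degrees are
uniform here). Partition assignment is argmax over user-supplied
probability tables (region mode) or mean-map-value × ROI-size scores
(network mode), ties to the first label with a warning. The joint
regression reports raw and standardized (z-scored, population SD)
coefficients with two-sided OLS p values and R²; predictors with
|r| > 0.999 are rejected. No multiple-testing correction is applied,
matching the reporting style mirrored. Nodes excluded from FC analysis
and cerebellar nodes are dropped pairwise per comparison.

## Problem sizes and determinism

The shipped study uses 60 subjects, a 60-node connectome (1,770
connections), 400 volumes at TR 2 s, and one PET + GMD table per
subject — sizes chosen so the complete chain, including ~1,900 MAP
fits and 3,600 Logan fits, reruns in well under a minute. The fitters
scale linearly in features; 33,930 connections × 57 subjects is a
desk-scale run. One global seed drives everything; stage seeds are
derived from it by name, and two runs with the same configuration are
byte-identical (checksums in the run manifest verify this).

## Known limitations

- Cross-sectional only: β's conflate aging with cohort and selection
  effects; the variance model cannot see individual trajectories.
- MAP point estimates only; no posterior uncertainty per feature.
- The correlation-matrix projection means the per-edge generative law
  holds only approximately for time-series-based runs (exactly for the
  direct edge-value generator).
- Welch tests on non-independent pair similarities (flagged above).
- The Logan estimator carries the familiar small negative bias at
  finite washout rates and under noise; the 18–55 min window does not
  remove it entirely.
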