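# Methods

This note documents the models, estimators, numerical choices and
limitations behind `famech`. Everything quantitative stated here is
computed by the test suite or the analysis drivers; nothing is asserted
that the code does not reproduce.

## Micropost traction mechanics

Each elastomeric micropost is an independent cantilever. A lateral tip
deflection δ maps to force by Euler–Bernoulli beam theory,

    F = δ · 3πED⁴ / (64 L³),

with E the Young's modulus of the post material, D the diameter and L
the height. Units are µm/nN/Pa at the API surface; the formula is
evaluated once in SI and converted (1 N/m = 10³ nN/µm) in a single
function, so no unit factor appears anywhere else.

The published array table gives (L, D, k) for three arrays labelled by
effective substrate stiffness (5/14/25 kPa) but not E. We calibrate E
by inverting the beam formula on the 5 kPa row (E ≈ 2.50 MPa) and use
that single modulus for all arrays: it reproduces the other two printed
spring constants to 0.1% and 0.01% (`analysis/01_post_mechanics.py`),
which is strong internal evidence that one elastomer batch and one
formula underlie the table. The registry stores both the printed spring
constants and the calibrated modulus; it does not attempt to derive the
kPa labels from the spring constants, since the label convention is a
separate (unstated) effective-modulus mapping.

Deflection extraction from post-grid images: intensity-weighted
centroids in a half-pitch window around each lattice node (median
background subtracted; empty windows mark the post missing rather than
zero). The reference lattice is registered to the detected positions by
a least-squares rigid fit (Kabsch rotation + translation) over posts
classified as non-contacted, iterating fit → reclassify (|δ| below a
0.1 µm noise floor) → refit for 3 rounds. At least 4 reference posts
are required. Image coordinates are origin top-left, x right, y down,
pixels scaled by an explicit µm/px factor.

## Coupling statistics

Coupling of a per-FA readout (integrated tFAK or pY397-FAK intensity)
to force is the two-sided t-test on the OLS slope of intensity against
force magnitude, pooled over FAs from multiple cells, significant at
α = 0.05. No clustering correction or multiple-testing adjustment is
applied across channels — the estimator mirrors pooled-FA regression
practice for this assay. A constant readout returns slope 0 with p = 1
directly (the degenerate OLS t-statistic is numerically meaningless
there).

Model adequacy is assessed by AICc between the 2-parameter line and a
4-parameter logistic I = bottom + (top − bottom)/(1 + e^−(F−F50)/s),
fitted by least squares from 5 starts spread over the force quantiles,
with the span parameterized non-negative so bottom ≤ top. Parameter
counts include the residual-variance parameter (k = 3 and 5); only
AICc differences matter for the Akaike weights, which are reported as
model probabilities. A non-converging logistic is reported as failed
and the line wins by default, flagged.

Group comparisons follow the standard screening cascade: Shapiro
normality and Levene variance checks select one-way ANOVA (t-test for
two groups), Welch's ANOVA (hand-implemented; Welch t for two groups),
or Kruskal–Wallis (Mann–Whitney for two groups). Post-hoc pairwise
comparisons use Dunn's rank z-tests with tie correction and Holm
adjustment (implemented in-package; no installed library provides
them). Zero-variance or n < 3 groups force the nonparametric branch
with a warning.

Spatial heatmaps accumulate intensities on a configurable grid and
smooth with a Gaussian kernel of sd 3 grid units (the convention for
these maps; the sd is interpreted in grid units because no physical
unit is attached to it). `mode="constant"` convolution conserves total
intensity to <1% for sources ≥3σ from the borders.

The magnetic-puller stiffness estimate is force/displacement with an
explicit pN→nN conversion: 30 pN over 0.3–1 µm gives 0.03–0.1 nN/µm,
two orders of magnitude below the posts' 7–18 nN/µm.

## Talin–FAK kinetic model

Species: unstretched talin T, stretched talin T_st, free FAK F, complex
FT_st, phosphorylated complex pFT_st. Mass action gives

    dT_st/dt  = k1·T − k2·T_st − k3·T_st·F + k4·FT_st
    dFT_st/dt = k3·T_st·F − k4·FT_st − k5·FT_st + k6·pFT_st
    dpFT_st/dt = k5·FT_st − k6·pFT_st

with conservation T_total = T + T_st + FT_st + pFT_st and
F_total = F + FT_st + pFT_st eliminating T and F, and the Bell relation
k1 = k1o·e^(αf) coupling force to the stretch rate. α carries units
pN⁻¹ so the exponent is dimensionless; f is treated as force per talin
molecule. The Bell exponent is capped at 50 (with a warning) purely as
an overflow guard.

The original parameter table is not available, so a documented base set
is adopted and required to reproduce all qualitative regimes:
T_total = F_total = 100 molecules, k1o = 0.1, k2 = 10, k4 = k5 = k6 = 1
(s⁻¹), k3 = 0.02 molecule⁻¹s⁻¹, α = 0.05 pN⁻¹, forces 7–11 pN (the
physiological per-talin load window). With this set (all config-driven,
nothing hard-coded):

- T_st, FT_st and pFT_st all increase linearly with force (OLS
  R² > 0.999 over 7–11 pN);
- α = 0 (or α ten-fold smaller) makes the response force-independent
  (the relative pFT_st response at α = 0.005 is <10% of the α = 0.05
  response);
- a 100-fold k3 reduction collapses the absolute pFT_st force response
  to <5% of the base response ("flattening" is measured as the span of
  the curve over the force grid relative to the base span, because a
  near-zero curve can retain a deceptively finite *percentage* slope);
- increasing k4 ten-fold equals decreasing k3 ten-fold exactly (only
  k3/k4 enters the steady state);
- a 100-fold k5 reduction drives pFT_st to <0.1% of F_total while
  T_st and FT_st stay linear (R² ≥ 0.99) with relative force responses
  within 10% of base.

Steady states are found by a Newton-type root finder (MINPACK hybr) on
the reduced 3-variable system from 8 starts spanning the conservation
simplex; all converged non-negative roots must agree within 10⁻⁶·scale,
which doubles as a uniqueness check, and residuals must fall below
10⁻¹⁰·max(totals). Two independent oracles back the solver in tests: a
closed-form reduction (at steady state pFT = (k5/k6)·FT, hence
k3·T_st·F = k4·FT and T_st = (k1/k2)·T, collapsing everything to one
quadratic in FT_st — also used to seed the search) and long-time stiff
integration (Radau to t = 10⁴/min-rate). When no start converges the
integrator is the fallback. Sweeps report species absolute and relative
to their value at the smallest force in the grid (the "relative number"
normalization of force-response panels); alternatives are a flag away.

Degenerate corner: with k3 = k4 = k5 = k6 = 0 the complex species
decouple and every (FT, pFT) is stationary, so the steady state is not
unique; the relaxation oracle from the empty state defines the physical
answer (T_st/T = k1/k2) and the solver's uniqueness check correctly
refuses.

## Wound closure

The normalized gap-area profile is A(t) = amplitude·exp(−(ln(t/t_peak))²
/(2·log_width²)): zero at t→0⁺, peak `amplitude` at t_peak (recoil from
tissue pre-stress), log-normal decay to closure. Time zero is wounding;
the first fitted frame is the first post-wound frame because the
profile is undefined at t = 0. `amplitude` summarizes pre-stress;
`closure_rate` is defined as the maximum descent speed of the fitted
curve, which has the closed form: with u* the positive root of
u² + w²u − w² = 0 (w = log_width), the rate is A(t*)·u*/(w²·t*) at
t* = t_peak·e^(u*). Both functionals are properties of the fitted
log-normal only, isolated in `closure_rate_from_fit` so alternative
definitions can be swapped in. The exact functional the original
analysis used is unknown; recovery tests therefore target the
generator, not published per-tissue values.

Non-closing tissues (constant area, fitted t_peak beyond the
observation window, or descent below 1% of amplitude/duration) return
`converged = False` with rate 0 rather than a spurious fit.

Segmentation is threshold (absolute or Otsu) → tissue mask → holes
enclosed by the tissue (fill-holes difference); the gap is the summed
hole area (count reported when several), tissue width is the filled
mask's extent on the horizontal centerline. This is a deliberate,
faithful simplification of a brightness-threshold region-filling
routine, validated against analytic ellipse areas (<3% error, the
discretization limit of an ellipse on a pixel grid) and generator
ground truth (r > 0.99). Otsu makes it invariant to global intensity
scaling.

Contractile force is spring constant × summed cantilever displacement,
with the device constant k = 9.72 µN/µm taken as printed (its
finite-element derivation is out of scope). Displacements must be
baseline-subtracted against collagenase-released bead positions;
pre-wound and post-wound indices are explicit arguments because the
two baselines (pre-wound force level vs collagenase zero) are distinct
concepts and both are kept.

## Migration

MSD uses overlapping-interval time averaging per track, then a
count-weighted ensemble average; counts are reported so users can
reweight. Default maximum lag is half the shortest track (tail lags
carry few intervals). MSD(0) = 0 by construction; the estimator is
checked against a naive O(N²) double loop to 1e-12.

The PRW fit is ordinary (unweighted) nonlinear least squares of the
2-D Fürth form MSD(τ) = 4D(τ − P(1 − e^(−τ/P))) over lags in (0, 12] h
by default; S = sqrt(2D/P). The 4D prefactor follows from 2-D tracking
(image-plane projections). In the Brownian limit the fitted P pins at
or below the smallest resolvable lag — documented behavior, asserted in
tests, not silently hidden. Speed is mean frame-to-frame displacement
over dt (which sits below the nominal RMS speed by the Rayleigh-mean
factor √(π/4) on OU tracks — the tests pin this against brute force
rather than "correcting" it); straightness is net displacement over
path length. No drift correction is applied by default since bulk
tissue motion is a real signal; an ensemble-mean subtraction is
available.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for every recovery test:

- **Per-FA datasets**: forces uniform on [0, 15] nN (per-FA force
  histograms are not published; uniform maximizes regression leverage
  without assuming a shape), intensities linear in force with Gaussian
  noise whose sd is set *analytically* from the target R²
  (sd = slope·sd(F)·√(1/R² − 1)), so recovery tests are self-consistent
  rather than tuned. Defaults: n = 66 FAs, R² = 0.6, the published
  control line (194.6 AU/nN, 1178 AU). Uncoupled regimes draw
  force-independent log-normal intensities matched to the coupled
  regime's mean and total variance (intensities are positive and
  right-skewed). Deflections are back-computed from force through the
  attached post geometry.
- **Bead assays**: ratio = slope·force + intercept + N(0, 0.2) at
  forces {0, 10, 30} pN, 3 replicates — the published force levels and
  replicate count.
- **Wound series**: the log-normal profile plus N(0, 0.05), clipped at
  0, on a 0.5 h grid over 24 h. The `area_norm` column is area
  normalized to the initial wound area; the generator emits the profile
  directly (amplitude = peak) rather than rescaling the first frame to
  exactly 1, because the rescaled series would no longer round-trip the
  generating amplitude.
- **PRW tracks**: exact discrete OU velocity updates
  (v ← v·e^(−dt/P) + η·σ_v·√(1−e^(−2dt/P)), σ_v = speed/√2 per
  component) with Euler position sums — the continuous model whose MSD
  is the Fürth curve, simulated on velocity rather than turning angles.
  Defaults: 30 µm/h, P = 1 h, 200 cells, 48 h at 0.5 h frames (the
  imaging cadence). The Euler position sum biases the apparent
  diffusivity by (dt/2P)-order terms (≈+2% at dt = 0.5, P = 1), well
  inside the 20% recovery band.
- **Images**: Gaussian spots on a lattice and rectangle-with-ellipse
  wound frames, with ground truth returned alongside. No PSF,
  bleaching, depth attenuation or realistic intensity scales: passing
  the image tests shows the centroid/segmentation operators are
  correct, not that they are robust to real microscopy artifacts.

All generators are `numpy` `default_rng`-seeded; identical seeds give
bit-identical outputs, and pipeline stages derive their seeds from a
global seed plus the stage name (SHA-256, reduced mod 2³¹).

## Problem sizes

Monte-Carlo sizes used throughout (tests and the acceptance script) are
chosen so sampling error sits far inside each tolerance band: 200 seeds
for FA-slope recovery (per-fit slope SE ≈ 10% of the slope at n = 66,
R² = 0.6, so the 200-seed mean has SE ≈ 0.7%), 500 seeds for bead
slopes, 100 seeds for R² and type-I checks, 50 for wound recovery, 10
seeds × 200 cells for PRW recovery, 20 random draws for the
solver-vs-integrator oracle.

## Known limitations

- The published biological regression statistics cannot be reproduced:
  the raw single-FA, Western-blot and microtissue data are not
  deposited. Recovery tests target generators parameterized to the
  printed fit lines, which validates the estimators, not the biology.
- The kinetic base parameter set reproduces qualitative regimes only;
  the original quantitative curve shapes are unrecoverable without the
  original parameter table.
- No spatial or stochastic (Gillespie) kinetics, no motor-clutch
  coupling, no explicit vinculin species (its contribution is lumped
  into the stretch rates k1/k2).
- Segmentation and centroid detection are validated on synthetic
  fixtures only; no claims about real micrographs.
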