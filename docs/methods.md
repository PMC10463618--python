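# Methods

## Signal model and preprocessing

The unit of analysis is one subject's anterior–posterior CoP displacement
x[n], recorded during 30 s of quiet stance at fs = 3000 Hz under one of four
conditions (SEO/SEC/UEO/UEC).  Only the sagittal direction is analyzed;
medio-lateral sway is out of scope.  Preprocessing is a least-squares linear
detrend followed by a zero-phase low-pass Butterworth filter (order 4,
10 Hz cutoff, applied forward–backward with `scipy.signal.sosfiltfilt`, so
the effective magnitude response is the squared Butterworth magnitude and no
phase distortion is introduced).  Detrending precedes filtering; a mean-only
detrend is available via `detrend_mode="mean"`.  The linear detrend was
chosen over mean removal so that slow drift (electrode/plate creep, postural
re-settling) does not masquerade as very-low-frequency sway in the deepest
wavelet levels.  Non-finite samples are a hard validation error, never
interpolated: silent imputation would bias the energy estimates the whole
method rests on.  Trials of any length ≥ 2 samples are accepted (a warning
is issued away from the nominal 30 s); the CoP displacement unit is
irrelevant downstream because relative energy is scale-invariant.

## Maximal-overlap wavelet decomposition

The preprocessed signal is decomposed with an undecimated (maximal-overlap)
dyadic filter cascade of J = 16 levels.  The analysis filters are an
orthonormal wavelet pair rescaled by 1/√2 (h̃ = h/√2, g̃ its quadrature
mirror), the default family being the symlet of order 4 (`sym4`,
configurable to db2–db8 and sym2–sym8).  Boundary handling is circular,
which makes two identities exact rather than approximate:

* **Energy conservation** — Σ_j ‖W_j‖² + ‖V_J‖² = ‖x‖² (observed relative
  error ~1e-12), because the rescaled filter pair satisfies
  |H(f)|² + |G(f)|² = 1 and the per-level transfer functions telescope.
* **Additive reconstruction** — the per-level multiresolution components sum
  back to the input (observed max error ~1e-11).

The cascade is evaluated in the frequency domain: the level-j detail
transfer function is G(2^{j-1}f) · Π_{l<j} H(2^l f) applied via FFT, which is
algebraically identical to circular time-domain convolution with upsampled
filters and costs O(N log N) per level.  Transfer functions are cached per
(length, levels, family).

At fs = 3000 Hz the level-16 scale spans 2^16 ≈ 21.8 s against 30 s of data;
the transform warns that the deepest components are weakly localized but
proceeds, since the 16-level configuration is exactly what separates the
very-low-frequency strategies of interest (fewer levels collapse everything
below ~0.1 Hz into one number).  Nominal bands are the ideal dyadic edges
(detail j ↦ [fs/2^(j+1), fs/2^j], approximation ↦ [0, fs/2^(J+1)]); they
tile [0, Nyquist] exactly and are the semantics used for band labeling and
synthesis.  Real wavelet filters leak across these edges — a pure sinusoid
localizes to its nominal level to within ±1 level (`band_localization_check`
verifies this), and measured relative energies differ from ideal-band
energies by roughly 1–2 percent points.

Relative energy divides each component's coefficient energy by the total
over **all 17 components** (16 details plus the approximation), expressed in
percent; the 17-vector sums to 100 by construction and is invariant to
scaling and to circular shifts of the input.

## Clustering and archetype labels

Subjects are clustered on their SEO 17-vectors only (the other conditions
feed the descriptive reports); the percent scale is used directly, with no
re-standardization, since the simplex normalization already puts all
components on a common scale.  The default method is Lloyd's k-means with
k-means++ seeding, 50 restarts and a fixed recorded seed, minimizing the
within-cluster sum of squares (WCSS); the per-iteration WCSS trace is kept
(it is non-increasing) and the best restart is returned.  On instances small
enough to enumerate exhaustively (n ≤ 8, k ≤ 3) the returned WCSS equals the
global optimum.  A k-medoids variant (Voronoi iteration, centers restricted
to observed subjects) is available behind `method="kmedoids"` because both
conventions exist in practice for this analysis; k-means is the default.
k = 3 is imposed by design — the method asks whether three strategy
categories (low, broadband, high) are recoverable — not selected from the
data.

Fitted centroids are labeled by energy-archetype rules: mean energy over
{D15, D16} > 20% ⇒ group 1; every component of D11..D16 strictly inside
(10%, 20%) ⇒ group 2; mean energy over {D11, D12} > 20% ⇒ group 3.  The
rules are observations turned into a procedure, so two conventions had to be
chosen: dominance rules take precedence over the range rule (group3 >
group1 > group2) when a centroid satisfies several, and a named label is
granted to at most one cluster (largest rule margin wins; the loser becomes
`unclassified`).  The evidence behind every label (band means, margins) is
recorded in the output so conflicts are visible rather than silent.

## Multinomial logistic model

Group membership is regressed on the 24 covariates (x1 = FES-I score
16–64; x2 reaction time, ms; x3 eyesight; x4–x5 touch sensation, g;
x6–x11 proprioception errors, degrees; x12–x23 muscle strength, N·m;
x24 falls history, 0/1) with group 3 as the reference class.  The
(optionally ridge-penalized) multinomial log-likelihood is maximized by
Newton's method on the full stacked Hessian with step halving, so the
iteration trace is monotone; convergence requires a vanishing gradient.
Inference is Wald: standard errors from the inverse observed (penalized)
information at the optimum, two-sided normal p-values, 95% CIs as
estimate ± 1.96·SE, and a p < 0.05 significance flag.  No multiple-testing
correction is applied and covariates enter in raw units by default
(`standardize=True` re-fits on z-scores and back-transforms coefficients and
covariance; predictions are identical at penalty 0).

With ~45 subjects and 24 predictors the unpenalized MLE sits at or near
(quasi-)separation.  That fragility is reported, not hidden: complete
separation is detected as a zero final deviance (the gradient alone cannot
flag it, because a saturated softmax has vanishing gradient at finite
coefficients), non-convergence is returned as `converged=False` with a
message recommending `penalty > 0`, and the pipeline completes and writes
the coefficient tables either way, since enormous unstable coefficients are
themselves the expected outcome at this sample size.  The ridge penalty
applies to non-intercept coefficients only; the default is 0 (pure ML).

Simulation behaviour (recomputed by `scripts/acceptance.py`): over 200
datasets of n = 500 with 3 classes and 5 predictors, the maximum
per-coefficient mean bias is ≈ 0.03 and the empirical 95% CI coverage,
pooled over the 12 coefficients, is ≈ 0.95 (per-coefficient values ~0.93–
0.98; at 200 replicates a single coefficient's empirical coverage has
binomial noise of ±0.015, which is why the pooled figure is the stable
summary).

## Synthetic-data generator

The generator exists because the study-scale recordings it emulates contain
sensitive health data and are not publicly deposited; it reproduces the
*structure* the method consumes, not the biomechanics of sway (no inverted
pendulum, no intermittent control).

**Trials.**  White Gaussian noise is split into the 17 ideal dyadic bands by
discrete-frequency masks and each band is rescaled so its energy share
equals the target profile; the masks are deliberately not the wavelet
filters, so generator and analysis are independent and the residual
~1–2 pp mismatch is honest filter leakage.  Rescaling alternates with
least-squares line removal (8 iterations), making the output orthogonal to a
linear trend: without this, analysis-side detrending strips most of the
energy out of the one-or-two Fourier bins that make up the deepest bands
(D16 loses ~10 pp otherwise).  Output amplitude is set to RMS 5 (think mm);
scale is immaterial to every downstream quantity.  A 30 s record at 3000 Hz
is close to the minimum that gives every band at least one frequency bin
(D16 spans a single bin); shorter records raise an error when a low band has
a positive target.

**Archetype targets** are presets consistent with the labeling rules —
group 1: D15 = D16 = 24, D13 = D14 = 15, D11 = D12 = 8; group 2: 15 on each
of D11–D16; group 3: D11 = 24, D12 = 26 with a low-frequency remainder —
with the leftover share spread uniformly over the unnamed components, plus a
broadband "young" preset.  Exact vectors are design choices (the rules only
constrain ranges), and all are configurable.

**Condition shifts** emulate the move toward higher-frequency strategies in
challenging trials: a fraction of the energy in components whose nominal
band lies below 0.2 Hz (D14–D16 and the approximation; D13 straddles 0.2 Hz
and is left out) moves into D11–D12, split 35/65 in favour of D12 so that
strongly shifted profiles converge on a *measured* dominant level of D12
despite the down-level leakage of the analysis filters.  Defaults: 30%
under SEC/UEO and 50% under UEC for groups 1–2, 5% for group 3 — a
qualitative emulation of the adaptation pattern, not a fit to data.

**Per-subject jitter** perturbs the target shares with SD
`jitter·sqrt(eᵢ/10)` percent points (i.e. the nominal `jitter` applies to a
10%-share band; near-zero bands stay near zero), rejecting negative draws
and renormalizing; the default jitter = 1 keeps subjects well inside their
own archetype's rule region while giving visible within-group spread.

**Covariates** are drawn per group from truncated normals on each variable's
valid range (FES-I on [16, 64], physical measures on [0, ∞)), with the
underlying normal parameters moment-matched so the *truncated* distribution
has the configured group mean/SD.  Matching is infeasible for a few heavily
skewed entries (a truncated normal on a half line cannot have SD ≥ mean −
bound, e.g. touch-sensation values with SD ≈ mean); those fall back to
direct parameterisation and their realized moments shrink toward the bound.
`moment_matchable()` reports which entries are exact.  Covariates are
mutually independent (only marginal moments are configured); falls history
is Bernoulli with the group proportion.  Consequently, passing recovery
tests shows the pipeline recovers *spectral-energy structure* and
*marginal covariate structure*; it says nothing about performance under
correlated covariates, non-Gaussian sway, or within-trial nonstationarity,
none of which the generator produces.

## Pipeline, determinism and sizes

`run_pipeline` chains the stages, writes every intermediate
(`spectra.csv`, `assignments.csv`, two coefficient tables, `descriptives.csv`,
`condition_profiles.csv`) plus a manifest with the configuration, seed,
package version, per-stage counts, labeling evidence and model diagnostics.
Runs are deterministic given configuration and seed (byte-identical
outputs).  Subjects lacking the clustering condition (SEO) are excluded from
clustering and modeling with a logged warning; subjects in unclassified
clusters are excluded from the model only.  Presentation rounding happens
only at print time; CSVs keep full precision.

Default problem sizes — 45 subjects (15 per group), 180 trials of 90 000
samples, 16 levels, 50 k-means restarts, 200 model-recovery simulations of
n = 500 — run the full test suite in about a minute and the acceptance
script in a similar time on one CPU.

## Known limitations

* Printed non-dyadic band edges sometimes quoted for levels beyond the first
  (e.g. D2 as 338–832 Hz) have no dyadic derivation; this package uses ideal
  dyadic edges throughout and treats such figures as descriptive.
* Wald inference is asymptotic; at n = 45 with 24 predictors the CIs are
  decorative at best, and the package makes the instability visible rather
  than resolving it.
* The archetype rules leave a gap (spectra matching no rule are
  `unclassified`), which is a faithful consequence of turning three observed
  group descriptions into a total procedure.
* k-medoids and k-means can disagree on small samples; both are provided,
  k-means being the default convention.
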