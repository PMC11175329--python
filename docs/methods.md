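# Methods

`freezenir` re-implements, as a tested pipeline, an NIR-chemometrics workflow
for deciding whether fish tissue is fresh, once frozen-thawed, or twice
frozen-thawed from 900–1700 nm absorbance spectra. This note records the
models, the numerical choices behind them, what the synthetic generator does
and does not emulate, and the known limitations.

## Spectra and pretreatments

The carrier type `SpectraSet` holds a strictly increasing wavelength grid
(nm), an `n_samples x n_channels` absorbance matrix, unique sample ids,
optional class labels from `{fresh, frozen1, frozen2}`, and optional
metadata (fish piece id, dorsal/ventral region, replicate index). Files
declared as reflectance are converted to apparent absorbance `log10(1/R)` at
load; everything downstream operates on absorbance.

Two pretreatments are used, in two fixed roles:

* **Savitzky–Golay second derivative** (default window 11 channels,
  polynomial order 2) for classification. It removes baseline offset and
  slope and sharpens overlapping bands. The window/order are exposed in
  `PreprocessConfig`; 11/2 is a common choice for 512-channel NIR, and the
  robustness sweep (`analysis/04_robustness_checks.py`) shows held-out
  accuracy stable across windows 7/11/15 (93.9/99.0/98.0% on the default
  scenario). The derivative is taken per channel index and scaled by the
  mean wavelength step; edges are handled by the boundary polynomial fit, so
  no channels are lost. Exact for polynomials up to the fitted order
  (a quadratic maps to the constant second derivative).
* **Multiplicative scatter correction (MSC)** for aquagrams only. Each
  spectrum is regressed on a reference (the set mean) and replaced by
  `(x - b)/m`, removing per-sample gain and offset. MSC is idempotent
  against a fixed reference; spectra whose fitted slope is ~0 are rejected
  as degenerate.

The model artifacts record which pretreatment they were fitted on and
re-apply it to raw data at prediction time.

## SIMCA

One PCA model per class, fitted on the second-derivative spectra of that
class's calibration samples.

**Component count.** `k` is chosen by leave-one-out cross-validation with a
parsimony rule: the smallest `k` whose PRESS lies within 1% of the minimum,
capped at 15 components. The PRESS statistic is leverage-corrected:
for a held-out spectrum with residual `e` and loading leverages
`h_j = sum_m v_jm^2`, the fold contributes `sum_j (e_j/(1-h_j))^2` — the
exact leave-one-channel-out prediction error of regressing the held-out
spectrum on the loadings. The naive reconstruction error is monotone
decreasing in `k` even for pure noise (the held-out row participates in its
own scores) and therefore cannot select a model; the leverage-corrected form
rises again once components stop generalizing. With this selector, white
noise yields `k = 1` and an exact rank-2 construction yields `k = 2`.

**Acceptance rule.** A class accepts a sample when two statistics both stay
below their critical limits:

* the residual variance ratio `F = s_i^2 / s_0^2`, where `s_i^2` is the
  sample's mean squared orthogonal residual and `s_0^2` the pooled
  calibration residual variance with `(P - k)(n - k - 1)` degrees of
  freedom. Its default critical value is a Box moment-matched chi-square
  (`g*chi2_h`, with `g, h` fitted to the mean and variance of the
  leave-one-out calibration residuals at the chosen `k`). The moment
  matching matters for two reasons: Savitzky–Golay filtering correlates
  channel noise, so the textbook F quantile on `(P - k, (P-k)(n-k-1))`
  degrees of freedom (available as `residual_limit="f"`) is badly
  miscalibrated on derivative spectra; and the leave-one-out residuals,
  unlike the fitted ones, have the magnitude of a genuinely new sample's
  residual.
* Hotelling `T^2` of the scores against the new-observation limit
  `k (n-1)(n+1) / (n (n-k)) * F_crit(k, n-k)`.

The membership probability threshold (default 0.95) is split across the two
tests Šidák-style: each uses `alpha = 1 - sqrt(threshold)`, so the joint
nominal acceptance probability of a genuine class member equals the
threshold, and the rule degenerates correctly at both ends (threshold near 1
accepts all calibration members; thresholds near 0 reject everything except
samples essentially at the class center). A residual-only mode
(`mode="residual"`) uses the single residual test at `alpha = 1 - threshold`.

**Assignment.** A sample accepted by exactly one class gets that class;
accepted by several, the nearest by reduced distance
`d = sqrt(F/F_crit + T^2/T^2_crit)` (all accepting classes are recorded);
accepted by none, `no_match`. Fitting uses SVD only — there is no randomness
in this module.

## PLS-DA

SIMPLS regression of the second-derivative spectra onto a one-hot class
indicator matrix. SIMPLS is deterministic and numerically stable; at full
rank it reproduces the multivariate least-squares solution (pinned in tests
to 1e-6, and cross-checked against an independent NIPALS implementation).

The number of latent variables is chosen by leave-one-out cross-validation
minimizing the argmax misclassification count, with the same 1% parsimony
rule, capped at 15. Per-class decision cutoffs are placed where two Gaussian
densities — fitted to the in-class and out-of-class *leave-one-out*
predictions of the indicator value, weighted by empirical priors — cross
between the two means (a Bayes threshold); the fit uses the LOO rather than
the fitted calibration predictions because the latter are optimistic and
push cutoffs too high for new data. Degenerate geometry (inverted means, no
crossing between the means) falls back to 0.5, and a `fixed:0.5` rule is
available. A sample whose predictions clear no cutoff is `no_match`;
otherwise the accepting class with the largest prediction wins.

PLS-DA has one structural weakness on this problem worth knowing about: the
freeze-thaw classes are ordered along an almost one-dimensional effect
continuum, and the indicator of the *middle* class (`frozen1`) is a
non-monotone function of position along it, which a linear regression can
only capture through the argmax geometry. SIMCA, which models each class
separately, does not share this weakness; in the default scenario both
exceed 90% held-out accuracy but SIMCA is consistently ahead, and PLS-DA
leaves more samples unmodeled — the same qualitative contrast the original
study reports between the two methods.

## Aquagram

For chosen water matrix coordinates (wavelengths in the first overtone of
water), the aquagram value of sample `i` at coordinate `λ` is

    Aq_iλ = (A_iλ - μ_λ) / σ_λ

where `A` is the MSC-corrected absorbance and `μ_λ, σ_λ` are the mean and
sample standard deviation (`n-1` denominator) over *all* spectra in the set,
pooled across classes. Coordinates are snapped to the nearest grid channel
(snap distance recorded). The default coordinate list —
1342, 1364, 1374, 1384, 1396, 1404, 1444, 1452, 1464, 1476, 1494, 1518 nm —
is this package's convention: twelve first-overtone coordinates spanning
1342–1518 nm, covering the free/weakly hydrogen-bonded water region below
1410 nm and the strongly hydrogen-bonded region above 1440 nm. No
coordinate is placed at 1410–1443 nm because there the generator's two
freeze-thaw effects on the 1416 nm band (intensity loss and a small
rightward shift) nearly cancel and the sign of the class difference is not
identifiable. Per-subset normalization (e.g. one fish across its three
states) is obtained by slicing the input before calling the function.

## Synthetic data generator

No spectra from the original experiment are publicly deposited, so every
pipeline stage is exercised on synthetic spectra built to embody the
reported freeze-thaw spectral changes. Each spectrum is a sum of Gaussian
bands on a 512-channel 900–1700 nm grid plus a linear baseline, scaled by a
per-sample gain `~N(1, 0.02)` and degraded with white noise (SD 5e-4
absorbance):

| center (nm) | σ (nm) | amplitude | class factors (fresh/frozen1/frozen2) | center shifts (nm) |
|---|---|---|---|---|
| 975 (O–H) | 18 | 0.18 | 1.00 / 0.95 / 0.91 | — |
| 1164 (C–H) | 12 | 0.10 | invariant | — |
| 1210 (C–H, O–H) | 16 | 0.15 | 1.00 / 0.95 / 0.91 | — |
| 1416 (water, 1st overtone) | 30 | 0.85 | 1.00 / 0.95 / 0.91 | 0 / +1.5 / +2.5 |
| 1462 (N–H / bound water) | 30 | 0.75 | 1.00 / 1.04 / 1.07 | — |
| 1510 (N–H) | 30 | 0.45 | 1.00 / 1.04 / 1.07 | — |
| 1662 (C–H) | 16 | 0.30 | invariant | — |

Water bands lose intensity with each freeze-thaw cycle, the 1416 nm band
also shifts slightly to higher wavelength, the N-H/bound-water region gains
intensity, and the two C–H bands are class-invariant controls. Replicates
cut from the same fish piece (two per piece by default) share a piece-level
amplitude effect (SD 0.01) so grouped splitting can be exercised. The
amplitude/width and nuisance constants are this package's calibration — the
source study prints no band intensities — chosen once so that default
held-out accuracies land inside the study's reported 79–99% envelope
(SIMCA 96–99%, PLS-DA 88–95% at n=100/class across seeds); they are pinned
in the test suite. `null_config` zeroes all class effects (a negative
control on which accuracy falls to chance) and `scale_effects` scales them
globally (accuracy is monotone non-decreasing in the multiplier).

What the generator deliberately does not emulate: non-Gaussian band shapes,
wavelength-dependent scatter, temperature effects on the water bands,
instrument drift, and freeze-thaw effects that are not collinear across the
two cycles. Passing tests therefore show that the pipeline recovers the
class structure it assumes — band-level intensity/position changes against
multiplicative scatter — not that it would reach the same numbers on real
carp spectra.

## Metrics

Confusion tables carry a no-match column. The per-class F1 convention is
pinned by arithmetic against the published tables: precision uses only the
predicted-class columns (a rejection is never a prediction of a class);
recall divides by the full row including no-match (a rejected in-class
sample is a miss). Total accuracy is the diagonal over all samples, with
no-match incorrect. This is the unique simple convention that reproduces,
to the printed precision, every internally consistent published value (17
F1 cells and 6 accuracies). Two published validation tables and one
calibration F1 cell are *not* derivable from their own counts under this or
any convention tried; the reporting tool flags them rather than reproducing
them. Reported values are rounded half-up at the printed precision; internal
values keep full precision.

## Splitting

Calibration/validation splits are stratified by class (per-class calibration
count = `round(fraction * class size)`, within one sample of the target) and
driven by a mandatory explicit seed recorded in the split manifest. An
optional group key (e.g. `fish_id`) keeps all pieces of one fish on the same
side, with greedy allocation and a warning when a group exceeds one side.
The original experiment's own 283/126 partition is not uniformly two-thirds
per class (its per-class fractions range from 0.66 to 0.72), so only the
overall size, not the exact per-class allocation, can be matched by a
stratified rule.

## Problem sizes and determinism

Default analysis sizes are n=100 samples/class for the main scenario and
n=60/class for the null control; at these sizes the full pipeline (fit,
cross-validation, evaluation, aquagram) completes in seconds. All
stochastic steps (generator, splits) consume explicit integer seeds;
model fitting itself is deterministic (SVD/SIMPLS), so a fixed
configuration reproduces byte-identical metrics output.

## Known limitations

* The membership statistic of the commercial package used in the original
  study is proprietary; the acceptance rule here (Box-limited residual
  F-ratio + Hotelling T², Šidák-split threshold) is a documented
  reconstruction with the same operational semantics, not a clone.
* The Box residual limit is fitted per class from at most `n_cal`
  leave-one-out residuals; for very small classes (n < ~10) its tail
  quantiles are rough.
* JCAMP-DX support covers single-spectrum `(X++(Y..Y))` AFFN data with a
  linear X axis only.
* Aquagram class contrasts are asserted as directions (signs), not
  magnitudes; magnitudes depend on the generator's calibration constants.
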