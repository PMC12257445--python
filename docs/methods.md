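# Methods

`modemdwi` implements a simulation-plus-classification study design for
diffusion-weighted MRI (DWI): synthetic multi-b-value signals are generated
by Monte-Carlo random walk in idealized cellular substrates, degraded with
Rician noise, and then classified two ways — model-free, by a multilayer
perceptron (MLP) reading the raw normalized decay ("MODEM"), and
model-based, by logistic regression on parameters fitted from five
analytical diffusion models. A repeated-resampling harness compares the two
routes by ROC AUC and accuracy.

## Monte-Carlo substrate simulation

**Geometry.** A tissue is modeled as a periodic 2D box of non-overlapping
disks: the transverse sections of infinite parallel cylinders whose
boundaries act as permeable cell membranes. Uniform-radius substrates are
hexagonally packed; the lattice constant solves
`phi = 2 pi r^2 / (sqrt(3) a^2)` so the intracellular volume fraction
(ICVF) is hit exactly, up to the closed-form hexagonal maximum
`pi/(2 sqrt 3) ~ 0.9069`. Gamma-distributed radii (cell-size dispersion)
are packed by largest-first random sequential addition with a few
Monte-Carlo relaxation sweeps on failure; random sequential packings jam
near area fraction ~0.54, below the 58% default target, so the *achieved*
ICVF is recorded in the substrate metadata and is the quantity that
describes the realized geometry.

**Walk.** Walkers start uniformly in the box and take fixed-length steps
`L = sqrt(4 D0 dt)` in uniformly random in-plane directions
(`D0 = 2.0e-3 mm^2/s`, `dt = TE / n_steps`). Because the diffusion gradient
is perpendicular to the cylinder axes and the geometry is
translation-invariant along them, the axial coordinate never enters the
phase; the walk is therefore executed in 2D with no approximation. On
crossing a membrane a walker transmits with the substrate's per-encounter
transit probability `p` (the printed permeability percentages, e.g.
0.2% -> p = 0.002) and otherwise reflects specularly about the local
tangent; a step-rejection mode is available as a configuration alternative.
At most one membrane interaction is resolved per step, which is accurate at
the default step size (0.06 um at the full 20 000-step profile, 0.58 um at
the reduced profile — still well below the smallest 2 um radius; a warning
fires if a configuration violates this).

**Signal.** The pulsed-gradient spin-echo (PGSE) phase is accumulated as
`phi = gamma * Gd * sum_i w_i x_i`, where `w_i` is the signed fractional
coverage of step `i` by the two rectangular gradient lobes (de-meaned so
the lobes balance exactly, making the phase independent of absolute
position) and `x_i` the walker's unwrapped coordinate along the gradient.
The signal is the magnitude of the ensemble-average phasor
`S(b) = |mean exp(i phi)|`, so `S(0) = 1` exactly. One trajectory serves
all b-values because the waveform shape is shared and only the amplitude
`Gd(b)` changes; `Gd` inverts `b = (gamma Gd delta)^2 (Delta - delta/3)`.

**Timing defaults.** The simulation's PGSE timing is not dictated by the
substrate grid, so the package defaults to `TE = 85 ms` (the clinical echo
time), `delta = 25 ms`, `Delta = 50 ms` — feasible for every default
b-value (0–3000 s/mm^2) at realistic gradient amplitudes. All three are
configurable.

**Profiles.** The full profile is 100 000 walkers x 20 000 steps per
substrate; the reduced (`ci`) profile used by the test suite and the
acceptance script is 2000 x 2000, which keeps the free-diffusion slope
within ~1% of `D0` while running a hundred simulations in under a minute.

## Noise model

Complex Gaussian noise of standard deviation `sigma = level * S(0)` is
added independently per b-value to the real and imaginary channels and the
magnitude is taken (Rician statistics):
`M = sqrt((S + e1)^2 + e2^2)`. Study levels are 0–25% of the b = 0 signal.
Each simulated decay is doped `n_reps` times (1000 in the full design), so
a substrate contributes `n_sim_repeats x n_reps` rows per level. Features
are later normalized by the *measured* (noisy) b = 0 magnitude, matching
what a real acquisition can do; normalization by the true S0 is available
via the array API. Seeds spawn hierarchically (master -> signal set ->
repetition) from `numpy.random.SeedSequence`, so every table is exactly
reproducible.

## Diffusion models

All diffusivities are in mm^2/s, b in s/mm^2, fitted on normalized signals
with S0 fixed at 1.

| model | form | parameters | fit |
|---|---|---|---|
| mono | `exp(-b ADC)` | ADC | closed form from b = 0, 1000 |
| IVIM | `f e^{-b Dperf} + (1-f) e^{-b Ddiff}` | f, Dperf, Ddiff | segmented two-step |
| DKI | `exp(-b D + b^2 D^2 K / 6)` | D, K | bounded least squares |
| FROC | `exp(-D mu^{2 beta - 2} (gamma Gd delta)^{2 beta} [Delta - (2b-1)/(2b+1) delta])` | D, beta, mu | bounded least squares |
| CTRW | `E_alpha(-(b Dm)^beta)` | Dm, alpha, beta | bounded least squares |

Bounds bracket physiological ranges: D-type in [1e-6, 50e-3] mm^2/s,
f in [0,1], K in [0,3], alpha/beta in (0,1], mu in [0.1, 50] um. The IVIM
first step is an ordinary log-linear fit on 200 <= b <= 1000 (unweighted:
delta-method S^2 weights emphasize the b = 200 point, where residual
perfusion biases Dperf noticeably at typical parameter values); the
second step fits Dperf on b <= 200 with f and Ddiff frozen. The nonlinear
fits use SciPy's bounded trust-region least squares (`trf`) — the bounded
analog of Levenberg–Marquardt, chosen because plain LM cannot enforce the
bounds — initialized at the mono-exponential ADC with K = 0,
alpha = beta = 1.

Two numerical facts shaped the fitters:

* **Boundary saddle.** The alpha = beta = 1 initialization lies on a
  boundary saddle of the FROC/CTRW objectives; a single descent from there
  can terminate "successfully" without entering the interior. The fits
  therefore always try two deterministic interior restarts (alpha, beta
  around 0.9 and 0.7–0.8) in addition to the nominal start, keeping the
  best residual (ties break toward the smaller parameter norm); random
  jittered restarts remain as a non-convergence fallback. The monotone
  trust-region iteration guarantees the returned residual never exceeds the
  chosen initialization's (descent property).
* **FROC ridge.** At fixed beta, D and mu enter the FROC exponent only
  through `D mu^{2 beta - 2}`: they are not separately identifiable, by
  construction of the model. Recovery tests therefore assert beta and the
  identifiable product; individual D and mu values from any FROC fitter are
  coordinate choices on this ridge.

**Mittag-Leffler numerics.** `E_alpha(-x)` (the CTRW kernel) is evaluated
to >= 8 significant digits: the power series below the crossover x = 0.9
(geometric decay for every alpha; cancellation is mild there), and above
it the complete-monotonicity
spectral integral, rewritten with `u = -cos(a pi) + sin(a pi) tan(t)` so
the Lorentzian spectral peak — which sharpens into a delta function as
alpha -> 1 — is absorbed analytically; the remaining integrand is bounded
by 1, strictly positive, and smooth uniformly in alpha, and is integrated
adaptively to 1e-11 relative tolerance. Closed forms handle alpha = 1
(exp) and alpha = 2 (cosine); 1 < alpha < 2 is supported for cross-checks
via the series, restricted to x <= 30 where double precision retains 8
digits. Validated against `erfcx` (alpha = 1/2 identity) and a 60-digit
series oracle.

## Model-free classifier

Features are the normalized signals at the nonzero b-values (12 for the
simulation grid, 16 for the 17-b clinical-style grid). The MLP has six
hidden ReLU layers of n units (n = feature count) and a two-class
probabilistic output, trained with Adam (step 1e-3, batch 200) on
cross-entropy for at most 100 epochs with a 10% validation hold-out and
early stopping after 10 stagnant epochs. It is built on scikit-learn's
`MLPClassifier`; for two classes that estimator uses a single logistic
output unit, which is mathematically identical to a 2-way softmax.

Class imbalance is corrected on the training partition only, *before* the
internal validation split, by SMOTE with k = 5 Euclidean minority
neighbors (implemented in-package; every synthetic point is a convex
combination of a minority sample and one of its neighbors). Training rows
are put in a canonical lexicographic order before fitting so the validation
split — and hence the early-stopping epoch count — is invariant to the
order in which samples arrive.

## Evaluation harness

Each iteration draws a stratified 80/20 split (stratification is a package
choice; it keeps small tests well-posed), trains MODEM on the SMOTE-balanced
training partition, fits each requested diffusion model (fits are cached
across iterations since they do not depend on the split), runs a
per-model logistic regression (intercept included; internally standardized
features; C = 1e4 ridge so perfect separation degrades gracefully), and
records test AUC and accuracy (threshold 0.5). AUC is the normalized
Mann-Whitney U with ties counted one half — verified against an all-pairs
brute-force oracle on every random instance up to n = 50.

Summaries are per-method mean and SD over iterations; each model is
compared with MODEM by a two-sided Mann-Whitney test (exact enumeration of
the permutation distribution when both groups have <= 8 values, handling
ties by direct recomputation; tie-corrected normal approximation
otherwise). Logistic coefficients are scaled by the training-feature SD,
absolute values taken (signed coefficients cannot generally sum to one),
and normalized to sum to 1 within each model; the reported table is the
across-iteration mean, renormalized.

## What the synthetic world does and does not establish

The generator reproduces the stated simulation design: 4 cellular-property
axes x 10 levels (40 substrates), 13 b-values, 7 noise levels, 10 walker
repeats x 1000 noise repetitions. It does *not* emulate perfusion (hence
IVIM is fitted only to clinical-style data in the original design), T1/T2
relaxation, 3D crossing geometries, multi-coil (non-central chi) noise, or
intra-voxel heterogeneity beyond the cylinder mixture — so a green
simulation test establishes correctness of the pipeline and the qualitative
noise/performance trends, not clinical performance. The clinical headline
numbers require patient data that is not publicly deposited and are out of
scope.

## Numerical and testing choices

- Tolerances: Monte-Carlo assertions use ~3 standard errors of the phasor
  estimator `sqrt((1 - S^2)/(2 N))`; fitting self-consistency uses the
  spec-level 1–5% relative bands; Mittag-Leffler identities use 1e-8.
- Degenerate inputs: all-equal or nonpositive signals produce flagged
  (non-converged) fit records, never crashes, and are dropped with logging
  by the study driver (a model's iteration is reported NaN if >10% of rows
  fail).
- Determinism: every stage is seeded through `SeedSequence` spawning; the
  pipeline manifest records artifact SHA-256 checksums, and a rerun with
  the same configuration reproduces them bit-for-bit.
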