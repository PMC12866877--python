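# Methods

`brainguard` emulates high-dimensional fields of von Mises strain — the
mechanical injury indicator at the interface between brain tissue and an
implanted probe array — from a handful of scalar inputs (material moduli
or micromotion displacements).  It combines a linear reduced-order model
of the field with independent Gaussian-process regressors on the reduced
coefficients.  This note records the model, its assumptions, the
numerical choices, and what the bundled synthetic data generator does and
does not establish.

## Reduced-order model of the strain field

Training data are a snapshot matrix ζ ∈ R^{J×M}: M full fields of J
points, one column per sampled input ε^{(j)} ∈ R^I.  The snapshots are
centred by their arithmetic mean μ_ζ and decomposed by a thin SVD,

    ζ − μ_ζ 1ᵀ = Φ D Vᵀ,

computed through the M×M Gram problem when J ≫ 4M (identical result,
much cheaper at J up to ~3·10⁵).  The basis keeps the smallest m whose
discarded energy Σ_{i>m} σ_i² / Σ_i σ_i² falls below a truncation
threshold (default 10⁻¹⁰).  Each retained singular vector's sign is
fixed by making its largest-magnitude entry positive, so bases are
identical across linear-algebra backends.  A field maps to coefficients
β = Φ̃ᵀ(ξ − μ_ζ) and back via ξ = μ_ζ + Φ̃β.

Two guards supplement the energy rule:

* `max_components` (default 40 in `TrainConfig`) caps m outright.
* `noise_cutoff="auto"` drops singular values below the median-based
  optimal hard threshold for additive white noise (Gavish & Donoho
  2014).  Noisy snapshots turn the spectrum tail into a
  Marchenko–Pastur-style bulk that the energy rule would retain almost
  entirely; those directions carry no signal, and each one would cost a
  full O(n₁³) GP fit.  On noise-free data the spectrum median sits at
  the numerical-rank floor and the cutoff never binds.

Degenerate inputs: an all-identical snapshot matrix has zero centred
energy; `fit_basis` clamps m to 1, warns, and the emulator reduces to a
constant-field predictor.

## Per-coefficient Gaussian processes

Each retained coefficient β_k is modelled as an independent zero-mean GP
over the z-scored inputs (normalization fitted on the training design,
shared by all components — coefficients are zero-mean by construction,
which is what justifies the zero prior mean).  The kernel is squared
exponential, c(x,x′) = σ_k² exp(−|x−x′|²/2l²), plus i.i.d. observation
noise σ².  One (σ_k, l, σ) triple is fitted per component.

Hyperparameters minimize the negative log marginal likelihood

    L = ½ βᵀC⁻¹β + ½ log|C| + (n₁/2) log 2π,   C = C_k + σ²I,

by Polak–Ribière nonlinear conjugate gradient in log-hyperparameter
space (positivity for free), with:

* analytic gradients ½ tr((C⁻¹ − ααᵀ) ∂C/∂θ), α = C⁻¹β, validated
  against central finite differences to 10⁻⁵ relative in the test suite;
* backtracking Armijo line search (c₁ = 10⁻⁴, shrink 0.5, ≤ 50 halvings,
  adaptive initial step);
* PR⁺ (negative β reset to steepest descent) plus a periodic restart
  every 3 × (free parameters) iterations;
* convergence at ‖∇L‖ < 10⁻⁶, iteration cap 500, both configurable;
* a windowed stall stop: if L improves by less than 10⁻⁵·(|L|+1) over
  each of two consecutive 15-iteration windows, the search stops.  The
  marginal likelihood of noise-dominated coefficients has broad flat
  basins; polishing them changes predictions by nothing and costs
  hundreds of O(n₁³) factorizations;
* a noise floor σ ≥ 10⁻⁶ × std(β) (free-noise fits only), and jitter
  10⁻¹⁰ × mean-diagonal escalating tenfold to at most 10⁻⁴ on Cholesky
  failure;
* initialization σ_k = std(β), l = median pairwise distance of the
  normalized inputs, σ = 0.05·std(β).  Three seeded log-uniform
  (×0.1…×10) perturbations of that point are screened by their NLML;
  conjugate gradient runs from the most promising start, the others
  serving as fallbacks if it fails to improve.  Running full CG from
  every start quadruples cost without changing the optimum on this
  problem class (checked against an independent quasi-Newton optimizer).

Prediction is the standard Gaussian conditional with the noise variance
in both blocks: mean K₂₁(C₁₁+σ²I)⁻¹β₁, variance diag(K₂₂+σ²I −
K₂₁(C₁₁+σ²I)⁻¹K₁₂), clamped at zero against roundoff.  With σ = 0 the
posterior interpolates the training targets.  Field-level prediction
decodes the coefficient posteriors; the variance field uses component
independence: var_j = Σ_k Φ̃_jk² var(β_k).

## Error metric

All accuracy statements use the normalized relative error
err_j = |S_pred,j / max|S_pred| − S_ref,j / max|S_ref||: each field is
scaled by its own maximum before differencing, making the metric
invariant to a uniform rescaling of either field.  `EvaluationReport`
exposes three summaries: the per-point error map averaged over test
samples (`mean_error_field`, whose maximum `max_mean_error` is the
headline full-field accuracy figure), the per-sample means over points,
and the worst single point of any single sample (`max_error`).  The
distinction matters: samples whose true field is nearly zero (vanishing
micromotion) have an ill-conditioned normalization — any absolute
prediction error is amplified without bound as the reference maximum
shrinks — so the worst-case-over-samples number is dominated by a few
near-degenerate samples and is reported separately rather than mixed
into the averaged map.

## Synthetic data generator

No public dataset pairs implant micromotion with whole-brain strain
fields, so training data come from an analytic stand-in for a nonlinear
finite-element campaign.  What it reproduces:

* **Sampling design**: 900 samples, 80/20 split; brain modulus
  E ~ N(9, (0.2·9)²) kPa and probe modulus N(16.5, (0.2·16.5)²) kPa
  (both truncated at 0.5 kPa, ν fixed at 0.45/0.49) for the
  preoperative predictors; micromotion u ~ N(0, (100 µm)²) per axis for
  the monitor.  Predictor regimes carry a scalar micromotion amplitude
  along a fixed direction — 60 µm (respiration, vertical) and 20 µm
  (vascular pulsation, lateral), CoV 0.2; these nominal levels are
  package choices on the order of reported physiological micromotion,
  respiration being the larger driver.
* **Geometry**: an 80 mm hemispherical domain, a 5×5 probe array at
  400 µm pitch implanted 2 mm below the crown, J = 5000 measurement
  points by default (tested up to 3·10⁵).  40% of points cluster around
  the probe tips at the influence-radius scale ρ = 300 µm, 20% fill a
  near-field ball, 40% cover the hemisphere with a scrambled Halton
  sequence — mimicking adaptive mesh refinement at a contact interface.
* **Forward model**: a superposition of probe-centred Gaussians of
  width ρ, modulated by a directional term and an amplitude
  A = E_p/(E_p+E_b) · (|u|/ρ) · (1 + 0.5 tanh(|u|/200 µm)) — smooth,
  nonlinear in |u|, zero at u = 0, strain concentrated at the contact.
* **Noise**: output-side additive Gaussian noise with variance set from
  the dataset signal power P = mean((ζ − row-mean)²) as
  σ_n² = P/10^(SNR/10), plus an optional bias expressed in units of the
  mean absolute strain.  Injected into training data only; evaluation
  references stay clean.

What it does **not** reproduce, and therefore what passing tests do not
show: contact mechanics, hyperelasticity, tissue heterogeneity, or a
realistic strain dynamic range.  Two structural consequences are worth
naming.  First, the amplitude law A ∝ |u| has a cone (non-smooth point)
at u = 0 which an isotropic RBF GP cannot represent; together with
extrapolation beyond ~3σ of the Gaussian input distribution this sets a
floor on the worst-case per-sample error that no hyperparameter choice
removes (verified by an oracle sweep).  Second, the synthetic field's
max/rms ratio (~6) is far below that of a whole-organ field where most
points carry near-zero strain; since injected noise is scaled to the
dataset rms, noise is effectively *larger* relative to the error
metric's normalization here than it would be on organ-scale data, and
the noisy-training error maps are correspondingly pessimistic.

The generator's forward model has exact parametric rank 4 (one radial
mode plus three directional modes), so the fitted basis retains 4–5
components at the default truncation — consistent with the rapidly
decaying spectra the emulator assumes.

## Workflow layer

`train_emulator` → `predict_field`/`predict_fields` → `evaluate` chain
the pieces; `monitor_stream` applies `predict_field` statelessly to a
displacement stream with an optional strain-threshold exceedance flag
(malformed steps are skipped with a warning, keeping the stream alive);
`select_optimal_device` queries both physiological-regime predictors for
each candidate probe and returns the candidate minimizing the injury
aggregate — by default the predicted maximum strain, with mean strain
and fraction-above-threshold as configurable alternatives; no aggregate
is canonical, so the choice is explicit configuration.  Ties keep the
first candidate in input order.  Emulators serialize to HDF5 with full
double precision; a save/load round trip reproduces predictions to
1e-12.  The `braingd` CLI wraps these operations with atomic writes,
single-seed reproducibility and distinct exit codes per error category.

## Problem sizes used in the bundled runs

The reference benchmark (tests and `scripts/acceptance.py`) uses the
default J = 5000 / 900-sample design across five noise conditions; each
condition takes roughly half a minute on one CPU.  Unit and property
tests use scenes of 400–800 points and 40–240 samples, which exercise
the same code paths at interactive speeds.  The exact-rank sanity
experiment uses 600 training samples of a rank-2 field with smooth
nonlinear coefficient functions and fixes σ = 0 (the data are
noiseless); its test inputs are drawn inside the training hull because
GP accuracy claims are interpolation claims.

## Known limitations

* Isotropic RBF only; a single length scale per component cannot adapt
  to the radial/angular anisotropy of the micromotion response, and no
  alternative kernels are provided.
* Component GPs are independent; cross-coefficient posterior
  correlations are not modelled (variance fields are exact only under
  that independence).
* The marginal likelihood of noise-free, very smooth coefficients is
  maximized on a flat ridge toward large length scales where kernel
  matrices are ill-conditioned in double precision; accuracy there is
  conditioning-limited (~10⁻⁵–10⁻⁶ relative), not statistics-limited.
* Worst-case per-sample error on near-zero-amplitude samples is
  intrinsically unbounded under the max-normalized metric; consumers
  monitoring for injury should gate decisions on the predicted strain
  magnitude, not the normalized error, at small micromotion.
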