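# Methods

## Task generative process

A trial is a sequence of up to `max_samples = 10` samples. The initial
state is ±1 with equal probability; before every subsequent sample the
state flips with hazard `H = 0.1`. Sample angles are drawn from the
untruncated Gaussian `N(state·µ, σ)` with µ = 26°, σ = 29°; the
log-likelihood ratio of a sample is the exact Gaussian density ratio,
which reduces to `2µx/σ²` for equal variances. Angles beyond the physical
±90° half-ring are neither truncated nor wrapped: only the density ratio
enters any computation, and a clipped *display* would not change it.
Trial length is pre-drawn at trial start — `max_samples` with probability
0.7, otherwise uniform on 1..9 — which is distributionally identical to
terminating on the fly. Trials are split into two contiguous session
blocks (labels 0/1). The warning cue at 0° carries no evidence
(LLR(0) = 0) and is not simulated as a sample.

The correct response is the state that generated the final presented
sample. Under this convention the last-sample benchmark strategy has
analytic accuracy Φ(µ/σ) = 81.5% and the three benchmark strategies
(ideal observer / last-sample / perfect accumulation) measure
88.2 / 81.5 / 75.8% on large simulations; the strict ordering, not the
second decimal, is the property the pipeline relies on.

## Observer models

Normative: `ψ_s = f(L_{s-1}; H)` with the log-odds hazard transform and
`L_s = ψ_s + gain·LLR_s`, `L_0 = 0`. The transform is evaluated with
log-add-exp so it is stable for |L| in the hundreds. Note the recursion is
*prior plus evidence*; an accumulation that bypasses the prior transform
would make the non-linearity inert, contradicting its defining role.
Rivals: perfect (`L_s = L_{s-1} + gain·LLR_s`), non-absorbing bound
(posterior clipped at ±bound), leaky (`L_s = (1-leak)·L_{s-1} +
gain·LLR_s`; leak = 0 recovers perfect accumulation exactly).

Surprise is the analytic change-point probability: the posterior
probability that the current sample directly followed a state switch,
given the pre-sample belief and H. The change hypothesis pairs each
state-conditional likelihood with the *other* state's prior probability;
this crossed assignment is what makes surprise reduce exactly to H at a
flat prior (a property asserted in the tests). Only likelihood ratios
enter, so the implementation consumes the LLR. Surprise is
logit-transformed before any regression use; uncertainty is −|ψ|. The
evidence gain multiplies the LLR both in the accumulation and inside the
surprise computation (subjective evidence); a flag disables the latter.
Surprise in regressions uses the generative H by default (a fitted
subjective H can be passed instead).

The belief update `Δψ_s = ψ_{s+1} − ψ_s` requires a prior *after* the last
sample; we define it by one extra application of the transform to the
final posterior and flag it as extrapolated. Choice probabilities are
`p(right) = 0.5 + 0.5·erf(L/noise)` exactly (no √2 — the erf scale *is*
the noise unit); a probit alternative is available for sensitivity checks.

## Fitting

Cross-entropy between observed ±1 choices and model `p(right)`, with
probabilities clamped at 10⁻¹⁰, minimised by global-best particle swarm
optimisation. Coefficients: inertia 0.72, cognitive = social = 1.49;
velocities clamped to 0.25× the bound width; out-of-bound moves are
reflected with damped velocity. The clamp/reflection matters: with
full-width velocities and hard clipping the swarm intermittently piles up
on the `h_subj` lower bound — a perfect-accumulation-like plateau of the
objective — and returns fits worse than the generating parameters.
Parameter bounds ("wide"): h ∈ [0.001, 0.5], gain ∈ [0.01, 10],
noise ∈ [0.01, 20], bound ∈ [0.1, 20], leak ∈ [0, 1]. Budgets: the
desk-scale default is 60 particles × 200 iterations, which recovers the
present 2–3-parameter models to well within their sampling error at 1440
trials; `FitConfig.study_scale()` exposes 300 × 1500. All trials are
fitted (only the regression analyses are restricted to full trials).
Free-parameter counts: normative 3, perfect 2, bounded 3, leaky 3;
`BIC = 2e + k·log n`. The objective is evaluated for the whole swarm at
once (vectorised over particles × trials), so one fit takes seconds.

Note on identifiability: gain and noise trade off strongly (scaling both
leaves choices nearly invariant), so individual gain/noise estimates
scatter along a ridge while `noise/gain` and `h_subj` are well
constrained. Recovery is therefore assessed at the group level.

## Kernel regressions

Weight on choice: logistic regression of P(choice = right) on an
intercept, LLR at positions 1..10, and LLR × surprise and LLR ×
uncertainty interactions at positions 2..10 (position 1 has a flat
prior). Full trials only. Modulators are z-scored per participant (pooled
over positions 2..10) before interactions are formed, keeping modulation
coefficients comparable across participants; LLR stays in natural units.
Maximum-likelihood fits via statsmodels with an L2-stabilised refit
(λ = 10⁻³) on separation, which is flagged in the result. Residual
variants add LLR × residual-CPP interactions (positions 1..10) or
residual-lateralisation main effects (positions 2..10); residuals are
z-scored per participant. Group inference uses two-tailed sign-flip
permutation tests (exact enumeration when 2ⁿ is small enough).

## Synthetic EEG generator

The generator emits *post-preprocessing* data: 200 Hz, epochs
[−0.4, 5.4] s around trial onset, sample onsets at 0.4·s, no artifacts.
Its purpose is to realise, with known gains, exactly the statistical
structure the analyses assume:

- **Decision variable** d(t): holds the running belief and ramps linearly
  in [0.1, 0.4] s after each onset to incorporate that sample's update,
  with every update multiplied by `(1 + η)`, η ~ N(0, σ_η) i.i.d. per
  (trial, sample). The same corrupted final value (plus terminal Gaussian
  noise) determines the agent's choice, so one noise source produces all
  three residual couplings the analyses look for.
- **Motor channels** (6 + 6): a beta carrier (20 Hz, random phase per
  trial/channel) with envelopes `A0·10^(±κ_m·d(t)/40)` plus broadband
  noise. The exponential envelope makes the *decibel* left-minus-right
  power difference exactly `κ_m·d(t)` in expectation, so the
  lateralisation regressions have an analytic ground truth.
- **Centroparietal channels** (4): raised-cosine kernels (peak 0.35 s,
  half-width at half maximum 0.2 s) at each onset scaled by
  `κ_c·|Δψ_s·(1+η)|`, plus white noise, 1/f drift and a session offset.
- **Anterior channels** (4): the same kernel scaled by `κ_a·|LLR_s|`.
- **Uninformative channels** (4): noise, drift and offset only.

Default amplitudes are chosen for realism of single-trial scalp EEG —
evoked components of a few µV (κ_c = 1 µV per log-odds unit of update,
κ_a = 0.4 µV per LLR unit) against 14 µV white sensor noise and 2 µV
slow drift, κ_m = 1 dB per log-odds unit, σ_η = 0.3. This puts
single-participant standardised encoding betas in the 0.05–0.3 range and
makes 20-participant cluster tests clearly significant without being
trivial. Two caveats follow from the design itself and are visible in the
acceptance suite: (i) because |Δψ| is anti-correlated with |ψ| given
|LLR| and surprise (confident beliefs imply small updates), a CPP that
truly encodes |Δψ| carries a small *negative* partial |ψ| loading
(≈ −0.085 standardised before noise attenuation), so the "no |ψ|
encoding" null holds only against limited power; (ii) an anterior signal
that truly encodes |LLR| is fit strictly better by the objective-evidence
model than by the effective-evidence model, so their adjusted-R²
difference is genuinely negative rather than zero. What the synthetic
data do *not* emulate: volume conduction, realistic topographies,
artifacts, eye movements, or the raw-recording preprocessing chain (ICA,
interpolation, CSD) — passing tests certify the analysis pipeline's
statistical machinery, not its robustness to real-world recording
problems.

## Signal conditioning and regressions

STFT: Hanning taper, 0.4 s window, 5 ms steps, centred windows; points
whose window would cross an epoch edge are emitted as missing rather than
zero-padded (zero-padding would bias the pre-trial baseline). dB
conversion is `10·log10(power/baseline)` with the baseline averaged over
trials and the 100 ms before trial onset, per channel × frequency. The
lateralisation index averages dB power over 13–30 Hz (inclusive
endpoints) and over each hemispheric electrode group, left minus right.
Filters are two-pass (zero-phase) Butterworth, 3rd order throughout: the
ERP chain for the slow analyses is 0.1 Hz high-pass → 6 Hz low-pass →
100 ms pre-trial baseline; the single-trial residual/model-comparison
chain replaces the high-pass with 1 Hz and skips the per-trial baseline
(the high-pass removes the slow drift the baseline would otherwise have
to absorb). No additional smoothing of lateralisation traces.

Time-resolved regressions run per sample position and per time point in a
1 s post-sample epoch across full trials, with predictors and outcome
z-scored within (position, time point) and the session covariate entering
raw; coefficients are averaged over positions 2–10 (sample 1 is excluded
whenever a prior term appears, since ψ₁ ≡ 0). Signed regressors are used
for lateralisation, unsigned magnitudes for ERPs. The single-regressor
comparison fits intercept + candidate (+ session; p = 2 predictors in the
adjusted-R² penalty) for the decision-variable (ψ_{s+1}), effective-
evidence (Δψ) and objective-evidence (LLR) candidates and reports
per-participant adjusted-R² differences against the objective-evidence
reference. Scalar residuals are the unstandardised-fit residuals averaged
over a fixed 0.25–0.50 s post-sample window (a fixed window keeps the
pipeline deterministic; a data-driven cluster window is a config option)
and over the role electrode group. Motor updates ΔMBL_s use the mean
lateralisation over the first 100 ms after each onset, differenced
between consecutive samples; the coupling regression
`ΔMBL_s ~ Δψ_s + Δψ_s × residualCPP_s` is fit per sample position
(1..9 — the last position has no successor) and per participant.

## Group statistics

One-sample cluster-based sign-flip permutation tests: pointwise t across
participants, clusters = maximal contiguous same-sign runs with two-tailed
pointwise p below 0.05, cluster mass = sum of t, null = maximal |mass|
under random whole-participant sign flips, cluster
p = (1 + exceedances)/(n_perm + 1). Desk-scale default 1000 permutations
(10000 by argument). The add-one convention plus permutation discreteness
makes the test slightly conservative at small permutation counts
(measured family-wise rate ≈ 3–5% at nominal 5%). Zero-variance time
points are excluded and reported. Paired contrasts use the same sign-flip
scheme on differences, with exact enumeration when 2ⁿ ≤ 2·n_perm.

## Problem sizes and reproducibility

Simulation sizes used by the test suite and acceptance script: strategy
benchmarks on 2–3×10⁵ trials; fitting recovery on 20 agents × 1440 trials
with the 60 × 200 swarm; EEG cohorts of 20 participants × 320 trials
(the generator's own default remains 18 × 80 = 1440 trials over two
sessions); calibration runs of 300–600 null simulations. Every stage
draws its seed deterministically from one global seed (SeedSequence
spawning; per-stage CRC-derived streams in the pipeline), and all
analyses are pure functions of (data, config, seed) — reruns are
bit-identical.

## Known limitations

- The benchmark strategy accuracies depend on the exact convention
  linking early-terminated trials to the scored final state; under the
  convention implemented here the last-sample benchmark is analytically
  81.5%. Reported values from comparable experiments vary with that
  convention by 1-2 percentage points, so the strict ordering
  (ideal > last-sample > perfect) is the robust property.
- Surprise and uncertainty modulators are z-scored pooled over positions;
  per-position standardisation would change coefficient scales (not
  signs).
- The leaky model's leak is a per-sample retention complement; continuous
  -time formulations are out of scope.
- Gain/noise ridge: individual-level gain estimates should not be
  interpreted in isolation (see Fitting).
- The EEG generator shares one evoked-kernel shape across roles and
  participants; kernel-shape variability is not modelled.
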