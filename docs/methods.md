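# Methods

`hrvstress` implements an end-to-end pipeline for detecting acute cognitive
stress from beat-by-beat RR intervals (RRI) and for estimating
population-average stress reactivity, across three diagnostic groups: major
depressive disorder (MDD), panic disorder (PD) and healthy controls (HC).
Because the clinical recordings this kind of study uses are private, the
pipeline is driven by a synthetic cohort generator that reproduces the
*structure* of such data — not any measured values — so that every stage is
testable.

## Synthetic cohort model

Each participant has a subject-level resting mean RRI
`mu_i ~ Normal(mu_rri, sigma_subject^2)` and attends between one and five
visits; the number attended is drawn from the attendance distribution of the
emulated cohort (110 of 147 complete all five visits, 16 four, 4 three,
7 two, 10 one), rescaled for cohorts of any size. Each attended visit yields
a 5-min resting baseline and a 5-min mental-arithmetic stress phase.

Beats are laid down iteratively. The interval following the beat at time
`t_n` is

    rri_n = m(t_n) + A_lf sin(2*pi*f_lf*t_n) + A_hf sin(2*pi*f_hf*t_n) + eps_n,
    t_{n+1} = t_n + rri_n / 1000,

with `eps_n ~ Normal(0, sigma_noise^2)` and a hard floor of 300 ms (floor
rather than rejection sampling, to keep beat counts predictable). The mean
function `m(t)` is constant at `mu_i` during baseline; during stress it drops
by `delta_g + eta` (with `eta ~ Normal(0, sigma_delta^2)` a per-session
reactivity deviation) for the first minute and recovers by `rebound_g` from
minute two onward. The two oscillations mimic the low-frequency (~0.1 Hz,
baroreflex) and high-frequency (~0.25 Hz, respiratory sinus arrhythmia)
bands of resting heart-rate variability; the high-frequency amplitude is
damped under stress (40 → 20 ms), encoding vagal withdrawal, which gives the
classifier a realistic spectral cue in addition to the mean shift.

Defaults (all tunable; chosen as plausible resting-adult values, not
measured ones): `mu_rri` 850 ms, `sigma_subject` 70 ms, `sigma_noise` 10 ms,
`sigma_delta` 10 ms, `A_lf` 25 ms, `delta` −60 (HC), −35 (MDD), −30 (PD) ms,
`rebound` +15 (HC), +12 (PD), 0 (MDD) ms. The ordering — controls react most,
patients show attenuated reactivity, and only MDD lacks the S1→S2 rebound —
is the qualitative pattern the statistics and the classifier are expected to
recover. Visit has no effect by default (`visit_shift = 0`); a per-visit
drift exists for exercising the visit covariate.

What the generator does **not** emulate: ectopic beats and measurement
artifacts beyond white noise, respiratory frequency drift, non-stationary
oscillation amplitudes, medication/sex/age/BMI effects, circadian structure,
and any coupling between clinical severity and reactivity. Tests passing on
this cohort therefore demonstrate that the pipeline recovers the structure it
was told to expect at realistic noise levels — not that the classifier would
reach any particular accuracy on clinical recordings.

## Preprocessing

1. **Artifact filter.** A beat is flagged when its interval leaves
   [300, 2000] ms or deviates from the median of its five nearest
   neighboring intervals by more than 25%. Flagged intervals are replaced by
   natural-cubic-spline interpolation over beat index and beat times are
   recomputed; a series with more than 20% flagged beats is rejected. These
   thresholds are conventional tachogram-editing choices. The filter is
   idempotent on its own output.
2. **Resampling.** The (beat time, RRI) pairs are interpolated with a
   natural cubic spline (second derivative zero at the ends — the
   least-assumption boundary condition) and evaluated on the equidistant
   4 Hz grid `k/4 s`, `k = 0 .. 4T−1`, giving 1200 samples for a 5-min phase
   and 240 for a 1-min epoch. Grid points are retained up to 2 s past the
   last observed beat (never past the phase end), using the spline's
   boundary extrapolation. The heart keeps beating across the phase
   boundary, so the RRI function is physiologically defined up to roughly
   one beat beyond the last R peak; without this margin the final one or two
   grid samples of nearly every recording become zero padding, which brands
   the *last* epoch of each phase with a positional artifact — a
   convolutional classifier then "detects" B5 versus B4 at far above chance
   from the padding alone, poisoning the intra-baseline null. Genuinely
   short recordings are still tail-padded with zeros.
3. **Segmentation.** Phases are packed into fixed 1200-point vectors,
   epochs into 240-point vectors, zero-padded at the tail (`n_valid` records
   the boundary). Epoch windows are half-open: B4 = baseline [180, 240) s,
   B5 = [240, 300) s, S1 = stress [0, 60) s, S2 = [60, 120) s, so adjacent
   epochs share no sample. Values are fed to the model in raw milliseconds;
   per-segment z-scoring exists behind a flag but is off by default because
   the absolute RRI level carries the reactivity signal.

## Classifier

A one-dimensional adaptation of ResNet34, written directly in NumPy with
explicit forward and backward passes (verified against finite differences in
the test suite). Stem: conv(kernel 7, stride 2) → batch norm → GELU → max
pool(3, stride 2). Four stages of 3/4/6/3 residual blocks (16 total) at
64/128/256/512 channels, stride 2 at each stage entry. Each block is
conv(3)–BN–GELU–conv(3)–BN–GELU–conv(1) with a kernel-size-1 convolution as
the shortcut in **every** block, and no activation after the residual
addition; batch normalization precedes each activation. This three-
convolution/two-BN block deliberately differs from the canonical two-
convolution ResNet34 block. Head: global average pooling → linear → single
logit, sigmoid probability of the positive class. Kernel sizes, channel
widths and the training schedule are canonical choices: binary
cross-entropy, Adam at 1e-3, batch 32, up to 100 epochs with early stopping
on validation loss (patience 10). Zero padding is not masked; after the
extrapolation margin above, padding occurs only for genuinely short
recordings, where its position is informative of record length, as intended.

Everything is deterministic given the build seed (initialization) and the
training seed (batch order); training and validation loss curves are
recorded per epoch.

## Evaluation

Repeated k-fold cross-validation (default 10×10) with fold assignment at the
participant level — all segments of a participant share that participant's
fold — and stratification by diagnostic group, so each fold mirrors group
proportions (this keeps per-group test metrics populated for the pooled
model). Within a repetition the splits rotate: split *i* tests on fold *i*,
validates on fold *(i+1) mod k* (used only for early stopping; the 0.5
decision threshold is never tuned) and trains on the rest. The "separate"
strategy restricts training, validation and testing to one group; the
"combined" strategy trains on the pooled groups and stratifies test metrics
by group. Both strategies see identical fold plans per repetition, so their
metrics are paired. Test predictions are pooled over the k splits of a
repetition (each participant is tested exactly once per repetition);
accuracy, AUROC, sensitivity and specificity are computed per repetition and
summarized as mean ± SD **across repetitions**. A hard assertion audits
every split for participant overlap between roles.

## Reactivity statistics (GEE)

Population-average models are fitted by generalized estimating equations
(Gaussian family, identity link; statsmodels backend) with participants as
clusters and an exchangeable working correlation — any two observations of a
participant share a common correlation α, estimated by the moment
(residual-product) estimator. An AR(1) option exists but is not the default;
with clusters as small as two observations it is fragile. Inference uses the
Liang–Zeger robust sandwich covariance, which is consistent even when the
working correlation is wrong.

* **phase5min**: response = mean of the resampled RRI over each 5-min phase
  (the mean is the standard per-window reduction for RRI level analyses);
  fixed effects phase (baseline reference) × group (HC reference) + visit
  (categorical).
* **epoch1min**: response = mean RRI of each 1-min epoch; epoch (S1
  reference) × group + visit.

Wald z contrasts answer the scientific questions: a group's
baseline-to-stress change is the phase main effect plus that group's
interaction (HC's is the main effect alone); group differences in reactivity
are the interaction terms; per-group B4/B5/S2 versus S1 contrasts quantify
the stress nadir and rebound. Raw two-sided p values are reported with no
multiplicity correction, matching the conventional α = 0.05 reporting style
for this design.

With the default generator the within-cluster correlation of phase-mean RRI
is extreme (between-subject SD 70 ms dwarfs within-session noise), so the
estimated α sits near 1 and statsmodels' degrees-of-freedom-corrected
estimator can slightly exceed it; occasional non-convergence at the boundary
is flagged and such fits are excluded from simulation summaries.

## Problem sizes used in the test suite

Desk-scale sizes keep the suite fast while leaving each claim testable: the
chance-level intra-baseline control uses 60 participants and one repetition
of 10-fold CV with a reduced (two-stage, 8/16-channel) network; the
effect-size monotonicity check uses 36 single-group participants, a
participant-level holdout and three seeds per effect size; GEE calibration
and recovery use 200 simulated cohorts of 50 participants per group
(150 clusters — sandwich inference is asymptotic in cluster count, and
coverage checks at materially smaller cohorts measure small-sample bias
rather than correctness), with the generative truth for the marginal stress
effect computed by brute-force Monte Carlo of per-session phase-mean
differences. The full-size default network (16 blocks, ~9.4 M parameters for
1-min inputs) is exercised for construction and forward-pass contracts;
training experiments use the reduced variant.

## Known limitations

* The NumPy network trains on CPU only; throughput is adequate for the
  desk-scale experiments here, not for large hyperparameter studies.
* The generator's sinusoid phases are locked to phase onset, so B4 and B5
  share oscillation phase exactly; real respiratory drift would decorrelate
  them (this makes the intra-baseline null *stricter*, since any positional
  artifact is the only discriminative signal).
* α estimation near its boundary (highly correlated clusters) can fail to
  converge; such fits are reported as non-converged rather than repaired.
* No multiple-comparison control across contrasts, by design.
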