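# Methods

This note documents the models, numerical choices and known limitations
behind `fnirsdrive`, in the order data flows through the package.

## Synthetic hemodynamic episodes (`synth`)

Each episode emulates a passenger watching one driving episode: a 20-s
resting baseline, a stable driving phase, and a single risk event.
Risk-evoked activity is modeled as a boxcar over the risk interval
convolved with the canonical double-gamma hemodynamic response function
(gamma shapes 6 and 16, undershoot ratio 1/6, unit peak), scaled by
`hrf_amplitude` (default 0.5 μM) and a per-channel gain. ΔHbR is the
classic mirrored response: −1/3 of ΔHbO, lagged 1 s. Nuisance terms are
sinusoids at 1.1 Hz (cardiac), 0.25 Hz (respiration) and 0.1 Hz
(Mayer waves) with per-channel random phases, a ±0.005 μM/s linear drift
with random sign, and white noise (sd 0.05 μM on ΔHbO, one third of that
on ΔHbR, matching the smaller dynamic range of the deoxy signal). These
frequencies were chosen to straddle the pass band of the downstream
filter so that the filter is genuinely exercised. Timestamps are jittered
by ±2 ms around the nominal 50 Hz grid to exercise the spline resampler.

The button channel equals risk-interval membership delayed by a 0.8-s
reaction time — a plausible motor latency for a forewarned button press.
Datasets draw one risk interval per episode with onset uniform between
10 and 18 s after driving starts and duration 5–8 s; per-episode seeds
are spawned deterministically from the master seed.

What the generator does **not** emulate: motion artifacts, optode-contact
drift, superficial (scalp) hemodynamics, inter-subject variability of the
response shape, and any optical-density-to-concentration conversion.
Passing tests therefore demonstrate that the pipeline recovers risk
structure *of this generative form*; they are not evidence about recorded
human data, whose response shapes and artifact content are unknown here.

## Real-time preprocessing (`preprocess`)

Order: cubic-spline resampling to 50 Hz → subtraction of the 20-s
resting-window mean per channel → band-pass filtering of ΔHbO and ΔHbR
separately → ΔCOE = (ΔHbR − ΔHbO)/2 → rolling 5-s buffers.

The band-pass is the difference of two DEMA filters
(DEMA_λ = 2y₁ − y₂ with y₁, y₂ cascaded EMAs), λ₁ = 0.001 and
λ₂ = 0.055, followed by a 100-point simple moving average. All recursions
run through `scipy.signal.lfilter` with carried delay-line state, which
makes sample-by-sample streaming and batch processing identical to
machine precision — a property the test suite pins at 1e-10.

Two numerical choices deserve explanation:

* **Initialization.** DEMA accumulators seed with the first observed
  sample (switchable to zero-init). Zero-init costs a transient of order
  1/λ₁ = 1000 samples (20 s); first-sample seeding removes it, which
  matters for 5-s buffers.
* **Band-edge definition.** Cutoffs are −3 dB relative to the passband
  maximum of the DEMA-difference stage, computed from the closed-form
  transfer function on a 200 000-point log grid plus root bisection.
  This stage defines the nominal 0.016–0.90 Hz analysis band. The SMA
  smoother is deliberately *excluded* from the band definition: a 2-s
  boxcar average at 50 Hz attenuates −3 dB at ≈0.22 Hz, so folding it in
  would misrepresent the band the DEMA difference is designed to pass;
  `band_edges(include_smoothing=True)` reports the full-cascade edges
  (≈0.012 and ≈0.26 Hz) for completeness, and
  `frequency_response_table` writes an audit CSV.

Slices are 8×250 (5 s at 50 Hz); the newest 200 samples (4 s) feed the
feature stage, so every feature window has at least 1 s of filter
warm-up inside its buffer. The default emission stride is 0.2 s online;
dataset construction uses coarser strides (1–2 s) to keep windows weakly
dependent. A window's label is the button state at its final sample.

## Wavelet features and selection (`features`)

4-level DB4 decomposition with symmetric boundary extension (the mode is
recorded with the selector because coefficient lengths depend on it).
Per coefficient set, 12 statistics in a fixed registry order: Shannon
entropy, percentiles 5/25/50/75/95, mean, sd, variance, RMS,
zero-crossings, mean-crossings. The entropy's probability vector is the
normalized squared-coefficient (energy) distribution — one defensible
construction among several, chosen because it is scale-structure
sensitive and parameter-free; it is documented rather than asserted as
canonical.

Information gain uses base-2 logarithms and 10-bin quantile
discretization of each feature. Selection keeps the 4 highest-gain
features per channel (8×4 = 32 total), ties broken toward the lowest
feature index so selection is deterministic; an all-constant channel
yields all-zero gains, is selected purely by tie-break, and is flagged
in the selector state. Selectors are fitted per subject per scenario and
never transferred.

## Risk classifier (`riskclf`)

Six members, soft voting with equal weights, decision threshold 0.5 with
ties resolved to "risky" (the conservative direction for a safety gate).
Boosted members use 50 SAMME rounds; the SVM base is
probability-calibrated; scale-sensitive members (SVM, logistic
regression, MLP) get a standardizing front end. On very small or
intractable samples AdaBoost can reject its first weak learner; the
member then falls back to its unboosted base classifier so the ensemble
always fields six voters (the fallback is recorded on the member).
Evaluation is stratified 5-fold cross-validation with balanced accuracy;
class imbalance is handled only through the metric, not by resampling.

The "better than chance" claim is tested by permutation: labels are
permuted against the *held-out* cross-validated predictions (10 000
draws, add-one correction). Refitting the six-member ensemble per
permutation is computationally out of reach; the fixed-prediction
permutation is the standard exchangeability test of the association
between predictions and labels.

At zero noise the cross-validated balanced accuracy is high but not
exactly 1: the button label leads the hemodynamic response by several
seconds (reaction delay 0.8 s versus an HRF rise of ~5 s), so windows
near onsets and offsets are intrinsically ambiguous. This mislabeling at
the boundaries is a property of the measurement physics, not a pipeline
defect; the linear-separability test therefore uses physiology-aligned
labels (evoked response above half maximum at the window end).

## Driving simulator (`drivesim`)

Forward-Euler kinematics at dt = 0.05 s, episode cap 40 s, vehicle
length 4.5 m. The normalized action maps linearly onto [−8, +3] m/s²
(emergency braking to moderate throttle). Scenario parameters follow the
protocol: emergency braking (both vehicles 50 km/h, 50 m gap, hard brake
at a uniform 20–40 m trigger gap, preceded by a mild 1 m/s² closing
phase), cut-in (50 vs 40 km/h, 80 m, instantaneous lane merge at a
uniform random time in 10–15 s; lateral dynamics are out of scope), and
pedestrian crossing (40 km/h, crossing 300 m ahead at a uniform random
time in 10–20 s, 1.5 m/s walker, 1.5 m near-miss clearance).

The ground-truth risk flag — the oracle form of the passenger's
subjective perception — is raised during the scripted hazard phase *and*
whenever the ego's own behavior becomes dangerous (time-to-collision
with the current leader under 4 s, or a nearly closed gap), with
hysteresis: once raised it stays up until the closing situation is
resolved (TTC above 8 s or no longer closing). Without the
self-inflicted component an exploring agent could ram the leader before
any scripted hazard fires, which no passenger would watch impassively;
without hysteresis the gate chatters at the threshold.

IDM fallback: v₀ equals the scenario's initial ego speed, x₀ = 2 m,
T = 1.5 s, a_max = 2 m/s², b_max = 4 m/s², δ = 4, output clamped to
[−b_max, a_max]. Closed-loop IDM completes 100 seeded episodes of every
scenario without collision; that property is what makes it acceptable as
the safety fallback.

Reward (the environment's own design; per step, bounded):
`+0.1·max(0, 1 − |v − v_ref|/v_ref)` for speed keeping, `−10` on
collision or near miss, `−0.01·(Δa)²` for comfort (the per-step
acceleration increment, i.e. jerk·dt, keeping the term bounded by ~1.2),
and `−Ev·dt` charging the instantaneous driving risk field. The
collision penalty dominates everything else an episode can accumulate.
Doubling or halving individual weights changes learning speed but not
the ordering of the guided and unguided arms in the seeds examined.

## Guided TD3 (`nets`, `agent`)

Networks are numpy MLPs (ReLU hidden layers, tanh actor head, manual
backprop verified against finite differences, Adam). Defaults follow
standard TD3: two 256-unit hidden layers, α = β = 3e-4, γ = 0.99,
ρ = 0.995, batch 256, policy delay 2, exploration noise 0.1, target
smoothing noise 0.2 clipped at 0.5, 1000-step warm-up. Target-policy
smoothing is included (and switchable off) even though the plain
critic-target formula omits it. Observations are scaled by fixed
constants (positions /100 m, velocities /20 m/s) before entering the
networks.

The switching rule a = (1 − k)·a_RL + k·a_IDM is exact at both gate
values. The behavior-cloning term k·‖a_IDM − π(s)‖² shares the actor's
learning rate and carries an optional weight (default 1). The replay
buffer stores the *executed* action (so critics learn on executed
behavior) plus a_IDM for the cloning term; storing the RL proposal
instead is available behind `store_executed_action=False`, since either
convention is defensible.

The training protocol alternates gated training episodes with agent-only
test episodes (gate forced 0, no exploration noise, no updates), 30
pairs by default. Experiments in the test suite run a reduced setting —
two 32-unit layers, batch 128, 300-step warm-up, 15 episode pairs, five
seeds on the emergency-braking scenario — which keeps the full A/B
comparison (oracle-gated versus plain TD3) to a few minutes while
preserving the qualitative effect: higher test-episode reward in most
seeds and a lower mean per-episode maximum of the risk field during
early training.

## Metrics and statistics (`evalstats`)

* Risk field: |Ev| = G·R₂·M/|r|^{k₁}·exp(k₂|v₂|cos θ₂) with G = 0.001,
  R₂ = 1, M = 1705 kg, k₁ = 1, k₂ = 0.05. θ₂ is measured between the
  relative position vector (taken from the front agent toward the ego,
  so a leader driving away gives θ₂ = π and a decaying exponential) and
  the other agent's velocity; the simulator computes the angle from the
  actual vectors, so a crossing pedestrian contributes cos θ₂ ≈ 0.
* TTC = (gap − l)/(−gap rate) while closing; +∞ when the gap is constant
  or opening (and excluded from minima unless no closing ever occurs);
  0 exactly at contact.
* Jerk by central differences (one-sided at the ends); positive and
  negative samples averaged separately, 0 when a sign has no samples.
* Group comparisons: robust z-scores use the median and 1.4826·MAD;
  |z| > 3 observations are dropped (on pair differences in paired mode)
  before a one-sided Wilcoxon signed-rank (paired) or rank-sum
  (independent) test; fewer than 3 survivors is an error, not a p-value.
* Classifier families: Friedman omnibus (statistic 0, p 1 when every
  subject ranks all models identically), then Nemenyi pairwise p-values
  from the studentized range distribution on mean-rank differences
  (rank 1 = best).

## Known limitations

* The generator's hemodynamics are canonical, not subject-specific; real
  recordings would add artifact classes the pipeline has never seen.
* The simulator is longitudinal-only; the cut-in is an instantaneous
  merge and the pedestrian a point agent.
* The reward function, physical action bounds, timestep and termination
  rules are this package's own stand-ins — the architecture under study
  specifies none of them.
* With 30 episode pairs the agent does not converge to an optimal
  policy; the claims tested are comparative (guided versus unguided),
  not absolute.
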