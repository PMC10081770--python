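# Methods

`wristpd` re-implements, as a tested analysis pipeline over synthetic
data, a wrist-accelerometer workflow for Parkinson's disease (PD): block
spectral features, patient-vs-control separation, diary-aligned symptom
envelopes, ordinal accelerometer scoring with drug/task contrasts, and
VAE movement-state embeddings.  This note documents the models, their
assumptions, the numerical choices, and what the synthetic results do and
do not show about real data.

## Synthetic data generator

The generator (`wristpd.synthdata`) emulates 50 Hz tri-axial wrist
accelerometry in g units.  A recording is

    a(t) = g(t) + m(t) + n(t)

with `g` a unit gravity vector drifting as a spherical random walk
(~1°/min — slow posture change), `m` voluntary movement, and `n` white
measurement noise (sd 0.01 g).  Movement is a bout mixture of everyday
activities (default 50 % sitting, 20 % standing, 30 % walking; bout
lengths log-normal, ~8 min median).  Task signatures: walking carries a
gait fundamental in 1.5–2.5 Hz with two harmonics; standing has postural
sway plus occasional weight-shift transients; finger-to-nose combines a
slow 0.3–0.5 Hz arm-transport oscillation with 5–8 Hz contact bursts;
repeated arm movement is a large 0.7–1.1 Hz oscillation; sitting is
gravity plus noise.

Symptoms follow the standard clinical phenomenology, each scaled by a
0–4 severity:

* **tremor** — additive narrow-band oscillation at `tremor_freq` (5 Hz,
  jittered ±0.15 Hz per event), amplitude `tremor_amp·severity/4`
  (default 0.15 g at severity 4) with slow amplitude modulation;
* **bradykinesia** — the <4 Hz part of voluntary movement is scaled to a
  power factor `1-(1-brady_attenuation)·severity/4` (default floor 0.25,
  i.e. −6 dB at severity 4), via a zero-phase band split so the
  components recombine coherently;
* **dyskinesia** — additive band-limited (1–8 Hz) irregular activity,
  RMS `dyskinesia_amp·severity/4` (default 0.10 g at severity 4).

Levodopa (drug ON) multiplies tremor/bradykinesia severity by
`drug_effect` (default 0.5) and divides dyskinesia severity by it — the
polarity the scoring analysis must recover.

Patients in the home-monitoring scenario carry a **constitutive** mild
symptom load (per-subject severities drawn uniformly from
`baseline_severity`, default 0.5–2 for tremor and bradykinesia) plus
**episodic** worsening events (Poisson, default 8 tremor and 4+4
other events/day; log-normal durations, 20 min median, clipped 5–90 min;
severity uniform 1–4).  The constitutive component matters: PD motor
signs are present throughout the day, and it is what makes *aggregate*
patient spectra differ from controls (low-frequency attenuation, tremor
band elevation).  With purely episodic symptoms the aggregate contrast is
much weaker.  Diaries report only the episodic events, with start/end
jittered by N(0, `diary_jitter_sd`²) (default 3 min) and 5 % of durations
inflated twofold; timestamp glitches drop 0.5–10 s runs of samples at
Poisson times (default 0.5/h).

Default scenario: 8 patients, 8 controls, 8 h per subject.  Eight hours
(~40 blocks/subject) is the smallest span at which per-subject mean
spectra are stable enough to characterise; it also keeps a full cohort
in memory (~0.6 GB) and the end-to-end analysis in tens of seconds.

What the generator does **not** emulate: physiological gait dynamics,
orientation-dependent wear effects, heart-rate streams, diurnal activity
structure, or clinically calibrated amplitude scales (severities are
calibrated to be detectable above the 0.01 g noise floor, not to UPDRS
magnitudes).  Passing tests therefore demonstrate that the pipeline
recovers known structure of this class, not clinical performance.

## Blocks and spectra

Recordings are segmented into 65536-sample blocks (21.8 min at 50 Hz)
with a 32768-sample hop, so interior samples are covered exactly twice.
Blocks are aligned to the recording start.  A block is rejected when any
inter-sample interval exceeds `gap_tol` (1 s) or its observed span
deviates from the nominal span by more than `drift_tol` (1 %); the
acceptance percentage is floor-rounded.  The gap/drift thresholds are
exposed in configuration since any specific cut-off is a judgement call.

Spectra: per channel, mean removal, Hann taper (to control leakage into
the tremor band), real FFT, one-sided power density, averaged within
eleven log-spaced bins over 0.25–25 Hz (single default so every analysis
shares a feature space), then `10·log10(power + 1e-12)`.  Mean (not sum)
within a bin makes bins comparable as densities; empty bins fall to the
−120 dB floor.

Derived channels:

* **g-aligned** (g, dg, ddg): the gravity estimate is a causal
  first-order exponential smoother with `alpha = 1 - exp(-2*pi*0.1/fs)`
  (0.1 Hz low-pass), good when the wearer is still and deliberately
  rough otherwise; `dg` is the component of the first difference of the
  unit gravity vector orthogonal to it; `ddg = g x dg` completes a
  right-handed orthonormal triad.  Realising the third axis as a cross
  product (rather than a second differential) guarantees orthonormality;
  degenerate samples (constant gravity direction) fall back
  deterministically to the least-aligned device axis, orthogonalised.
* **PC channels** (pc1, pc2): for each FFT frequency the complex
  coefficient triplet describes an ellipse in 3-space; pc1 ≥ pc2 are the
  singular values of the 3x2 matrix [Re c, Im c] — the ellipse semi-axes
  — and are invariant to fixed rotations of the device frame (verified
  to 1e-9 under random rotations).  They are binned as mean squared
  amplitude in dB.

## Cohort separation

Per (channel, bin), a Welch-type score over pooled blocks:

    z = (mean_P - mean_C) / sqrt(var_P/n_P + var_C/n_C)

with unbiased variances and block counts n; subjects are deliberately
not the replication unit, so z measures aggregate contrast, not a
subject-level inference.  Classification uses per-subject mean x-channel
spectra, an L2 logistic model (lambda = 1, standardised features — any
linear discriminative model consistent with the approach) under
leave-one-subject-out, AUC as the Mann-Whitney statistic of held-out
scores.  The permutation null re-runs the entire LOO loop per label
permutation: held-out scores are pessimistically biased under the null,
so a band around 0.5 computed from fixed scores would be wrong.

## Symptom envelopes

Diary events are mapped to tremor vs other movement symptoms, reported
durations above two hours rejected (self-reported long durations are
unreliable), and analyses anchored at the event midpoint.  For offsets
k = −K..K (default K = 5, ±54.6 min; configurable — the temporal window
is a judgement call), the spectral block whose centre is nearest to
`midpoint + k·hop` is selected; cells are masked, never imputed, when no
block centre falls within half a hop.  Matching block *centres* (not
starts) makes offset 0 the block centred on the event.

The shared symptom signature is the rank-1 factorial model

    L_itfc ~ N(u_t v_f w_c + b, sigma^2)

fitted by least squares (the Gaussian MLE) with alternating exact
coordinate updates over u, v, w, b on observed cells only; the event
index i is marginalised — envelopes are shared across events, which is
how the formula reads (none of u, v, w is indexed by i).  Initialisation:
b = grand mean, (u, v, w) from leading singular vectors of the
event-averaged tensor's unfoldings; convergence at relative objective
change < 1e-8 (absolute floor 1e-12 for noiseless data) or 1000
iterations; the objective is asserted non-increasing.  The fit is
identifiable only up to scale and sign, so the gauge is fixed: v and w
unit-norm with their largest-magnitude element positive, scale absorbed
into u.  A constant tensor has no factorial structure and returns u = 0
with a degenerate flag.

Limitation worth knowing: the rank-1 term captures whatever (t, f, c)
structure dominates the tensor.  On activity-heavy backgrounds that is
the static average spectrum shape (tens of dB of range), not the symptom
contrast; on rest-dominated recordings — where resting tremor is
actually characterised — the tremor spike at 5 Hz is the leading
structure and the temporal envelope peaks at offset 0.  The envelope
analyses therefore use a rest-dominated activity mix, and events-only
(no constitutive) symptom load so the event contrast is what is being
estimated.

## Ordinal accelerometer scores and drug effects

Per symptom, a proportional-odds (cumulative-logit) model maps the 66
spectral features (device + g channels, 11 bins, dominant hand only) of
a task replicate to the 0–4 observer score.  Cutpoints are parametrised
as (c0, log-gaps) so monotonicity holds by construction; the L2 penalty
applies to weights only; optimisation is L-BFGS with analytic gradients;
lambda is chosen by subject-grouped 5-fold cross-validated held-out
negative log-likelihood (grouping prevents subject leakage).  The
*accelerometer score* is the linear predictor, standardised over the
scored set (the raw scale is arbitrary; only contrasts are meaningful).

Drug/task effects: `score ~ task * drug` with random intercepts for
subject and session, fitted by REML (statsmodels MixedLM), falling back
to OLS when the mixed fit fails.  This is a deliberately simpler
surrogate for a full Bayesian hierarchical model; it preserves the
replication structure (subject, task, drug state, session) without
committing to priors.  `drug_delta` per task is the fixed-effect ON−OFF
contrast; `signal_strength` is the SD of observed scores within the task
(how much symptom signal the task exposes — a declared surrogate, since
"relative strength" has no canonical definition); confidence intervals
are percentile intervals over ≥200 subject-level bootstrap resamples.
With every task replicated under both drug states, the OLS variant
reduces exactly to differences of cell means, which the tests use as a
closed-form oracle.

## VAE movement states

Ten-second windows (500 samples x 3 channels, standardised per channel
within the window, flattened channel-major to 1500 values; windows
crossing timestamp gaps dropped; non-overlapping) are modelled by a
fully connected VAE: encoder 1500-400-(20, 20), symmetric decoder,
ReLU, unit-variance Gaussian likelihood (MSE reconstruction term), KL
weight 1, reparameterised sampling, Adam (lr 1e-3, batch 128).  The
model and its gradients are implemented directly in NumPy — at this size
a framework adds nothing — and training is exactly reproducible given
the seed.  Defaults (epochs 30; analyses use 20) keep training to a few
minutes on one CPU; the ELBO trace is recorded per epoch and its
reconstruction/KL decomposition is asserted in tests.

Downstream, tasks are classified from latent *means* (not samples) with
a standardised MLP of two 50-node hidden layers, under five-fold CV
grouped by subject (identity leakage would otherwise inflate accuracy).
Transfer is evaluated by encoding a freshly generated cohort with the
trained VAE and applying the already-fitted classifier.  Expected
behaviour on the six-task scenario: accuracy well above the 1/6 chance
level, confusion concentrated within task families (walking vs its
variant; sitting vs standing), and above-chance transfer.  Per-window
standardisation discards absolute amplitude and orientation, so tasks
differing mainly in those respects (sitting vs standing) remain the
hardest pair — visible in the confusion matrix.

## Pipeline

Stages (simulate, blocks, spectra, cohort, envelope, score, vae) write
plain CSV/JSON artifacts into a run directory and a manifest listing
every artifact with the configuration and seeds; every stochastic stage
has an explicit seed and the configuration round-trips losslessly
through JSON.  The numbered drivers under `analysis/` are thin
narrations over these stages; all computation lives in the library so
tests and the acceptance script import the same code paths.
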