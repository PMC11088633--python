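# Methods

`reafference` is a synthetic-data reimplementation of a population-level
analysis of how the cerebellum cancels self-generated (reafferent) vestibular
signals.  Primate anterior-vermis Purkinje cells receive vestibular,
neck-proprioceptive and motor-related inputs; their simple-spike responses to
head motion are strongly attenuated - or even sign-reversed - when the motion
is self-produced, and their inhibitory convergence onto deep-cerebellar
(rostral fastigial) neurons can construct the suppression of reafference
observed there.  No public recordings exist for this paradigm, so the package
pairs every analysis stage with a generator that emulates the study's
behavioural conditions and population statistics; all quantitative claims in
this note refer to synthetic data.

## Behavioural conditions and kinematics

Six conditions are modeled, all rotations about the yaw axis (positive =
ipsilateral to the recorded side):

* **whole-body** - head and body rotate together (vestibular stimulation
  only); machine-driven 1 Hz sinusoid, 40 deg/s peak velocity;
* **body-under-head** - body rotates beneath a stationary head (neck
  proprioception only); same sinusoid;
* **head-on-body, passive** - the head is rotated on a stationary body,
  replaying active-like trajectories;
* **head-on-body, active** - self-generated head turns: raised-cosine
  velocity half-cycles, 500 ms duration, default 110 deg/s peak
  (27.5 deg displacement, capped at the behavioural +-30 deg range), with
  ~10% amplitude and +-20 ms onset jitter across trials;
* **combined** - active head-on-body movement atop a passive 1 Hz, 40 deg/s
  whole-body sinusoid, with the passive/active velocity decomposition stored
  exactly;
* **attempted** - the head is unexpectedly restrained: kinematics are zero
  while a logistic neck-torque waveform rises past 1 N.m (5%-of-range
  crossing at t = 0).

All traces are sampled at 1 kHz; positions, velocities and accelerations are
analytic, mutually consistent to the O(dt^2) of a numerical derivative.

## Ground-truth Purkinje cells

Each cell has a vestibular channel driven by head-in-space motion and a neck
channel driven by head-re-body motion, each a (position, velocity,
acceleration) triple that may differ between rotation directions.  In the
regression basis (head motion, body motion) this is c_head = a_vest + a_neck
and c_body = -a_neck, which lets vestibular-insensitive cells respond to
head-on-body motion while staying silent during whole-body rotation.

Default population statistics (configurable; fractions follow the recorded
population, distributions are the package's calibration):

| parameter | default | origin |
|---|---|---|
| bimodal / unimodal / vestibular-insensitive | 0.70 / 0.20 / 0.10 | reported fractions |
| motor-responsive | 0.80 | reported fraction |
| active-sign same / flipped / other | 0.50 / 0.40 / 0.10 | reported fractions |
| tuning linear / rectifying / V-shaped | 0.70 / 0.15 / 0.15 | calibrated |
| type I / II | 0.5 / 0.5 | convention |
| passive sensitivity | lognormal, median 0.4 (sp/s)/(deg/s), sigma 0.5 | calibrated |
| response phase | N(0, 10) deg | calibrated |
| resting rate | lognormal, median 70 sp/s, sigma 0.3 | typical simple-spike rates |
| cancellation gain k, same-sign | N(0.92, 0.03) clip [0.84, 0.99] | 92% mean attenuation |
| cancellation gain k, flipped | N(1.12, 0.05) clip [1.02, 1.30] | sign reversal, >80% reduction |
| rate noise | additive Gaussian, sd 10 sp/s, white | stated default |

"Calibrated" parameters are not printed in the source study; they were chosen
once so that the synthetic population reproduces its measured outcomes (the
92% mean preferred-direction attenuation, and the hypothesis-sweep population
sizes below) and are never adjusted per run.

### The efference-copy template

For motor-responsive cells the motor-related response is the negative of the
cell's own predicted sensory reafference, scaled by the cancellation gain k:
for executed movements the template predicts the trial's own kinematics
(perfect self-prediction - an idealization), for attempted movements the
stereotyped intended profile.  Active responses therefore equal the sum of
the passive and attempted responses *exactly*, and the active/passive
sensitivity ratio is (1 - k): attenuation and sign reversal emerge from one
mechanism.  The template lead defaults to 0 ms (a forward model compensates
the efferent delay); timing analyses generate populations with a 20 ms lead,
which reproduces firing-rate onsets ~20 ms before movement onset.  Cells
without a motor response are attenuated on the sensory side instead, which
deliberately breaks additivity for that 20% of the population.

Rates are rectified at 0 sp/s after noise.  Trial-averaged rates for the
population model may be drawn directly at sd/sqrt(n) ("averaged" noise mode),
which is exact for Gaussian noise up to per-trial rectification (negligible
at the default operating point).

## Single-cell analyses

**Kinematic regression.**  Firing rate is regressed on bias + position +
velocity + acceleration of one or more kinematic channels, solving the
all-non-negative and all-non-positive hypotheses per channel (bounded least
squares) and keeping the lowest-residual combination; VAF = 1 -
var(residual)/var(total).  A trial-level nonparametric bootstrap (default
n = 2000; desk-scale runs use 200-300) yields percentile 95% CIs and
coefficients whose CI spans zero (within a 1e-9 solver tolerance) are set to
exactly zero and the model refit.  Whole trials are the resampling unit, and
whole-body plus body-under-head sessions are fit jointly so the head and
body channels are dissociable.  Single-frequency sinusoids make position and
acceleration collinear with the bias within a channel, so only the velocity
term of a pure-sinusoid fit is uniquely identified; transient profiles do not
have this degeneracy.

**Gain and phase.**  Retained coefficients map to a signed sensitivity and a
phase in (-90, 90] at f = 1 Hz (the half-cycle duration).  The
single-argument arctangent form is used exactly as written, with the channel
sign carrying the other half-plane; a zero velocity coefficient maps to the
+-90 deg limit.

**Tuning classes.**  Direction-resolved sensitivities classify cells as
linear (increase in the preferred direction, decrease in the other,
magnitudes within 0.2 (sp/s)/(deg/s)), rectifying (sub-threshold modulation
in the non-preferred direction), V-shaped (increase in both directions), or
other; type I/II follows the direction of the larger sensitivity.

**Combined-condition ratios.**  The combined condition is fit with separate
passive-head and active-head channels (full term sets, positions and
accelerations reconstructed from the stored velocity decomposition);
sensitivities normalized by the passive-alone sensitivity give the
exafference and reafference encoding ratios.

**Motor-response test.**  Per attempted trial the statistic is mean rate in
(0, 100) ms minus mean rate in (-300, -100) ms; the neuron-level statistic is
the trial average, the null permutes pre/post labels within trials
(sign-flips), and Benjamini-Hochberg controls the family at 0.05.  The test
runs per direction; a cell is motor-related if it responds in at least one
direction.  At the default noise and a 10-trial attempted budget the test
detects a minority of the truly motor-responsive cells (the 0-100 ms window
captures only the rise of a velocity-shaped template); at lower noise the
detected fraction converges to the true 80%.

**Timing.**  Onsets are 5%-of-range crossings of 4-parameter logistic fits
(initialized from the 10-90% rise; fits whose range is within the noise
floor return "no onset"; transient bumps should be fit on their rising
phase).  The sliding correlation uses causal 40 ms windows stepped by 1 ms -
causal so that a pre-movement significance onset cannot be produced by
post-movement samples - with the threshold the upper 95% bound of
baseline-epoch ((-300, -100) ms) correlations, floored by the analytic
Pearson null bound for the window length, and a >= 10 ms sustained-
exceedance rule (population-mean curves use a 40 ms rule).

## The linear-summation test

Responses in the passive head-on-body, attempted and active conditions are
vectorized in the (-50, +100) ms window around (attempted-)movement onset.
The attempted condition is fit against the mean active head velocity (the
intended-movement proxy); window fits use the velocity regressor at the full
1 kHz rate - position moves < 3 deg there and is collinear with the bias,
and downsampling white-noise rates only discards information.  The vectors
are not bootstrap-pruned: zeroing a small attempted vector would bias the
difference-of-vectors prediction.  The complex sum of the passive and
attempted vectors predicts the active vector; each cell is evaluated in the
direction of its larger motor-related response, and observed active gains
and phases are regressed on the predictions (OLS; slope 1 = perfect
calibration) with the fraction of sign agreements reported.  Prediction
records are restricted to cells with a significant motor response - cells
without one have nothing to sum.  On additive populations within the linear
operating range the prediction is exact at zero noise, and at the default
noise the gain regression reaches R^2 ~ 0.94 with a slope CI covering 1.

## Population readout of the target neuron

Trial-averaged rates (100 movements per direction - consistent with sessions
in which attempted trials are <5% of several hundred active movements) are
stacked over both directions and the included conditions; one non-positive
weight per Purkinje cell (inhibitory synapses) plus an unconstrained
intercept (the equations carry no bias, but ~70 sp/s resting rates would
otherwise forbid a zero target during passive blocks) are fit by NNLS on
negated columns.  Traces are downsampled to 200 Hz for the readout.

**Cancellation model.**  The target is the negative of the vestibular
afferent reafference (head velocity x unit gain) during active movement and
zero during passive blocks; the design spans whole-body, passive
head-on-body and active head-on-body only - including an attempted block
with a zero target would, by the generator's exact additivity, make any
nonzero active-block output linearly infeasible.  Suppression is measured
out-of-sample: weights fit on one replicate of trial averages, residual
reafference on an independent replicate, over the movement epoch (samples
with afference > 5% of peak).  The criterion is a residual <= 30% of the
afference (>= 70% suppression), the statistic the median over 20 selection
draws per population size N.  Compositions: H1A/H1B - a single same-sign /
sign-flipped cell; H2 - same-sign cells only; H3 - half same, half flipped.
Under the default calibration single cells and the same-sign composition
cannot reach the criterion (H2 stays above it through N = 400), while the
mixed-sign composition reaches it at roughly 40-60 cells: cancelling the
passive response while producing the active-block signal requires pairing
cells whose active responses differ in sign.

**Target-neuron model.**  The reference deep-cerebellar neuron encodes
passive head velocity at 0.5 (sp/s)/(deg/s) (15 deg phase lead), active head
velocity at 30% of that (70% suppression), and is flat during attempted
movements; its trial budget is 20 (previously recorded reference data are
tens of trials).  The fit uses all four conditions and the full
vestibular-responsive pool - the non-motor and weakly-attenuated cells supply
the active/attempted discrimination the readout needs.  R^2 versus N is
summarized over random cell subsets with percentile CIs; N_match is the
smallest N whose CI overlaps the reliability band 1 - SEM^2/var(target).
The full-population model (N = 200) reproduces the 70% suppression within
+-5 points with one weight vector across all conditions, and its systematic
output (weights applied to noise-free responses) modulates by < 5% of the
passive response during attempted movement.  The largest single |weight|
typically carries ~25-30% of the total weight mass (NNLS solutions are
sparse); weight magnitudes do not differ detectably across modality, type,
tuning or motor subclasses (Kruskal-Wallis).

**Augmentation and mossy fibers.**  Extra cells are drawn from per-class
Gaussians over (log sensitivity, phase, log neck ratio, cancellation gain,
log resting rate) - log-magnitudes, since sensitivities are positive and
right-tailed - preserving the source sensitivity distribution
(two-sample KS).  Simulated mossy-fiber inputs sum an independent vestibular
and neck response with gains 0.6 +- 0.1 (sp/s)/(deg/s) and phases 20 +- 5 deg
(doubling/halving variants available) and enter the target-neuron fit as one
additional non-negative column.

## Problem sizes and numerical choices

Desk-scale defaults: hypothesis sweeps use a 1200-cell pool, 20 draws per N,
a 20-point grid to N = 400 (about half a minute end to end); the target
-neuron analyses use 600-cell pools; per-neuron fitting stages downsample
trials five-fold except the 1 kHz summation windows.  Ascending-grid sweeps
stop at the first passing N.  All randomness flows through
`numpy.random.default_rng` seed chains, so identical configurations produce
byte-identical artifacts; JSON artifacts map non-finite values to null.

## What passing tests do and do not show

The generator realizes the study's *reported statistics* with idealized
structure: responses live exactly in the kinematic regression basis
(plus rectification), the efference copy predicts executed movements
perfectly, trial noise is white Gaussian on the rate, and eye movements,
complex spikes and plant biomechanics are absent (torque is a stylized
waveform).  Recovery of the calibrated attenuation, the summation R^2
regime, or the hypothesis-sweep population sizes therefore validates the
analysis chain - estimators, constraints, statistics and their calibration -
not the biological claims themselves.  Known sensitivities: temporally
correlated rate noise (available via `NoiseModel(corr_ms=...)`) sharply
reduces the effective sample count of every epoch average and degrades
motor-response detection, summation recovery and the cancellation noise
floor; the mixed-sign population size depends on the (unprinted) phase
spread, tuning-class mix and flipped-cell magnitudes, for which the
calibrated values above are one consistent choice; and OLS of observed on
predicted gains is attenuated when prediction noise is comparable to the
true gain spread, which is why the summation checks run on linear-range,
onset-aligned populations.
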