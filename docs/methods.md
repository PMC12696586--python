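# Methods

## The model in brief

`godiva-aos` is an event-level implementation of the bilateral GODIVA
account of acquired apraxia of speech (AOS). In the intact model, each
well-learned syllable has a speech sound map (SSM) neuron population
(premotor cortex / anterior insula, 80 % of neurons in the left
hemisphere). A syllable is initiated when its population crosses the
normal-readout threshold T = 400 (80 % of the maximum activity 500); its
motor program is then read out with the baseline feedforward weighting
α_ff = 0.85, the remainder α_fb = 1 − α_ff going to the (right-lateralised,
slow) auditory/somatosensory feedback controller. Toward the end of each
syllable, the articulatory configuration of its final phone cues a
transient putamen D2R pulse — the shift-preparation trigger — which
quenches the active population and opens the preparation window in which
the next population climbs toward threshold.

A lesion destroying a fraction of left-SSM neurons (default 22.25 % of the
left hemisphere, i.e. 17.8 % of all SSM neurons) caps every population
below threshold. The speech system is assumed to force readout anyway, and
three consequences follow:

1. **Graded feedforward weighting.** At syllable initiation with activity
   s < T, the readout weighting is α_ff = 0.85 · s/T. The initial phone of
   the syllable is prolonged by P_estimate times the percent change of α_ff
   from baseline, with P_estimate = −2.142 (calibrated elsewhere on a 150 %
   phone prolongation at a 70 % weighting reduction). α_ff enters this
   formula truncated to two decimals; truncation, not nearest rounding, is
   what reproduces the worked values (0.85·332/400 = 0.7055 → 0.70 →
   37.8 %), and the untruncated weighting is reported alongside.
2. **Alternative shift timing.** Threshold crossings can no longer time the
   shifts. Transitions instead use: a learned fixed period after the
   shift-preparation trigger (mechanism I, the default; the period equals
   the control-condition trigger-to-shift gap); the memorized control
   duration of the ongoing syllable, for short syllables whose
   syllable/duration combination is frequent (mechanism II, applied to
   'the'); or the memorized latency from the utterance-initiation signal,
   for the first syllable (mechanism III). At the utterance start
   mechanism III takes precedence over II.
3. **Trigger displacement.** Prolonging the initial phone pushes the final
   phone — and hence the trigger cue — late. Short syllables suffer the
   full delay (trigger = control position + prolongation). Long syllables
   catch up: the trigger is moved back to its control-relative position and
   the final phone is truncated by the prolongation (an error is raised if
   the truncation would consume the whole final phone).

The chain 1→3 produces the domino ("extra-low-activity") effect: a delayed
trigger into a mechanism-II shift squeezes the next syllable's preparation
window, so it initiates at very low activity, prolongs its own initial
phone massively, and — if it is short — delays its outgoing trigger by the
same amount. In the fixture utterance "here is the potato" this lengthens
'po' from 122 ms to ≈259 ms (+112 %) while every long syllable keeps its
control duration.

## Timing calibration

All times are milliseconds from the utterance-initiation signal at t = 0;
syllable intervals are half-open [onset, shift). The control timeline is
fully determined by the syllable durations (278/147/96/122 ms for
here/is/the/po; 'po' is 122 ms, the value consistent with the full event
timeline, with 120 ms accepted in configs) plus:

* onset latency 145 ms (first shift 423 ms minus 278 ms),
* per-transition trigger leads 42/21/30/25 ms (differences of the control
  trigger and shift times); the leads out of 'ta' and 'to' are not
  constrained by any reported value and default to 25 ms,
* 'ta' = 180 ms and 'to' = 160 ms control durations, also unconstrained
  defaults, configurable.

The sub-threshold activity rise is a saturating exponential
A(w) = A_dyn·(1 − e^−(w−t_lat)/τ) of the preparation window w, with
asymptote A_dyn = 390 (the ceiling the lesioned system approaches but
never exceeds). τ and t_lat are not stored: `default_calibration()` solves
them numerically from the two anchor points A(21) = 332 and A(11) = 133 —
the two activity levels tied to known preparation windows — giving
τ ≈ 6.72 ms and t_lat ≈ 8.20 ms. Below t_lat no activity accrues.

The first syllable's preparation window is not observable; it defaults to
the first syllable's own trigger lead (42 ms for 'here'). With the default
calibration, long syllables therefore initiate at activities 358–387.5 and
receive prolongations of 7.6–22.7 %. These values are emergent and
unconstrained; the two constrained initiations ('the' at 332, 'po' at
≈132.5) reproduce their anchors by construction. A zero lesion bypasses the
sub-threshold machinery entirely and reproduces the control timeline
event-for-event.

## Traces

Continuous time courses are derived *from* the event timeline (0.33 ms
grid), not the other way round: each SSM series rises along the calibrated
exponential, rescaled to attain exactly the recorded initiation activity at
its shift-in time, holds during execution, and decays with a 5 ms constant
once its outgoing D2R pulse (rectangular, 20 ms wide, amplitude 450 a.u.)
fires. Pulse width, amplitude and decay constant are presentation
parameters with no effect on any reported quantity.

## Comparison metrics

Syllable lengthening is 100·(d_AOS − d_control)/d_control. Stress contrast
uses the pairwise variability index, PVI = 100 · mean over adjacent pairs
of |d_k − d_{k+1}| / pair mean, computed on **total** syllable durations;
acoustic studies often use voiced portions only, so absolute PVI levels are
not comparable across the two, only directions of change. Designated
unstressed–stressed pairs are adjacent (short, long) syllables — ('po','ta')
in the fixture.

A caveat the test suite makes explicit: with the default 'ta' = 180 ms the
PVI of ('po','ta') drops under the lesion (38.41 → 36.06), but because the
lengthened 'po' (≈259 ms) is independent of 'ta', the reduction only holds
for 'ta' above ≈178 ms; for shorter 'ta' defaults the lengthened 'po'
overshoots and the pair contrast grows. The contrast-reduction claim is
therefore conditional on the stressed syllable being long enough, not a
structural invariant.

## Synthetic functional connectivity

No clinical series are distributed, so the FC module generates them:
per subject, 216 volumes at TR = 2.2 s for the six model ROIs, as
multivariate Gaussians. A group is parameterized by a target 6×6
correlation matrix and a per-pair between-subject SD on the correlation
scale; each subject perturbs the target by N(0, SD) per pair (clipped to
±0.97, repaired to the nearest-PSD matrix by eigenvalue clipping) and draws
their series from the resulting covariance. Heterogeneity is applied on the
correlation scale rather than the Fisher-z scale because the reported group
statistics are means and SDs of r: z-scale noise followed by tanh would
bias the group mean r downward (≈0.38 instead of 0.42 for the strongest
pair). The helper `subject_sd_r` subtracts the within-subject sampling
variance (1 − r²)²/(T − 3) from the reported SD so the *observed*
between-subject spread matches the report.

The two emulated groups are 16 "aphasia-only" and 15 "AOS-plus-aphasia"
subjects; three pairs carry group differences (left SSM lateral–right
articulator 0.25 vs 0.01; left–right articulator 0.42 vs 0.11; right
SSM–left articulator 0.12 vs −0.09, SDs as reported) and the remaining 12
pairs are null with a nominal background heterogeneity of 0.25. The
pipeline is per-subject Pearson r per pair → Fisher Z → per-pair Welch
t-tests (the groups' SDs differ, so the unequal-variance form is the
defensible default) → Benjamini–Hochberg FDR across the 15 pairs at
q < 0.05. Under this parameterization the left–right articulator pair is
detected in roughly 56–59 % of seeded replicates and the familywise
false-positive fraction under a null configuration is ≈3.5 % — the group
sizes put the printed effects near the detection boundary, which is
faithful to the small-sample setting being emulated.

What the generator does **not** emulate: autocorrelated BOLD noise, head
motion, global-signal regression, eigenvariate extraction from voxel
spheres, or lesion-dependent signal dropout. Passing tests show the
*pipeline* behaves correctly on series with the reported second-order
statistics, not that real data would reproduce them.

## Numerical choices and degenerate inputs

* α_ff truncation to 2 decimals uses floor(100·α + 1e−9)/100; the 1e−9
  guard absorbs float dust just below a tick.
* The activity-rise solve uses `scipy.optimize.fsolve` from (τ, t_lat) =
  (5, 5) and rejects solutions with residual > 1e−8; a closed-form identity
  cross-checks it in the tests.
* Negative activities, negative preparation windows, over-truncated final
  phones, trigger leads longer than their syllable, and frequent-combo
  flags on long syllables are all rejected with errors naming the culprit.
* Event construction validates global ordering (one utterance onset, one
  shift per boundary, onset < trigger < shift per syllable).
* The whole event pipeline is closed-form; runs are bit-reproducible. Only
  the FC module is stochastic and takes an explicit seed.

## Problem sizes

The default test and acceptance workloads are desk-scale: six-syllable
utterances (sub-millisecond to render, ≈48 k trace samples at 0.33 ms),
and 200-replicate FC simulations (31 subjects × 216 volumes × 6 ROIs per
replicate, a few seconds per 200).

## Known limitations

* The continuous neural-field dynamics of the parent model are replaced by
  the event-level rules above; traces are renderings, not integrations.
* Activity-rise constants are calibrated at the default lesion; other
  lesion fractions reuse them (the lesion gates sub- vs supra-threshold
  behaviour but does not rescale A_dyn).
* Initiation activities of syllables other than 'the' and 'po' are
  emergent from the default windows and should not be read as fitted.
* Non-initial phone durations are not modelled; long syllables absorb
  prolongation purely by final-phone truncation.
* Utterance termination uses mechanism I with the last syllable's lead; it
  is a convention, not a claim.
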