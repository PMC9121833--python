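# Methods

## The analysis problem

A recording session on a Y-maze alternates two behavioral phases: the
*trial* (the rat runs from the start-arm origin to the end of a chosen goal
arm, ~6.5 s) and the *intertrial interval* (ITI; the self-paced return,
~55.6 s).  Spikes from a simultaneously recorded medial-prefrontal
population, 30 Hz position tracking, per-trial labels (direction choice,
light position, outcome), and slow-wave-sleep (SWS) intervals flanking
training make up one session.  The package asks, on such sessions:

1. **Subspace separability** — do the population firing-rate vectors of the
   two phases occupy linearly separable low-dimensional subspaces?
2. **Feature decoding** — which task features can a linear decoder read out
   from each phase's activity, against a label-shuffle chance level?
3. **Decoding-axis geometry** — what angle do the two phases' decoding axes
   for the same feature subtend, and does a decoder trained on one phase
   transfer to the other (cross-decoding)?
4. **Behavior** — is the session a learning session, and where does the
   reward rate change?
5. **Sleep reactivation** — is phase- and feature-specific activity
   preferentially revisited in post-training SWS?

All analyses operate on *population rate vectors*: the N-vector of spike
counts divided by interval durations, over half-open intervals, restricted
to the *active* neurons (those firing at least one spike in every trial
interval).  Times are seconds at 0.1 ms resolution; trials are 1-indexed.

## Core procedures

**Separability.** The 2T phase vectors (trials and ITIs interleaved in
temporal order) are column-centered and projected onto the top d principal
axes (d = 1..4).  A linear soft-margin SVM (C = 10^3, acting as a hard
margin whenever the data are separable) supplies the separating direction;
the reported error is the *minimal training misclassification over
intercepts along that direction*.  This makes the score a geometric
separability measure rather than a hinge-loss artifact: on 1-D projections
it equals the exhaustive optimal-threshold error exactly, and it is
invariant to phase relabeling and to common rescaling of the centered data
(an internal global rescale feeds the SVM).  Training error is reported
deliberately — the question is how separated the point sets are, not how a
classifier generalizes.  Chance is the majority-phase proportion (0.5 for
the balanced trial/ITI design).  Section-pair maps use the same machinery at
d = 2 on per-section rate vectors.

**Decoding.** The decoder everywhere is L2-regularized logistic regression
(inverse penalty C = 1.0) on features standardized with the training fold's
mean/SD; held-out labels are predicted at the 0.5 probability threshold
(ties to the positive class).  Accuracy is leave-one-out (LOO); chance is
the mean accuracy over label permutations (50 by default), which absorbs
label imbalance.  *Relative accuracy* = accuracy − shuffle mean.  Label
conventions: trial rows decode the current trial; ITI rows decode the trial
just completed (their "previous" trial — the ITI after trial i carries
trial i's labels); "following" shifts one trial forward and drops the last
row.

**Axis geometry.** For each feature the full-data decoder weights (mapped
back to raw rate units by dividing out the standardization) give w_t(f) and
w_I(f); the angle is arccos of their clipped normalized dot product.
Shuffled-label refits provide reference angles, and the SD over LOO-fold
axes (each against the full-data axis) quantifies within-phase axis
stability.  Cross-decoding trains on all of one phase's vectors and scores
the other's (a LOO variant guards against training-set optimism); its null
permutes trial indices and applies the same permutation to both phases,
preserving the pairing.

**Maze linearization.** Position samples are projected onto the two-segment
skeleton start-arm origin → center → chosen-arm end (85 cm per segment);
the linear coordinate is normalized arc length, cut into five equal
sections.  Samples farther than 8 cm from the skeleton are excluded.  The
outbound phase of each ITI begins at the first run of ≥400 ms of samples
whose heading points within 90° of the start-arm origin; headings are
backward differences of a 3-sample moving average.  The backward difference
keeps the detector from anticipating the reversal by more than one raw
sample (a centered difference plus smoothing anticipates by ~2 samples,
which matters when validating the ~1.14 s reversal delay); the cost is up
to ~3 samples of lag when there is no arm-end pause at all.

**Behavior.** A *learning session* contains three consecutive correct
trials followed by ≥80% correct through the session end (window includes
the run; the first of the three is the learning trial).  Otherwise a
metadata rule-change trial defines the split; otherwise the split maximizes
r_after − r_before with at least 5 trials on each side.  Reward rates are
slopes of robust lines (bisquare IRLS, tuning constant 4.685, ≤50
iterations) fit to the cumulative reward curve on each side of the split;
2-point and constant segments fall back to exact least squares.

**Reactivation.** The template for (feature, value, phase) is the mean rate
vector over matching rows.  Each SWS interval is tiled from its start with
equal bins (trailing partial bin dropped; 1 s default, sweep 0.1–10 s every
0.15 s, 67 sizes bracketing the ~6.5 s trial).  Spearman rank correlation
(average ranks; constant bins excluded with counts kept) of the template
with every pre and post bin yields two distributions; the statistic is
M_post − M_pre, the difference of medians, with a two-sample KS test
between the distributions.  The within-epoch control differences the two
values of a feature against the *same* epoch and should center on zero.
This is *reactivation* — rank alignment with a subspace region — not
sequence replay.

## The synthetic-session generator

The generator emits sessions with exactly the structure the analyses probe,
plus the implanted ground truth:

- **Rates.** Each neuron's baseline is softplus of a Normal draw
  (mean log 5 ≈ 1.61, sd 0.5 by default → ~1.8 Hz typical, yielding
  realistically small active populations).  The phase mean adds ±s/2 along a
  random unit *offset direction* (s = `phase_separation`, default 4 Hz),
  plus Σ_f β_f·x_f·c_f^phase where c_f^trial and c_f^ITI are unit axes with
  a configurable angle α_f between them (default π/2) and x_f ∈ {−1,+1}
  encodes the current trial's labels in trial phases and the just-completed
  trial's labels in ITIs.  Per-phase-instance Gaussian rate jitter
  (`rate_noise_sd`, 0.5 Hz) is added, rates are floored at 0.1 Hz, and
  spiking is homogeneous Poisson within each phase.
- **Behavior.** Outcomes are Bernoulli(p_before = 0.4) before the optional
  learning trial and Bernoulli(p_after = 0.85) after; light sides are
  pseudorandom; the direction is the rule-correct arm exactly when the
  outcome is 1, with a 5% lapse that flips both consistently.
- **Trajectory.** Uniform-speed piecewise-linear motion along the maze
  skeleton, out during the trial, paused at the arm end for
  `outbound_delay` (1.14 s), then back; sampled at 30 Hz and quantized like
  real tracking.
- **Sleep.** Two SWS epochs (default 1200 s each) tiled into 1 s segments;
  with probability ρ_pre/ρ_post a segment's rate vector is a noisy scaled
  copy (lognormal, sd 0.3, per neuron) of a randomly chosen feature-specific
  trial mean vector, otherwise a random permutation of the baseline vector.
- Identical (config, seed) reproduce byte-identical bundles; cohorts derive
  per-session seeds from one master seed.

**What the generator does not emulate:** refractoriness, bursting, theta
modulation, place fields, behavioral state drift within a phase, section-
dependent coding (coding is constant along the maze), or realistic SWS
microstructure.  Passing recovery tests therefore certify the *analysis
chain* — that implanted separability, coding geometry, change points, and
reactivation gains are recovered — not that real cortical data behave like
the model.

## Validation-study designs (fixed, with rationale)

- **Angle recovery** (N = 12, T = 40, 20 seeds per implant α ∈ {0, π/4,
  π/2}): high-SNR implant — baseline softplus mean 20 Hz, gains 12 Hz,
  rate noise 1.75 Hz.  Two biases shape the recovered between-phase angle:
  estimation noise in the fitted axes inflates small angles, and the
  decoder being a *whitened* discriminant (other features' coding variance
  enters the within-class covariance differently in each phase) pushes
  intermediate angles toward π/2.  Large gains shrink the first; the
  moderate isotropic rate noise dilutes the second.  Medians recover the
  implants to well within 0.1π.
- **Separability** (20 seeds each): the strong cohort (s = 12 Hz, baseline
  ~10 Hz so all neurons stay active and the offset direction survives
  truncation) classifies perfectly at d ≤ 2.  The null cohort (s = 0, no
  gains) uses *matched* phase durations (ITI 6.5 ± 0.5 s): with real-length
  ITIs the two phases differ in Poisson estimation noise, a dispersion
  asymmetry that an optimal threshold exploits by itself, so matching
  durations is what makes the phases exchangeable under the null.
- **Null calibration**: the chance estimator checked is the *mean over 25
  label shuffles* (the quantity the pipeline subtracts), 200 runs at
  T = 16.  A single shuffled LOO accuracy is not binomial(0.5) — LOO folds
  share training data, giving overdispersion and a pessimism bias that cap
  the single-shuffle in-band rate near 85% at any T; the shuffle-mean
  estimator sits comfortably inside the binomial band.
- **Cross-decoding** (8 seeds per α): aligned implants transfer (cross ≈
  within-phase accuracy); orthogonal implants drop cross accuracy into the
  shuffle-null band.
- **Change-point identifiability**: on noiseless step sequences learning-
  trial detection is exact.  On Bernoulli 0.4 → 0.85 sequences (T = 40,
  change at trial 15) *no* estimator localizes the change within ±2 trials
  much more than ~60% of the time — the optimal binomial-likelihood
  change-point estimator measures 57/100, the learning-criterion split
  57/100, a continuous-hinge fit 62/100, and the two-line robust-slope
  argmax 28/100 (edge-attracted).  The detection rate reported by the
  acceptance script (~0.6) is the information limit of these sequences, not
  an implementation ceiling.
- **Reactivation** (100 + 200 seeds): baseline softplus mean log 8 with sd
  0.8 — Spearman reactivation measures *cross-neuron rank structure*, so
  baselines must actually differ across neurons (at near-constant baselines
  the lognormal template noise swamps the ranks) — and full 1200 s sleep
  epochs for median precision.  ρ 0.1→0.4 yields a positive statistic in
  ≥95% of seeds; ρ equal gives sign-balanced statistics and paired controls
  centered on zero.

## Numerical choices

- PCA centers columns before the eigendecomposition (an uncentered switch
  exists); axes carry a deterministic sign (largest-magnitude component
  positive); d above the matrix rank raises.
- Logistic ties at probability exactly 0.5 predict the positive class.
- Spearman uses average ranks; constant vectors are undefined and excluded
  (feature templates: an error; sleep bins: dropped with counts logged).
- Robust slope fits fall back to exact least squares for 2-point or
  constant segments, where IRLS is ill-posed.
- Sessions serialize times at 0.1 ms (half-even); `load(write(s))` is
  bit-exact for quantized sessions.
- All stochastic steps (generator, shuffles, permutation nulls) draw from
  explicitly passed seeds or generators; the pipeline derives per-session
  streams from one master seed and reproduces byte-identical reports.

## Problem sizes

Validation cohorts use 8–12 neurons, 10–40 trials, and sleep epochs of
30–1200 s; oracle comparisons run on instances of at most 8 trials and 4
neurons, where brute-force refits and exhaustive scans are feasible.  These
sizes match the scale of the recordings the analyses target (populations of
4–22 active neurons, 7–51 trials per session).

## Known limitations

- The reported separability is training-set misclassification by design;
  it should not be read as generalization performance.
- Decoder axes are reported in raw rate units after unwinding the
  standardization; with strongly heteroscedastic populations the axis is
  the whitened discriminant, not the mean-difference direction.
- The inbound/outbound split depends on heading detection; sessions whose
  ITIs never turn toward the start are flagged degenerate rather than
  resolved.
- Rule-change sessions rely on metadata for the switch trial; nothing is
  inferred from behavior when the learning criterion fails.
- With fewer than ~3 active neurons rank correlations and decoders are
  undefined; such sessions are skipped and logged, mirroring the exclusion
  of under-sampled recordings.
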