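# Methods

## The scale

Each stimulation trial of one hind paw is reduced to three features: the
composite nocifensive score (count of orbital tightening, paw shake, jump,
paw guard; each binary, so the composite is an integer 0–4), paw height
(mm above the mesh floor at the withdrawal apex) and paw speed (mm/s,
lift-to-apex displacement over elapsed time). The composite is an
*unweighted* count: the behaviors are treated as exchangeable evidence of
a nocifensive response. This is the minimal reading of "combining" four
binary behaviors and keeps the score interpretable; it is an assumption,
not a derived weighting.

Fitting uses a baseline table containing all four natural stimuli (CS,
DB, LP, HP):

1. **z-scoring.** Means and sample SDs (denominator n − 1) are computed on
   the *pooled* baseline population, all stimuli together. Transformed
   training features have column means 0 and sample SDs 1 to 1e-9.
   A constant feature column is an error naming the feature; at least 3
   trials are required.
2. **PC1.** The loadings are the unit-norm leading eigenvector of the
   3×3 sample covariance of the z-features (`numpy.linalg.eigh`). If the
   two leading eigenvalues tie within 1e-12 the fit aborts (the component
   is not identified) rather than picking silently. The sign is oriented
   so the mean score of HP trials exceeds that of CS trials: positive
   PC1 = pain-like. With balanced classes and pooled centering this puts
   CS means below 0 and HP means above 0.
3. **SVM + calibration.** An RBF-kernel SVM (γ = 1, C = 1; scikit-learn
   SVC) is trained on the scalar PC1 scores of CS (label 0) and HP
   (label 1) trials only, at least 5 per class. Support vectors, dual
   coefficients and intercept are extracted so prediction recomputes the
   decision function `f(s) = Σ αᵢ exp(−γ(s − sᵢ)²) + b` from stored
   arrays; a serialized model therefore reproduces its predictions
   bit-identically after reload. Probabilities come from a Platt sigmoid
   `P = 1/(1 + exp(a·f + b))` fitted by minimizing the calibration
   negative log-likelihood (Nelder–Mead, fixed initialization, smoothed
   targets (N₊+1)/(N₊+2) and 1/(N₋+2)). No internal cross-validation is
   used: the training sets are tiny and one-dimensional, so CV folds
   degenerate; the smoothed targets provide the regularization instead.
   Training inputs are sorted by (score, trial id) before fitting so the
   result is independent of row order.

Scoring new data always applies the stored means/SDs/loadings/SVM;
appending trials to a table never changes the scores of earlier trials.

**Pain boundary.** The reported `pain_threshold_pc1` is the PC1 value at
which the calibrated probability crosses 0.5, found by grid scan plus
bisection *bracketed between the CS and HP training-class mean scores*.
An RBF decision function decays to its intercept far outside the training
support, so the probability curve can recross 0.5 in the far tails; the
crossing between the class means is the one that separates innocuous from
noxious responses.

**Decision rule.** `pain_call = 1` iff `pain_probability > 0.5`.

## Traditional von Frey scoring

Filaments are applied in ascending force order; the threshold is the
smallest force whose withdrawal proportion is ≥ 40% (2/5 qualifies
exactly), `None` if no force qualifies. When the threshold falls below
10 g, the percent response at 10 g is 100 × withdrawals/5 over exactly
five trials. Trials per force defaults to 5 where the count is not
stated by the protocol.

## Kinematic feature extraction

Trajectories are fixed-rate (default 2000 Hz) keypoint series with the
floor at y = 0; the floor, not the resting paw posture, is the height
reference. Defaults live in one `KinematicsParams` object.

* **Lift onset.** A lift exists when paw height exceeds the pre-stimulus
  baseline median (50 ms window) by `delta` (1 mm) for ≥ 3 consecutive
  frames — the persistence requirement suppresses single-frame tracking
  glitches. The reported onset time is refined with a hinge
  (changepoint) least-squares fit — flat baseline switching to a linear
  rise — over a window spanning the crossing. A plain threshold
  crossing lags the true onset by `delta`/slope, several frames for
  slow shallow lifts; the hinge fit removes this bias and is robust to
  0.2 mm tracking noise.
* **Height and speed.** The apex is the global maximum of paw height in
  (onset, onset + 0.5 s]; movements later than 0.5 s are guarding, not
  withdrawal. Speed uses the 2-D (x, y) Euclidean displacement between
  the paw position at onset and at apex over the elapsed time
  (lift-to-apex is a path-endpoint distance); a vertical-only mode is
  available behind a flag. With multi-peak withdrawals the global
  maximum in the window defines the apex — a package choice, not a
  claim about the original protocol.
* **Paw shake.** In [apex, apex + 0.3 s], the slow guard-decay trend is
  estimated with a Savitzky–Golay filter (window ≈ 1.2 periods of the
  slowest accepted oscillation, order 2) and subtracted. Cycles are
  counted as hysteresis sign changes of the smoothed residual (deadband
  = half the 0.5 mm amplitude band) divided by two. The shake flag
  requires ≥ 2 cycles, a dominant periodogram frequency ≥ 10 Hz, half
  peak-to-peak amplitude ≥ 0.5 mm, and a periodogram peak at least 20×
  the median bin power — the last two guards keep broadband tracking
  noise, which has no dominant line, from counting as a shake.
* **Orientation order.** The head-orientation time is the first
  post-stimulus crossing of 45° toward the stimulus; the statistic is
  whether the paw lifted first. Per-rat proportions are averaged across
  rats ("percentage of rats"); a per-trial alternative is a flag.
* Only the paw shake is detected automatically; orbital tightening,
  jump and guard remain manually scored inputs. Jumping is probably not
  detectable from a single-paw keypoint and is not attempted.

## Synthetic data

The generator exists so every stage is testable without animal data. It
emulates the *structure* of the real designs, not their effect sizes:

* Behaviors and withdrawal are Bernoulli; heights and speeds are
  lognormal (positive, right-skewed). Per-stimulus parameters are
  ordered CS < DB < LP < HP on every feature.
* Von Frey parameters are anchored at the DB (touch) level and ramp
  linearly in log-force by at most 15% of the DB→LP gap at 300 g, with
  withdrawal probability rising 0.5 → 0.95: reliable withdrawal reflexes
  whose quality stays touch-like. This realizes the construction in
  which filaments evoke withdrawals but not pain.
* Drug effects multiply behavior probabilities, kinematic medians and
  withdrawal probability of *noxious* trials by
  `m(T, s) = 1 − w(T)·(1 − drug_factor(s))`, with timepoint weights
  w(baseline) = 0, w(15 min) = 1, w(60 min) = 0.6. Innocuous trials are
  never affected, and von Frey trials are morphine-insensitive unless
  explicitly configured otherwise. Scenario defaults: direct 3 mg/kg
  timecourse `drug_factor = 0.4` (so 15-min effect < 60-min effect < 1);
  multigenerational 1 mg/kg `drug_factor` 0.5 for morphine-sired vs 0.9
  for saline-sired males (12 subjects/group, 3 trials per stimulus).
  These magnitudes are package constructs — the original effect sizes
  are only available graphically and were not calibrated to.
* Each subject carries a shared lognormal frailty (σ = 0.15) multiplying
  its behavior probabilities and kinematic medians, so trials cluster
  within subject and subject-level resampling is meaningful. Frailty
  does not scale withdrawal probability: it models response magnitude,
  not whether the spinal reflex occurs, and a configured-certain (p = 1)
  noxious withdrawal must stay certain.
* All randomness flows from one master seed through a named stream per
  subject (`SeedSequence` keyed by a CRC of the group/subject name), so
  adding a group never perturbs another group's draws.
* Synthetic trajectories are piecewise: flat baseline, quarter-sine rise
  to the apex (steep initial slope, flat at the apex), a
  truncated-cosine shake riding just *below* the decaying guard envelope
  (so the noiseless trace maximum equals the configured apex height
  exactly), exponential decay to a guard height, optional head/eye
  channels, additive Gaussian noise. The returned truth record carries
  the exact onset, apex, height, expected speed and shake parameters.

What passing tests on this generator do **not** show: real paw tracking
has autocorrelated, occlusion-prone noise rather than i.i.d. Gaussian;
real behaviors are correlated within a trial beyond a shared frailty;
real morphine pharmacodynamics are not a two-point multiplicative
timecourse. Results on synthetic cohorts demonstrate that the pipeline is
correct and adequately powered under its stated assumptions, not that the
biological effect sizes are as configured.

## Group analysis

Timepoint contrasts use a paired sign-flip permutation test on
subject-level means (two-sided; all 2ⁿ sign patterns enumerated when
2ⁿ ≤ 4096, otherwise 9999 random flips with the identity included).
Sire contrasts use a label-shuffle two-sample permutation test
(scipy). These replace repeated-measures ANOVA with Sidak post hocs —
a deliberate, assumption-light substitution; multiplicity within a
report table is handled with Holm adjustment. Group-mean uncertainty
is a cluster bootstrap resampling subjects, not trials.

Simulation sizes used by the test suite were chosen to give stable
Monte-Carlo estimates at desk scale: 500 seeds for null calibration of
the paired test (n = 10 subjects, exact enumeration), 150 seeds per
point of a three-point power curve, 100 replicates of the
multigenerational experiment, and 200 trajectories for kinematic
parameter recovery.

## Known limitations

* Paw side is not modeled (responses do not differ between paws).
* The SVM consumes PC1 only, not the three z-features; where a single
  strain×sex group is analyzed separately, fit separate models on
  subsets (`--filter`) — the mathematics does not change.
* Platt calibration on small, well-separated 1-D training sets yields
  steep sigmoids; probabilities very close to 0/1 should be read as
  ranks, not literal frequencies.
* The composite score treats the four behaviors as equally weighted;
  any true differential salience (e.g. guarding vs grimace) is folded
  into PC1 only through the kinematic covariates.
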