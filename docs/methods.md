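# Methods

## Scope

The package models the *planning* side of personalized, parcel-guided
theta-burst stimulation: everything from parcellated BOLD time series to
a stimulation prescription and pulse schedule, plus outcome
classification. Image-level processing (motion realignment, skull
stripping, slice timing, distortion correction, spatial smoothing) is out
of scope — inputs begin at parcel resolution. Neuronavigation, electric
field modelling and motor-threshold estimation are likewise out of scope;
the 30-mm depth cap stands in for coil reach.

## Preprocessing (parcel level)

Order is fixed: **scrub → detrend → confound regression → variance
normalization**; permuting the order changes the result, so the driver
enforces it.

* **DVARS** is computed over parcel series (the voxel-level definition
  has no parcel-resolution analogue): `dvars[t]` is the RMS over parcels
  of the frame-to-frame signal change, with `dvars[0] = 0` as a
  placeholder. Frames with DVARS above `mean + 2·SD` (one-sided — motion
  only inflates DVARS; the statistics come from frames 1..T−1 of the raw
  series, computed once) are dropped, not interpolated: covariance
  estimation needs no temporal contiguity. If fewer than `P + 2` frames
  survive, the series is flagged rank-deficient and shrinkage becomes
  mandatory downstream.
* **Detrending** removes per-parcel intercept + linear + quadratic
  trends, fitted on the retained frames' original indices so scrubbing
  does not warp the time axis.
* **Confound regression** uses a parcel-level CompCor surrogate: the
  noise pool is the top decile of parcels by variance (at least
  `c + 1` parcels so the pool is never annihilated by its own
  components), and the confounds are the first `c = 5` principal
  components of the pool's standardized series. Collinear columns are
  dropped with a warning. Global signal regression is deliberately not
  performed.
* **Normalization**: each parcel is scaled to unit variance over retained
  frames after confound regression. Whether normalization precedes or
  follows scrubbing is not externally constrained; this package
  normalizes last and documents it here.

## Connectivity and tangent embedding

Subject connectivity is the sample covariance of the normalized series
(a correlation matrix up to sampling), shrunk toward the scaled identity,
`(1−s)C + s·(tr C/P)·I` with `s = 0.1` by default, to guarantee strict
positive definiteness even when frames < parcels. Shrinkage-regularized
covariances — not raw correlations — enter the tangent map, the
established construction for tangent-space connectivity; raw correlations
remain available for reporting.

The reference point is the affine-invariant **Fréchet mean**, computed by
the standard fixed-point iteration started at the arithmetic mean and
stopped when the Frobenius norm of the mean log term falls below 1e−6
(max 50 iterations; non-convergence is an error carrying the last
residual). Tangent embedding uses symmetric eigendecomposition for the
matrix square roots and logarithm. Tests cross-check both operations
against independent oracles (scipy's inverse-scaling-and-squaring `logm`,
a closed-form geodesic midpoint, and a derivative-free manifold-descent
optimizer).

## Normative model and anomaly calling

Per upper-triangle edge, the model stores the cross-subject mean and
sample SD (ddof = 1) of the reference tangents. The highest-variance
third of edges — `ceil(E/3)`, ties at the cutoff broken by edge index
ascending — is excluded outright: those connections are too noisy in
healthy subjects to define a normal range, and removing them curbs false
discoveries. Exclusion is global (computed before any network
restriction) and is performed in tangent space, the same space where
scoring happens. Patients never enter the normative fit.

Scoring uses strict inequalities at |z| > 3. Network restriction keeps
only edges with **both** endpoints inside the selected networks
(matching per-network square anomaly matrices); cross-network edges among
several implicated networks survive when those networks are selected
together. Restricted-out edges are re-flagged "excluded" but keep their z
for audit. Heatmaps encode hyper = red, hypo = blue, normal = white,
variance-excluded = black.

**Measured specificity.** With mean and SD *estimated* from a 200-subject
reference, the null |z| > 3 exceedance is not the idealized Gaussian
2·Φ(−3) = 0.0027 but the finite-sample rate
`2·sf_t199(3/√(1+1/200)) ≈ 0.0031`; with the default synthetic cohort
(which adds per-subject coupling variability, see below) the long-run
measured rate is ≈ 0.0035 across reference seeds. The acceptance test
asserts the idealized band and is expected to fail at this precision;
the discrepancy is a property of z-scoring against estimated moments,
not of the implementation.

## Target prescription

Anomaly burden is the per-parcel count of incident non-excluded flagged
edges. Candidates are cortical parcels with burden ≥ `min_burden`
(default 3 — "numerous anomalies" quantified as a configurable floor)
and scalp depth ≤ 30 mm (deeper targets are beyond effective field
strength; subcortical structures are never candidates). Ranking is by
total burden descending, ties by hyper count descending then parcel id
ascending, truncated to three targets. Protocol assignment: cTBS when
hyper ≥ hypo (the tie goes to cTBS, following the cohort's 69/76 cTBS
predominance), iTBS otherwise; a parcel with no anomalies is not a
candidate. An empty prescription carries a machine-readable reason.

## Theta-burst protocols

Both protocols use three-pulse 50-Hz bursts (20-ms intra-burst spacing)
repeated every 200 ms (5 Hz), at 80 % of resting motor threshold.

* **iTBS**: 2-s trains (10 bursts, 30 pulses) × 40 trains = 1200 pulses.
  The 2-s train duration is derived — it is forced by 1200 pulses / 40
  trains / 3 pulses per burst at 5 Hz. The 6.3-s inter-train interval is
  read as the *gap* between train end and next onset, so the protocol
  spans 40·2 + 39·6.3 = 325.7 s.
* **cTBS**: one continuous train. The published description ("600
  stimuli … 1800 pulses") is internally consistent only if a "stimulus"
  is a burst, so the default delivers 600 bursts = 1800 pulses over
  120 s; conventional cTBS-600 (200 bursts, 600 pulses) is available as
  `mode="conventional"` / `--ctbs-bursts 200`.
* **Session**: targets stimulated in rank order with a configurable
  60-s inter-target pause (plumbing, not a published constant).
* **Course**: 5 sessions/day × 5 days with 1-h gaps between sessions;
  an infeasible day (sessions + gaps > 24 h) is an error.

## Outcome analysis

Response: BDI decrease ≥ 47 % from baseline (baseline 0 is an error —
the percent change is undefined). Remission: BDI ≤ 12, boundary
inclusive. Severity bands: 0–13 minimal, 14–19 mild, 20–28 moderate,
29–63 severe. Cohort rates use all patients as the post-treatment
denominator and follow-up completers only for follow-up rates; missing
follow-ups are never imputed. The treatment-resistance flag (≥ 2 failed
adequate antidepressant trials) is taken as data, not derived.

Longitudinal mixed-effects modelling with multiplicity-corrected post-hoc
tests was deliberately replaced by descriptive per-timepoint summaries
plus a Mann-Whitney rank-sum comparison of percent BDI change between
TRD and non-TRD patients: the replaced machinery is routine off-the-shelf
statistics orthogonal to this package's purpose, and the summary labels
itself accordingly. The rank-sum test enumerates all
`C(n1+n2, n1)` group assignments exactly (ties included) when both
groups have ≤ 8 observations, and otherwise uses the tie-corrected
normal approximation with continuity correction; the exact mode is
verified against brute-force enumeration and scipy.

## Synthetic data: what it emulates, and what it does not

`CohortSpec` defaults are the study's acquisition and normative-sample
conditions: 200 reference subjects, 128 volumes at TR 2.8 s; 60 parcels
(4 networks × 15) is the test scale and 377 (180 × 2 cortical + 17
subcortical) the full-scale parity configuration.

Subjects follow a latent network-factor model: one latent series per
network (DMN, CEN, Salience, Other), correlated across networks, plus
parcel noise. Couplings are parameterized so that `within = 0.35` and
`between = 0.12` are exactly the baseline population correlations —
typical magnitudes for parcel-level resting-state data. Two deliberate
departures from homogeneity make the pipeline's assumptions meaningful:

* a designated 10 % of parcels carries 3× noise SD, emulating the
  artifact-dominated regions the CompCor step is designed to capture
  (without a stable noise pool, the confound components would strip
  random shared-signal directions instead);
* each subject jitters its per-network loadings (SD 0.2), giving
  network-coupled edges genuinely elevated cross-subject variance — the
  heterogeneous edge-variance profile the highest-variance-third
  exclusion presumes.

Patients are reference subjects whose *population* covariance is shifted
on chosen edges, so injected anomalies pass through the entire pipeline
including preprocessing. The shift realizing a requested tangent-space
z is calibrated empirically: a probe amplitude pushed through the full
pipeline gives a linear estimate, and a second probe at that estimate
applies one multiplicative correction for the tangent map's
nonlinearity. Requests that would leave the positive-definite cone are
scaled down jointly with a warning (the realized z then falls short of
the request). Calibration against the 200-subject reference holds the
realized mean z within a few percent of the request; magnitude-5
injections are recovered at |z| > 3 with ≥ 95 % sensitivity and correct
sign.

Outcome records draw integer BDI baselines from a truncated normal
(mean 25.2, SD 7.7 on [1, 63]) and construct post/follow-up scores to
hit requested responder/remitter counts; a remitter-non-responder
requires baseline ≤ 22 and a responder-non-remitter baseline ≥ 25, so a
few baselines are redrawn inside the feasible band when a cohort draw
cannot support the requested mix. EQ-5D indices are clipped to [−1, 1];
follow-up intervals are truncated at one month.

What the generator does **not** emulate: hemodynamic response and
autocorrelated noise (frames are white in time), scanner drift beyond
polynomial trends, real motion artifact structure (DVARS spikes arise
only from sampling variability unless injected), non-Gaussian BOLD
amplitude distributions, and any spatial geometry beyond a synthetic
depth/centroid table. Passing tests therefore validate the pipeline's
statistical logic and bookkeeping, not its behaviour on real scanner
data.

## Problem sizes and determinism

The test suite fits one session-scoped reference (200 subjects × 60
parcels), scores 15 null patients for specificity, and uses 50 replicate
patients per injected-edge condition; full-scale 377-parcel structures
are exercised where cost is trivial (atlas construction, correlation
entry counts, normative exclusion counts on small random stacks). Every
stochastic operation takes a single seeded `numpy` generator, seeds are
recorded in output metadata, and identical spec + seed reproduces output
byte-identically; the pipeline driver writes a resolved-config snapshot
and hash with every run.

## Known limitations

* Depth is an atlas attribute; no scalp-surface computation is attempted.
* The normative model assumes exchangeability between the reference
  cohort and patients (acquisition and preprocessing parity).
* The 3-sigma rule is applied per edge with no further multiplicity
  control beyond variance exclusion — by design.
* The exclusion step's "highest-variance third" is a hard fraction; on
  cohorts with homogeneous edge variance it degenerates to selecting on
  estimation noise (see the specificity note above).
* Tangent-space z-scores inherit the finite-reference t-tail; users who
  need calibrated false-positive rates at small reference sizes should
  widen the threshold accordingly.
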