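# Methods

`ethoproto` discovers prototypical movement components in continuous
behavioural recordings without prior definition of behavioural
categories.  This note documents the model, its parameters, the
numerical choices, and what the synthetic test beds can and cannot show.

## Overview of the procedure

1. **Feature extraction.**  A 6-DOF trajectory (3-D position + yaw/
   pitch/roll at a fixed sampling step, canonically 1 ms) is optionally
   smoothed and differenced into six body-frame velocities per time
   step: forward/sideward/upward (m/s) and yaw/pitch/roll (deg/ms).
   The body frame makes the features independent of where the animal is
   and which way it faces, so recurring manoeuvres map to recurring
   feature vectors.
2. **Normalization.**  Each feature is z-scored (zero mean, unit sd) so
   that translational and rotational velocities, whose physical units
   are incommensurable, contribute comparably to squared-Euclidean
   distances.
3. **Ward pre-scan (optional).**  Agglomerative clustering under Ward's
   criterion on modest subsequences; the joining-cost elbow bounds the
   range of cluster counts worth scanning.
4. **Restarted k-means.**  Lloyd's algorithm from k random data rows,
   restarted (default 12 times) with the lowest-variance run retained.
5. **Validation.**  For every candidate k and every data condition
   (full data, and systematic leave-out of 10/20/50% contiguous blocks
   at 50 equidistant cut positions) the clustering is repeated; the
   *instability* of each collection of centroid sets and the *quality*
   of its mean set are computed, and k is chosen by stability-gated
   quality maximization.
6. **Segmentation.**  Each time step is assigned to its nearest
   prototype; maximal constant-label runs are the prototypical
   movements, and their run lengths the movement durations.

## Stability

Two centroid sets of equal cardinality are compared by matching their
centroids one-to-one with the Hungarian algorithm, minimizing the sum
of squared Euclidean distances; that sum, divided once by the number of
centroids k and once by the number of features F, is the configuration
distance.  Among m repeated clusterings the *mean set* is the one with
the smallest mean distance to the other m−1; that minimal mean distance
is the collection's *instability*, and the reported uncertainty is the
standard deviation of the mean set's distances divided by m (kept
literally in this form, although sd/√m is the conventional standard
error, because the divided-by-m form is the definition this measure was
introduced with).

The full-data condition repeats the clustering with different random
start seeds; each repetition is itself a restarted k-means.  A single
un-restarted Lloyd run would measure the roughness of the k-means
objective landscape rather than the stability of its optimum — on a
clean five-cluster benchmark single runs produce instabilities two
orders of magnitude above those of restarted runs, which contradicts
the intended reading of the full-data curve as near-zero for all
reasonable k.

Leave-out masks remove one contiguous block of round(N·fraction)
samples starting at round(p·N/50), wrapping past the sequence end so
every mask keeps the same number of samples.  Normalization parameters
are computed once on the full data and reused for the reduced sets, so
centroids from all conditions live in one space and can be matched
(re-normalizing each reduced set separately would conflate scale shifts
with genuine configuration changes).

## Quality

Cluster j's quality is the squared separation/compactness index

    Q_j = min_{i≠j} ||c_j − c_i||²  /  σ_j²,

where σ_j² is the mean squared distance of the members to centroid c_j.
The mean of Q_j over clusters scores a whole clustering.  Both numerator
and denominator are in squared-Euclidean units; this reading of the
"squared" index is isolated in one function (`validate.cluster_quality`)
for easy revision.  A mean set obtained on reduced data is always scored
on the *full* data, with membership recomputed by nearest-centroid
assignment.  A cluster with σ_j² = 0 reports Q_j = ∞ and is excluded
from the mean with a warning.

## Choice of k

Stability is a prerequisite; quality ranks the stable candidates.  A
candidate k is admissible when its between-condition instability is at
most `stability_factor` (default 2) times the minimum over the scanned
range, **or** below an absolute floor of 0.01 normalized units.  The
floor exists because the relative rule degenerates when the minimum is
at numerical-noise level (~1e-5): without it, other k whose instability
is equally "zero for all practical purposes" (1e-4, say) would be
rejected as 10× the minimum.  Instabilities below ~1e-2 are
indistinguishable from reproducible in this framework.  Among admissible
k the one with the best mean (over conditions) mean-set quality wins;
ties go to the smaller k.

## Ward pre-scan and the elbow rule

Ward merge costs are variance increases,
n₁n₂/(n₁+n₂)·||c₁−c₂||²; they telescope to the total data variance
(this is asserted, along with an O(N³) brute-force recomputation, in
the test suite).  The implementation delegates the agglomeration to the
Lance–Williams recurrence (scipy's Ward linkage) and converts its
sqrt-scaled heights back to variance increases.

Joining costs grow smoothly (roughly as 1/m² in the remaining cluster
count m) even for structureless data, so a fixed multiple of the
neighbouring costs would always "detect" an elbow near the end of any
dendrogram.  The detector therefore compares each cost against an
extrapolation of the local trend: the median successive ratio of the
`window` (default 5) preceding cheaper merges, times the nearest of
them.  A cost exceeding `factor` (default 2) times that prediction
breaks the trend; the largest such m is the elbow and the suggested
scan range is [2, elbow + margin].  If nothing breaks the trend — the
expected outcome for noisy, unstructured data — the detector falls back
to [2, 50] with a warning.

## k-means details

* Start: k distinct rows drawn uniformly with the run's seed.
* Convergence: maximum centroid displacement < 1e-6 (normalized units),
  or 1000 iterations.
* Empty clusters are re-seeded at the point farthest from its nearest
  centroid, iteratively (moving a singleton's only point can re-empty a
  cluster), so returned sets never contain empty clusters.
* Restarts use consecutive seeds; the run with the lowest objective
  wins, ties to the lowest seed.
* The k-d-tree assignment path is an optional acceleration and is
  label-identical to the naive argmin (asserted in the tests); the
  naive path is the reference.

## Angular rates

The rotational velocity at step i is the relative rotation
R_i⁻¹R_{i+1} expressed as a rotation vector (axis-angle) on the body
axes, divided by dt.  For a constant rotation axis this is exact; for
the sub-2 deg/ms rates of fly-scale movement at 1 ms sampling the
difference from true instantaneous per-axis rates is below 0.1%.
Orientation is stored as Tait–Bryan yaw/pitch/roll, intrinsic Z–Y′–X″,
right-handed with x forward, y leftward, z up: positive yaw = left
turn, positive pitch = head down, positive roll = clockwise seen from
behind.  The handedness is a documented package convention, not a claim
about any particular acquisition rig.

## Smoothing

Measurement noise is suppressed with an order-2 Butterworth filter at a
relative border frequency of 0.1 (of Nyquist), applied forward and
backward (zero phase, attenuation applied twice).  The test oracle for
the filter is the analytic bilinear-warped digital response
|H|² = 1/(1 + (tan(πf/2)/tan(πf_c/2))⁴).

## Synthetic test beds

**Five-cloud benchmark** (`default_artificial_spec`): five axis-aligned
2-D Gaussian components, unequal weights (0.30/0.25/0.20/0.15/0.10),
component sd 0.7, minimal centre separation 8 (≥ 11 sd), n = 500.  In
this regime the joining-cost elbow, the leave-out instability minimum
and the mean-set quality maximum all agree on k = 5, which is what the
acceptance checks assert.

**Saccadic flight simulator** (`default_flight_spec`): a semi-Markov
alternation of nine states.  Four saccade states carry |yaw| = 1.1
deg/ms with sign-coupled roll (0.35 deg/ms) and pitch-up/down variants
(±0.25 deg/ms) plus 0.4 m/s forward drift; five intersaccade states
span forward 0.23–0.64 m/s coupled with downward 0.02–0.31 m/s and
symmetric sideward components up to ±0.15 m/s, with no rotation.  Dwell
times are gamma-distributed: saccades mean 12 ms (shape 4), so that few
saccadic segments exceed 20 ms; intersaccades mean 40 ms (shape 2), so
that most intersaccadic segments straddle the 20 ms boundary.  Within a
state the body-frame velocity is the state mean plus white Gaussian
noise, sd 0.025 m/s (translational) and 0.08 deg/ms (rotational) —
small against the between-state separations, as behavioural variability
within a stereotyped movement class is small against the differences
between classes.  The trajectory integrates these velocities exactly
(position by the rotated body step, orientation by the body rotation
vector), making integration the exact inverse of the feature
extraction.

Because the simulator injects *process* noise on velocities rather than
measurement noise on positions, the end-to-end recovery experiments run
without Butterworth smoothing; smoothing targets sensor noise, which
the simulator does not model.

**What the simulator does not emulate:** aerodynamics and inertia
(state switches are instantaneous), gradual velocity transitions
between states (real data shows smooth ramps that produce transient
misclassifications), measurement noise, long-range correlations, or
gaze-stabilizing head–body coordination.  Passing the recovery tests
therefore shows the pipeline is correct and well-conditioned on data
matching its assumptions; it does not bound performance on real
recordings, where transition smoothness and sensor noise will lower
label accuracy near segment borders.

## Problem sizes used in tests and the acceptance script

The benchmark runs at n = 500 with the full validation protocol
(k = 2..12, three leave-out fractions at 50 positions, 12 restarts);
the flight experiment uses 60 s of simulated flight (60 000 velocity
samples, ~2 300 movement segments).  These sizes give comfortable
statistical margins for every asserted tolerance while keeping a full
run in the tens of seconds.

## Known limitations

* The quality index is undefined for k = 1 (no outer distance).
* Stability comparisons require equal cardinality; configurations with
  different k are compared only through the selection rule, never
  matched directly.
* The elbow detector is a heuristic; on data whose clusters blur into
  each other it deliberately falls back to a wide scan range.
* `duration_stats` treats each constant-label segment separately;
  adjacent segments of different prototypes in the same group (e.g. two
  saccade types back to back) are not merged.
* Very short segments are reported, not suppressed: they carry the
  classification-uncertainty signal.  `merge_short_segments` exists as
  an explicitly optional extension and is off by default everywhere.
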