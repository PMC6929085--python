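# Methods

This note documents the models, conventions, parameter choices and
limitations behind `posefit`. Everything stated here is computed by the
package's tests or the acceptance script; nothing is quoted from
external measurements except the embedded reference benchmark tables
(`posefit.reference`), which are used only for arithmetic
re-aggregation and as targets of like-for-like comparison.

## Conventions

* Quaternions are Hamilton, scalar-first `(w, x, y, z)`, encoding
  active rotations. `q` and `−q` are the same rotation; every statistic
  on quaternion components is taken after hemisphere canonicalization
  (`w ≥ 0`, ties broken on the first nonzero component) and, for
  Gaussian fits, after aligning each sample to the per-edge mean
  direction. Gaussian modelling across the double cover would be
  meaningless.
* The animation frame is taken as x-forward, y-left, z-up. Nothing in
  the pipeline depends on this labelling except the guidance
  *words* (which plane is "fore–back"); the choice is documented rather
  than asserted, and the sign rules are applied exactly as specified by
  the angle-difference formulas.
* All angles are radians; time is seconds; the default sample rate is
  40 Hz.
* Segment indices: 0 head, 1 breast, 2/3 left upper arm/forearm,
  4/5 right upper arm/forearm, 6 waist, 7/8 left thigh/shank,
  9/10 right thigh/shank. Sensors 0,1,6–10 share one local-frame init
  constant, `(0, √2/2, √2/2, 0)`; the arm sensors 2–5 share
  `(1/2, −1/2, −1/2, −1/2)`.

## Two-stage classifier

The BP-ANN is 9–15–5 with sigmoid activations and bias units, trained
on the flattened waist rotation matrix. The cost is the mean of
per-output binary cross-entropies (independent sigmoids, not softmax)
plus an L2 penalty `λ/(2m) Σθ²` excluding bias columns; log arguments
are clipped to `[1e-12, 1 − 1e-12]`. The optimizer is full-batch
gradient descent with a backtracking Armijo line search (initial step
0.5, halved on rejection, doubled between epochs, capped at 1e3), which
guarantees a monotonically non-increasing cost; training stops when the
per-epoch improvement falls below 1e-6 or after 5000 epochs. Weights
initialize uniformly in `±√(6/(fan_in + fan_out))` from a seeded
generator. Defaults: `λ = 0.01`. The analytic gradient is verified
against central finite differences to a relative error below 1e-6.

The second stage is one fuzzy C-means model per category with as many
clusters as the category has postures (`K2 ∈ {2, 4, 5}`), weight index
`b = 2`, tolerance 1e-8 on the objective, at most 500 iterations.
Because training data is labelled, centers initialize at per-posture
means (random initialization remains available), which also makes the
greedy bijective cluster→posture assignment near-trivial. A sample
coinciding with a center takes crisp membership (the singular limit); a
cluster that loses all weight restarts at the farthest sample. The
printed form of the membership denominator in the source description
repeats `m_j` where the summation index must appear; the standard
formula (sum over `m_s`) is implemented, since the printed form would
make every membership `1/K2`.

Thresholds `t1`, `t2`, `t3` are nowhere given by the reference study;
all default to 0.5 and are configurable. With `τ = 0.1` and `t3 = 0.5`,
emission needs six net supporting frames (150 ms at 40 Hz). Likelihoods
are clipped to [0, 1]; "noisy" frames leave them unchanged by default
(a decay variant is a config switch, since the original behaviour is
not recoverable from the text). The threshold crossing is strict, with
a 1e-9 guard so that accumulated `τ` steps landing exactly on `t3` (up
to float rounding) do not emit early.

Training subsamples 20 evenly spaced frames per training instance
before fitting either stage: the postures are static, so consecutive
frames are near-duplicates and the subsample loses no information while
keeping full-batch training cheap.

## Evaluation network

Per posture, one joint 8-D Gaussian per body-tree edge, fitted with
population (divide-by-m) moments. The head's parent is the breast by
default (the thoracic–neck chain); waist is the alternative, switchable
in the topology. Edges whose parent is the waist condition on the
waist's *animation-frame* quaternion, because the waist's
waist-relative quaternion is identically the identity; the waist root
itself is scored by its marginal Gaussian. This root handling is a
reconstruction — the reference study plots a score for all 11 parts but
never defines the root's.

A ridge `ε·I` is added to every covariance before inversion. Unit-norm
quaternion data leaves the covariance nearly singular along the mean
direction, where the residual variance is second order —
`~(σ²/2)² ≈ 2.5e-5` at a typical 0.1 rad angular spread — so the ridge
must dominate that scale while staying well below the informative
variances (≥ 3e-4 under the default noise model): the default is
`ε = 1e-4`.

The standard degree is the exceedance probability
`P(‖S − μ_s|t‖ > ‖s − μ_s|t‖)`: under the Mahalanobis norm this is the
χ² survival function with 4 degrees of freedom at the squared
Mahalanobis distance (closed form, the default); a Euclidean-norm
variant is estimated by Monte Carlo. The score is oriented so that
standard segments score high — the raw probability of the inequality as
written grows with distance, and the reported behaviour (standard
parts above 0.5, nonstandard below 0.3) identifies the survival
orientation as the plotted quantity. Flagging threshold: 0.3.

## Guidance

Deviation rotation: `μ_s|t⁻¹ ⊗ q_s-6` with the conditional mean
normalized to unit length and the observation flipped onto its
hemisphere. Planar differences follow the printed sign conventions
(`d ≥ 0` → backward / downward); for head and thighs the second plane
is read as left–right with `d ≥ 0` → rightward, a symmetric
reconstruction. Bend–stretch uses the x-component of the child's
longitudinal axis expressed in the parent frame, model minus actual, so
an over-bent joint yields `d < 0` → "straighten". The segment
longitudinal axis is local-x throughout (consistent with the pure
quaternion `(0,1,0,0)` in the bend–stretch construction and with the
first-column structure of the planar formulas). Corrections smaller
than 0.1 rad (configurable) are suppressed as within acceptable range.
For non-stand categories the deviation matrix is conjugated by the
category's nominal waist rotation before word selection, mapping
directions into the trainer's perspective — also a documented
reconstruction. Only three example sentences are attested
("lift up your left arm", "straighten your right forearm", "put your
left leg to right"); the remaining templates are analogous inventions.

## Synthetic data generator

The generator defines the study conditions for every test. It emulates:

* **18 posture templates in 5 categories.** Category waist rotations
  are fixed (identity; ±1.3 rad roll; ±π/2 pitch), mutually separated
  by ≥ 60°, so the first stage has a real but learnable task. Limb
  orientations are seeded random rotations of 0.7–2.2 rad, re-drawn
  until any two postures of a category differ by ≥ 20° on at least one
  segment. Template geometry is invented — the reference study shows
  pictures, not numbers — and the separation invariants guarantee the
  generator exercises, not trivializes, both classifier stages.
* **Subject offsets** (`σ_subject = 0.15` rad per axis, capped at
  0.3 rad, scaled by a per-subject lognormal flexibility factor):
  systematic body-shape differences between trainers.
* **Repetition jitter** (`σ_instance = 0.08` rad): the same subject
  does not reproduce a pose exactly across repetitions — the reference
  corpus's angle tables show between-instance ranges up to 1.2 rad.
* **Postural sway** (`σ_sway = 0.05` rad, AR(1) with a 1 s time
  constant): a held pose wobbles continuously. Without it, frames
  within an instance would be perfectly correlated and an edge
  covariance fitted from 9 instances would rest on 9 effective samples.
* **Sensor noise** (`σ_frame = 0.02` rad, white).
* **Timing:** instance durations uniform in 6–10 s at 40 Hz.

All perturbations are joint-level and propagate anatomically along the
body tree (`q_i = q_p ⊗ joint_i ⊗ ε_i`): rotating an upper arm carries
the forearm with it. This coupling is what makes child-given-parent
conditioning informative, and it confines an injected joint deviation
to its own edge — exactly the behaviour the evaluation network is built
to exploit. Deliberately nonstandard instances right-compose a known
axis–angle deviation at the named joint (default magnitudes
0.3–0.6 rad) and return the ground truth for recovery tests. Deviating
the waist root moves the whole body, so only the root's own
animation-frame score reflects it; the flag is recorded.

What the generator does **not** model: joint limits and biomechanical
coupling beyond the rigid tree, soft-tissue artifact, sensor drift or
magnetic disturbance, heteroscedastic per-segment noise, and transient
posture entry/exit. Passing tests therefore show the pipeline's
statistical machinery is correct under the assumed noise structure, not
that the accuracies transfer to any particular hardware deployment.

## Study-analog scenarios

* **Recognition analog:** 11 subjects × 18 postures × 10 instances,
  default noise, split 30/70 stratified per (subject, posture) — 3 of
  10 instances per cell train the classifiers. The test-set instance
  accuracy is the analog of the headline instance-recognition result.
* **Evaluation analog:** per-posture networks are trained on three
  *skilled* subjects (σ_subject = 0.05, σ_instance = 0.06 — a cohort
  selected for performing well sits close to the standard geometry and
  repeats it consistently), 3 instances each. The probe is a new
  trainer performing carefully (zero systematic offset and jitter, sway
  at sensor-noise scale) who deviates only the named segments. Reported:
  the fraction of frames where deviated segments score < 0.3 and
  undisturbed segments score > 0.5.
* **Guidance recovery:** the same probe model, with the network trained
  under sensor noise alone so the measurement isolates the deviation
  arithmetic from cohort bias; injected extents of 0.2/0.3/0.5 rad on
  planar and bend axes must be recovered within 0.05 rad. The
  correction scenario then reduces each deviation by the advised extent
  and reports before/after joint-angle errors; the guidance-recovery
  template uses controlled 0.9 rad elbow/knee bends about the local
  z-axis so bend–stretch differences map one-to-one onto injected
  angles.

## Problem sizes and determinism

Unit tests run on reduced instances (1–3 s durations, 2–4 subjects);
the acceptance checks run the full 11 × 18 × 10 recognition analog
(~630k frames, well under a minute) and pool three seeded evaluation
and guidance scenarios. Every random stage consumes a seed spawned from
a single run seed (`numpy.random.SeedSequence`); identical seeds give
byte-identical databases, models and summaries. Degenerate inputs are
handled explicitly: zero quaternions are rejected, samples exactly at
an FCM center take crisp membership, ties at classifier argmaxes
resolve to the lowest index, degenerate planar projections return 0
with a warning, and empty (subject, posture) split cells are skipped
with a warning.

## Known limitations

* The per-frame standard-degree score treats the fitted Gaussians as
  exact; with very few training recordings the conditional covariances
  are noisy and scores of genuinely standard frames spread downward.
  The skilled-cohort scenario quantifies this under its stated
  conditions; other cohort geometries will separate less cleanly.
* Guidance words assume the documented animation-frame axis labelling;
  on real hardware the mapping from deviation sign to "forward" vs
  "backward" must be validated once per mounting convention.
* The recognizer evaluates pre-segmented instances; continuous
  multi-posture streams (activity segmentation) are out of scope.
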