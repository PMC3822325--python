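# Methods

This note documents the processing chain, the probability model, the
synthetic data generator, and the numerical and design choices behind
them.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal chain

**Input.** A trajectory is a uniformly sampled record `(t, x, y, d)` —
gaze position in screen pixels (mathematical y-up convention; the CSV
reader can negate y for screen-convention sources) and pupil diameter
relative to the calibration baseline.  Sampling is nominally 75 Hz;
the reader tolerates a 1% jitter in the sampling interval.

**Smoothing.** Positions are convolved with the normalized binomial kernel
of order 20 (DC gain exactly 1).  Velocities are finite differences of the
smoothed positions — `np.gradient`: central differences at interior
samples, one-sided at the ends, exact for affine signals — and are
smoothed again with the same filter, so both position and velocity signals
are filtered.  Boundary handling is edge-reflection (symmetric) padding:
it preserves constants exactly and avoids endpoint shrinkage that would
fabricate spurious via-points; whole-sample reflection was rejected
because it is undefined when the kernel half-width exceeds a short
series.

**Saccade trimming.** Acceleration is the magnitude of the per-sample
velocity increment, in px/sample² — the unit in which the 0.4 threshold is
stated.  Within the first 30 samples, everything up to and including the
last sample exceeding the threshold is deleted; symmetrically from the
first offending sample within the last 5.  The two scans are iterated to a
fixpoint, which makes trimming idempotent: a single pass is not, because a
spike sitting just beyond the head window can slide into it after a first
deletion.  If a deletion would leave fewer than 2 samples the trajectory
is kept untrimmed and a `DegenerateTrajectoryWarning` is emitted — a
judgment call between the two natural contracts (warn vs. fail); failing
would make batch processing fragile against a single bad trial.

**Via-points.** Candidates are the first sample, the last sample, and
every zero crossing of ẋ or ẏ; a crossing between samples i and i+1
contributes the sample with the smaller |velocity|, and exact zeros
contribute their own sample.  A candidate is rejected when *both* its |Δx|
and |Δy| to the previously kept via-point are below `min_sep` (default
2 px) — the conjunction, not the disjunction, because a plateau in one
coordinate with genuine movement in the other is a meaningful via-point.
The final sample is always kept so that displacements telescope to the net
first-to-last displacement.  At most 15 via-points are kept,
earliest-first; the first carries displacement (0, 0) since eye writing
has no absolute reference frame.

**Auxiliary features.** `Sx`, `Sy` are the bounding-box extent in px.  `A`
is the summed one-sided power of the ẋ and ẏ spectra (rectangular window)
strictly above f₀ = 2.6 Hz, normalized so that the total over all
frequencies equals the mean square of the signal (discrete Parseval); the
x and y spectra are summed because the cutoff is meant to separate
pursuit from high-frequency components in either axis, and a resultant
speed signal would fold sign information away before the transform.
μ_p and σ_p are the mean and standard deviation of the pupil series; σ_p
is treated as an SD throughout (the symbol and its 0–5 domain fit an SD
scale, not a variance).

## Discrete domains and scales

| variable | domain | slots |
|---|---|---|
| Δx, Δy | integers −40..40 + termination well | 82 |
| ẋ, ẏ | integers −10..10 + termination well | 22 |
| Sx, Sy | 0..50 | 51 |
| A | 0..30 | 31 |
| μ_p | −1..1 step 0.01 | 201 |
| σ_p | 0..5 step 0.1 | 51 |
| L | 1–9, a–z, $ | 36 |
| H | 1, 2, 3 | 3 |

Velocities in px/s are divided by 30 before rounding into bins.
Displacements and sizes are divided by `position_scale` =
`size_scale` = 2.5 px/bin, chosen so the generator's ~100 px letter box
fills the ±40 displacement range and the 0..50 size range; `A` is divided
by `a_scale` = 100 (px/s)²/bin, chosen so that healthy trajectories
occupy the low bins and the strongest simulated tremor approaches, without
systematically saturating, the top of the 0..30 range.  These two scales
are free constants of the discretization (only the velocity scale is
canonical); what matters is that training and inference share them, and
they are recorded in the model archive.  Out-of-range values are clamped
with a warning.

Counting raw table entries over these domains, one displacement transition
term `P(Cⁱ_Δx | Cⁱ⁻¹_Δx, L, H)` has 82·82·36·3 = 726,192 entries, and the
full term set has 21,834,615 under this package's convention (all four
dimensions, first-via-point terms over the full 82/22-slot domains, 14
transition terms each, auxiliary terms, and the two priors).

## Learning

Via-point sequences are discretized, then padded to length 15 with the
termination well on all four dimensions, so "the trajectory has ended" is
itself learnable evidence: beyond a trajectory's last via-point, the
well→well transition carries nearly all the mass.  First-via-point terms
keep the well in their domain (it simply receives prior-only mass), which
keeps every table the same width as its transition siblings.

Counting gives Laplace succession laws `(nᵢ + α)/(N + αK)` with α = 10⁻⁷:
with any data the empirical frequencies dominate; with none, the slice is
the uniform 1/K.  Observed slices are then convolved along the target axis
with a truncated discrete Gaussian (support 15, variance 2 for
displacement terms; 7, 1 for velocity terms; "order" read as support
length, which must be odd) and renormalized.  The well entry is excluded
from the smearing — its mass is held fixed and the numeric part is
rescaled to the remainder — because the well is not on the numeric scale
and smearing termination mass onto geometry (or vice versa) would be
meaningless.  Unobserved slices are exactly uniform, which the
reflect-boundary smoothing maps to itself, so only observed slices need
the convolution; this makes learning at full domain sizes cheap.

`Sx`, `Sy`, `A` per (L, H) and μ_p, σ_p per H are truncated discrete
normals: sample mean and SD, density evaluated on the domain grid, zero
outside (no mass on negative sizes or energies), renormalized.  The SD is
floored at half a domain step so single-exemplar cells stay proper, and a
1e-12 uniform floor (before renormalization) keeps every domain value
representable so log-space inference never meets a hard zero for a merely
improbable observation.

Terms conditioned on the unknown symbol `$` are uniform over their full
domain *including* the well, which keeps `$` agnostic about trajectory
length.  `P(L)` and `P(H)` are uniform.  Raw counts and per-cell normal
sufficient statistics are stored alongside the tables so a confirmed
trajectory can later be added exactly.  Learning is invariant to exemplar
order bit-for-bit (integer counts; auxiliary samples are sorted before
reduction).  Cells with no exemplars keep the uniform prior with a logged
warning rather than failing.

## Inference

All posteriors are computed in log space; the hidden-variable
marginalization (over H for letter tasks, over L for disability) uses
log-sum-exp, so products of 60 small probabilities cannot underflow.  The
uniform L and H priors cancel in normalization.

- **Online recognition** after k via-points uses the first-via-point and
  transition terms up to k.  Dropping later terms is exact
  marginalization, since each transition slice sums to one.
- **Final recognition** pads short sequences with the well to 15 (mirroring
  training) and multiplies the `Sx`, `Sy`, `A` likelihoods into the H-sum.
  The pupil terms are omitted: they are independent of symbol identity,
  so the final posterior conditions on the non-pupil evidence (this is the
  model's stated independence assumption, not an approximation added
  here).
- **Novelty** is the same posterior with `$` participating; the decision is
  the argmax rule applied *before* auxiliary variables, because letter
  sizes vary little across an alphabet and a plausible size would mask an
  implausible shape.  A minimum-P($) threshold is available but off by
  default.  Ties anywhere are broken toward the earlier symbol in domain
  order and logged.
- **Disability** marginalizes L and includes every auxiliary term; the
  pupil terms multiply outside the L-sum (they are L-independent, so this
  is exact).  Posteriors over a session can be averaged for later
  inspection — a measurement, not a diagnosis.
- **Entropy** is −Σ p ln p in nats (0·ln 0 = 0); natural log throughout.

There is no model of via-point insertion or deletion: a spurious early
via-point shifts the pairing of all subsequent ones, which is the main
known failure mode of recognition.

Correctness of the log-space implementation is checked against an
independent brute-force oracle that enumerates the joint distribution of a
miniature model (3 symbols, 2 levels, 4 via-points, ≤ 6-slot domains) in
linear space with explicit sums over every unobserved variable.

## Synthetic data generator

Real eye-written letters exist only as figures in the literature, so the
generator emulates the *statistical structure* the model assumes rather
than anyone's letterforms: ten curated single-stroke control-point shapes
(loops, zigzags, arcs; symbol identity is arbitrary) in a 100×100 px box,
plus seeded procedural strokes (momentum random walks) for larger symbol
sets and allograph variants.  One trace = a cubic spline through the
control points over a 2 s nominal duration at 75 Hz, plus:

- pursuit noise: i.i.d. Gaussian, SD 0.8 px — the tracker-plus-pursuit
  jitter the binomial filter is there to remove;
- a high-frequency oscillation (0.3 px at 18 Hz by default), standing in
  for ocular microtremor; at 75 Hz sampling and after order-20 smoothing
  it is almost entirely suppressed, which is itself a faithful property of
  this processing chain;
- with probability 0.3, a fixation-plus-ballistic-jump prefix (~40 px),
  so boundary trimming has realistic work to do;
- a pupil series: baseline 0.1 + i.i.d. Gaussian, SD 1.0.

The impairment manipulation scales trajectories about their centroid by
4/5 (level 2) or 1/2 (level 3), adds a 6 Hz sinusoid on both axes, shifts
the pupil mean by +0.1 / +0.2 and scales pupil deviations by 0.7 / 0.4.
Tremor amplitudes default to 1.5 px (level 2) and 3 px (level 3): the
published qualitative account has tremor perturb control points only
marginally while mostly raising band energy, and amplitudes much above
~5 px at 6 Hz would instead trip the 0.4 px/sample² saccade trimmer and
destroy the trajectory — so "small" and "medium" are pinned just below
that regime.  Scaling about the centroid is immaterial to the model (only
relative displacements are used).

Every exemplar is seeded from `(master seed, alphabet, symbol, level)`, so
databases are reproducible as a whole and per item.

**What the generator does not emulate:** drift and wandering "burn-in"
pursuit inside letters, blink artifacts, pairing-breaking via-point
insertions mid-trajectory, writer-specific style, or correlated pupil
dynamics (light, attention).  Synthetic shapes are also more mutually
distinguishable than a real cursive alphabet (no o/a/d ambiguities), so
recognition and disability-recovery rates measured here are upper bounds
of a kind: they validate the machinery — that the posterior concentrates
on the generating class, that novelty falls to `$`, that impairment levels
separate — not performance on human data.

## Problem sizes used in the shipped experiments

The test suite and acceptance script run: leave-one-alphabet-out over
35 symbols × 9 alphabets (315 trials, reference 36-symbol domains) for the
trial-count and full-alphabet rate; 10 symbols × 9 alphabets (90 trials)
for class recovery and the entropy trend; 3 trained + 5 unseen shapes
(45 novelty / 27 retention trials) for novelty; and 10 symbols × 9
alphabets × 3 levels (270 assessments) for disability recovery — sizes at
which the full pipeline, including nine full-domain model fits, completes
in seconds.

## Known limitations

- No via-point insertion/deletion model; early spurious via-points are
  unrecoverable (by design, matching the modeled system).
- The smoothing that compensates for small databases makes recognition
  forgiving and therefore blunts novelty detection; the trade-off is
  inherent and application-dependent.
- Word-level segmentation, linguistic priors over `P(L)`, and any clinical
  interpretation of the disability posterior are out of scope.
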