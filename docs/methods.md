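# Methods

## Problem and scope

Radiosurgery of benign, slow-growing tumors such as vestibular schwannoma
(VS) delivers a single high dose (here 12 Gy prescribed at the 80 %
isodose, so the in-target maximum is 15 Gy) to a small target sitting
millimetres from the brainstem and cochlea. Because these patients have
long life expectancies, the *dose bath* — low-to-intermediate dose spread
through normal tissue — and *dose spikes* — fingers of high dose leaking
from the target along beam directions — are first-order concerns, not
afterthoughts. `shellplan` implements, at desk scale on synthetic
phantoms, a two-step automated planning workflow that attacks both:

1. a prioritized multicriteria pre-optimization that, after securing
   target coverage and organ-at-risk (OAR) sparing, minimizes the maximum
   dose on thin shells at 1, 3 and 5 cm from the target;
2. extraction of the achieved shell maxima as *individualized* hard
   constraints and re-planning under them with a simpler, deliverable
   objective stack (coverage to goal, then monitor-unit economy).

A companion experiment replaces the individualized constraints by their
population means ("fixed" constraints) and re-plans, to quantify how much
of the workflow's value lies in the individualization.

## Dose model

Beams are circular cones from a fixed set of non-coplanar nodes on a
spherical cap around the head (179 nodes by default, polar angle up to
120°, quasi-uniform Fibonacci spacing, standing off 700 mm from the head
centre). The per-beam kernel in a water-equivalent body is

    d(v) = U * (SAD / s)^2 * exp(-mu (z(v) - z_ref)) * P(rho; R(s), sigma)

with `U` the output calibration (1 cGy/MU at SAD and reference depth),
`s` the source-to-voxel axis distance, `z` the in-body path length from
entry to the voxel (sampled along the ray at 64 points, nearest-voxel
lookup), `mu` = 0.005 /mm (≈6 MV), `R(s)` the aperture radius projected
to the voxel plane (apertures defined at SAD = 800 mm), and `P` a flat
core with an error-function penumbra of width sigma = 2 mm. Dose is
linear in the beam weights (MU): `d = A w`, with `A` assembled sparsely
over all candidate beams (entries below 1e-6 of the column maximum are
dropped; the support is cut at 5 penumbra widths outside the field edge).
Candidate beams are the product of nodes, two Iris-style apertures
bracketing 1.1x the target's equivalent diameter (from the discrete set
10–40 mm), and aim points (target centroid plus one seeded random
interior point). These kernel constants are package defaults chosen for
plausibility, not vendor data; all are configurable.

## Lexicographic optimization

A wish-list holds hard constraints (always enforced) and objectives with
strictly ordered priorities. Phase k minimizes (or maximizes) objective k
subject to the hard constraints plus, for every j < k, a constraint
freezing objective j at its achieved value relaxed by the slip factor
delta = 1.03 (an objective with a goal and the *sufficient* flag is
frozen at its goal instead once the goal is met). Every phase is a linear
program over nonnegative beam weights solved with HiGHS:

* maximum doses enter as per-voxel rows;
* percentile metrics use their tail-mean (CVaR) linearization: the mean
  of the hottest (coldest) ceil(alpha*n) voxels is representable with one
  free threshold variable and n nonnegative auxiliaries, keeping the
  program linear. Exact order-statistic values (D2%, V12Gy) are always
  recomputed afterwards by sorting.

The coverage surrogate is the cold-tail mean at alpha = 2 %: if the mean
of the coldest ceil(0.02 n) target voxels is at least 12 Gy then the
ceil(0.02 n)-th coldest voxel is too, so at most ceil(0.02 n) - 1 voxels
are below 12 Gy and V12Gy strictly exceeds 98 %. This soundness argument
is asserted in the test suite on random dose vectors.

The default VS wish-list: hard target Dmax 15 Gy; hard OAR Dmax bounds
(brainstem 12, cochlea 12, nerves 15 Gy — package defaults consistent
with single-fraction practice, not a published protocol); priority 1
coverage (sufficient at 12 Gy); priorities 2–4 minimize shell Dmax at 1,
3, 5 cm (closest first — the three shells are interpreted as three
separate priorities, an explicit design choice); lowest priority
minimizes total MU, which also serves as the tie-break that makes the
returned plan unique in practice.

### Lazy row generation

Maximum-dose blocks over more than 256 voxels (the evaluation shells) are
handled by constraint generation: each phase is solved with a growing
subset of voxel rows, rows violating their bound (or exceeding the
current Dmax objective level) are appended (worst 256 per round), and the
phase is re-solved until no violations remain; the subsets persist across
phases and across the re-plans of the same patient. The converged
solution equals the full-row optimum (verified in tests); violations that
persist on rows already present are solver-tolerance noise (1e-6 Gy) and
terminate the loop. Interior-point is used per phase with a simplex
fallback.

## Constraint transfer and the fixed-constraint arm

Shell maxima of the step-one plan are rounded to integer cGy. When
re-imposed as constraints they carry half a rounding unit (0.5 cGy) of
slack so the extracted set is always feasible for its own patient — the
step-one plan is the witness. The step-two objective stack (coverage to
goal, then MU) emulates a clinical optimizer fed a planning template; the
vendor's actual objective internals are not public, so this stack is an
explicit emulation, exposed in configuration.

The fixed-constraint arm averages the 20 individualized sets per distance
(arithmetic mean, rounded to integer cGy) and re-plans every patient
under the common set. Plans are rescaled to exactly 98 % target coverage
before comparison when the hard maximum-dose bounds allow the required
factor; a plan that cannot reach 98 % within those bounds stays unscaled
and is flagged unacceptable. Rescaling before flagging is an
interpretation choice; the alternative (flag first) only relabels plans
that fail either way.

The *baseline* planner — coverage to goal, then MU, with no shell terms —
represents planning that optimizes only what the clinical protocol
strictly requires; it is the package's stand-in for conventional manual
planning and is intentionally simpler than any commercial system.

## Evaluation conventions

* V_D uses the closed threshold (dose >= D); D2% is the ceil(0.02 n)-th
  hottest voxel, no interpolation. Both are exact functions of the voxel
  dose multiset, hence permutation invariant.
* Rescaling sets the ceil(0.98 n)-th hottest target voxel exactly to
  12 Gy; the factor is nudged upward by at most 4 ulps so the order
  statistic lands at or above the prescription after the floating-point
  multiply, making the post-rescale coverage check exact rather than
  tolerance-based.
* Two conformity variants are computed (prescription-isodose-volume /
  target-volume ratio, and the inverse-overlap form PIV*PTV/overlap^2);
  neither is asserted against external values since the defining variant
  used in clinical reports is often unstated. The PIV is taken within
  the body; an empty PIV yields an undefined (null) CI.
* Paired comparisons use the two-sided Wilcoxon signed-rank test: exact
  for n <= 20 via the full 2^n null distribution computed by dynamic
  programming over doubled mid-ranks (ties handled exactly, zero
  differences dropped), normal approximation with tie and continuity
  correction above. Sample (n-1) standard deviations everywhere; the
  embedded clinical table reproduces its published summary row only
  under the n-1 convention, which fixed the choice. No multiplicity
  correction is applied; per-metric p values are reported raw.
* Percent differences are (reference - comparison)/reference * 100,
  positive when the comparison is smaller; per-patient values are
  averaged, which differs from the percent difference of the means.

## Synthetic phantoms

A phantom is an ellipsoidal head (semiaxes 80/95/85 mm), a vertical
brainstem cylinder (radius 8 mm), a randomly oriented ellipsoidal target
at a lateral posterior-fossa position, a cochlea sphere (radius 2.5 mm,
with a one-voxel fallback on grids coarser than the sphere), and two
nerve tubes (radius 1.5 mm) touching the target surface. The target's
continuous radius is calibrated so the voxelized volume lands within 10 %
of the request (a request needing fewer than 8 voxels is rejected,
naming the spacing that would work), and the target is shifted by whole
voxels until the distance-transform gap to the brainstem matches the
request to grid resolution. Cohorts draw target volumes log-uniformly on
1.0–7.3 cc — the published clinical size range — and gaps uniformly on
0–3 mm; per-phantom seeds derive deterministically from the cohort seed.

What the generator does *not* emulate: real neuroanatomy, CT density
heterogeneity, delineation uncertainty, and the full clinical OAR list
(optic apparatus, pituitary and eyes receive near-zero dose in this
geometry and are omitted from the generated set). Passing tests therefore
demonstrate that the workflow's mechanics and its qualitative findings
(shell-dose reduction, the cost of fixed constraints) hold under
controlled geometry — not that clinical dose levels are reproduced.

## Problem sizes and defaults

The cohort study runs 20 phantoms on a 4 mm isotropic grid (~42k body
voxels) with 179 nodes x 2 apertures x 2 aim points = 716 candidate
beams per patient; shells are one-voxel-thick bands (thickness
max(3 mm, voxel)). These sizes keep a full cohort run in the tens of
minutes on one core while preserving every structural element of the
workflow. Finer grids (2 mm) and more candidates are configuration
changes, not code changes.

## Known limitations

* The dose kernel is analytic and homogeneous; no scatter, no
  heterogeneity, no vendor beam data — absolute dose levels are
  surrogate-quality only.
* Coverage behaves cliff-like under tightened shell constraints at 4 mm
  resolution: a few cGy of extra tightness can drop coverage far below
  98 % rather than marginally, which makes the fixed-constraint failure
  counts grid-dependent.
* The node path, aperture discretization and delivery-time coefficients
  are plausible defaults, not vendor values; delivery time is reported
  but never asserted against clinical durations.
* Beam/node counts of the solved plans come from LP support sizes (and
  optional pruning), not from a vendor sequencer.
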