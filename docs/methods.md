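# Methods

## Data model and RSML

An RSA is a forest of polyline organs. Each node carries a 3D position
and a diameter; each root carries an order (0 = taproot, 1 = lateral,
…), an optional parent and an optional arc-length attachment position
on that parent. The internal canonical unit is cm. RSML metadata
(`unit`, `resolution`) is honoured on read — coordinates are divided by
the resolution and converted from the declared unit — and written
explicitly on write. Both RSML diameter conventions are read: a
per-node `diameter` sample function, or a root-level diameter
property/attribute; a missing diameter defaults to 0.1 cm so tracings
recorded without diameters remain scoreable. Root order is inferred
from nesting depth; an explicit `order` property that contradicts the
depth triggers a warning and the depth wins. The z axis points down
into the soil column; `read_rsml(..., flip_z=True)` accommodates data
recorded with z up. Writing emits per-node diameter functions and
stores the attachment position as an `insertion_position` property so
round trips are lossless.

## Segment distance and matching

The minimal distance between two closed segments is solved in closed
form (the clamped-quadratic closest-approach construction), vectorised
over all ground-truth × traced segment pairs. The parameterisation is
over the *closed* segments, i.e. parameters are clamped to [0, 1]:
an open-interval reading that excludes the endpoints differs only on a
measure-zero set and would extrapolate beyond the segment when applied
literally. A dense grid search over the two segment parameters is kept
in the test suite as an independent oracle (step 1e-3, agreement
within 2e-3 on 1000 random pairs).

Segment correspondence is a two-phase nearest-neighbour rule under the
threshold: phase 1 assigns every traced segment to its nearest
ground-truth segment within the threshold (1-to-n sets per ground-truth
segment); phase 2 offers the remaining traced segments to the
ground-truth segments holding exactly one correspondence, again within
the threshold (a relaxation factor is exposed because the exact
phase-2 tolerance is a free choice; default 1.0). Ties break on the
lowest row index, making the procedure deterministic. Segment
correspondences are diagnostic; the scores are built on root-level
matching.

The cumulative root distance d(m, n) is the length-weighted mean over
the ground-truth root's segments of each segment's minimal distance to
the traced root's segments. A weighted mean — rather than a sum — keeps
d(m, n) on the same scale as segment distances, so a single threshold
(15 voxels = 0.75 cm at the default grid) is meaningful for roots of
any length. Unweighted-mean and sum modes are available for
comparison.

Root matching runs in two stages. Stage 1 solves the rectangular
linear assignment problem minimising total cumulative distance
(scipy's Hungarian solver; "lowest among all other possible
assignments" is read as a global optimum, and a greedy
ascending-distance mode exists for comparison), then keeps pairs with
d(m, n) ≤ threshold. Stage 2 attaches each remaining traced root to
the Stage-1-matched ground-truth root of least cumulative distance if
within the threshold — this is what lets an organ traced in several
fragments count as matched (1-to-n). Root matching is not restricted
to pairs sharing segment correspondences. Leftover ground-truth roots
are false negatives, leftover traced roots false positives; the two
partitions are exact by construction.

## Scores

Whole-root lengths are summed over the match index sets. Recall and
precision carry penalties for under- and over-traced matched length:

    R = L_GC / (L_GC + L_FN + max(0, L_GC − L_TC))
    P = L_GC / (L_GC + L_FP + max(0, L_TC − L_GC))

The penalty sign deserves a note: a min(0, ·) form of these penalties
circulates, but it evaluates to exactly zero in the very situations a
penalty is meant to address (matched tracing shorter, respectively
longer, than its ground truth) and can push scores above 1 otherwise.
The default `penalty_mode="max"` realises the intended penalties and
preserves the [0, 1] codomain; `penalty_mode="literal-min"` retains
the other sign convention for forensic comparison. Zero denominators
(e.g. an empty tracing) score 0. F1 is the harmonic mean, 0 when both
components vanish.

## Traits

* **Total root length** Σlᵢ and **average root length** (total over
  root count) are direct polyline sums.
* **Lateral count** includes roots of order ≥ 1 at least
  `min_length` cm long (default 3 cm; short stubs are typically
  tracing artifacts, not organs — a 4 cm variant circulates and the
  threshold is a plain parameter).
* **Inter-lateral distance** is the mean arc-length spacing between
  consecutive lateral attachments along the taproot — measured *along*
  the organ, not as chord length between branch points. When no
  explicit attachment is recorded (human tracings attach laterals
  visually), the lateral's first node is projected onto the taproot
  polyline. Requires exactly one taproot and ≥ 2 laterals; otherwise
  the trait is undefined and reported as such.
* **Relative error** |traced − gt| / gt compares any trait against its
  ground-truth value.

All traits are invariant under rigid transforms of the system.

## Virtual MRI phantoms

**Voxelization.** Each segment is a capsule: a tube whose radius
interpolates linearly between the node radii, with hemispherical caps
arising naturally from parameter clamping. Per voxel, the occupied
volume fraction is estimated by testing a regular `supersampling³`
sub-grid of points (default 4³ = 64) against the union of capsules;
overlaps count once (the union is formed over unique sub-grid points,
not by summing per-capsule contributions). The estimator is
deterministic — no Monte Carlo — so outputs are bit-reproducible and
mass-conservation is testable: an interior capsule's total signal mass
matches its analytic volume πr²l + (4/3)πr³ within 5% at
supersampling 4. The default grid is isotropic 0.05 cm voxels, chosen
so the conventional 15-voxel matching threshold equals 0.75 cm.

**Water noise.** Inside a vertical soil cylinder (default diameter
1.5 cm, centred on the grid unless placed explicitly), signed unit
impulses are seeded at `impulse_density` (default 0.02 of cylinder
voxels) with random signs. The whole volume then passes through the
Weierstrass transform — convolution with a normalized isotropic
Gaussian (default bandwidth 0.1 cm, i.e. 2 voxels; zero-padded
boundaries so interior-supported mass is preserved; σ = 0 is the
identity) — turning the impulses into smooth bright/dark blobs.

**SNR contract.** No standard SNR definition exists for this kind of
phantom, so the package fixes one and uses it on both sides: SNR =
(peak clean signal within the cylinder dilated by 3 voxels) / (RMS of
noisy − clean within the cylinder). The impulse amplitude is
calibrated against the post-smoothing RMS of the realized impulse
field, region-wide (a per-blob variant of "local" scaling would also
be defensible; region-wide was chosen as the simpler, testable
contract). Consequently measuring the smoothed phantom against the
smoothed clean volume returns the configured SNR (default 4.3)
essentially exactly, per seed; the across-seed mean is the reported
quantity. Volumes read/write as NIfTI (voxel size and origin in the
affine) or raw float32 with a JSON sidecar.

## Synthetic ground truth and tracing errors

The generator emulates the architecture of a young faba bean in an MRI
soil column: one taproot grown downward as a gravitropism-biased
random walk (exact arc length; default 15 cm, node spacing 0.25 cm,
tortuosity 0.1) with 25 first-order laterals attached at regular
arc-length spacing (default 0.5 cm starting 1 cm below the collar),
branching at 70° ± 10° with uniform azimuth, lengths drawn from
N(5, 1²) cm truncated below at 3 cm so every lateral clears the
default count filter, taproot diameter 0.3 cm and lateral diameter
0.1 cm with per-lateral overrides (e.g. one very thin, hard-to-see
root). These defaults are illustrative of the study system, not a
replication of any specific simulation; every value is a parameter.
The generator is parameter-transparent: at zero attachment jitter the
trait pipeline returns the configured spacing and count exactly, which
is what makes it usable as an oracle. It does not model growth
dynamics, diameter taper, higher-order branching, root water uptake or
soil mechanics — so passing tests demonstrate correctness of the
evaluation machinery on idealised architectures, not robustness to
every real tracing pathology.

The perturbation model composes observed human-tracing artifact
classes in a fixed order (so seeds are reproducible): (1) root
dropping with its subtree (taproots are never dropped — annotators
reliably find the taproot), (2) i.i.d. Gaussian node jitter, which
also inflates polyline length and thereby exercises the over-trace
penalty, (3) signed tip over-/under-tracing by a fraction of each
root's length, (4) spurious short branches at random arc positions
(misclicks along an organ), (5) free-floating false-positive roots
scattered around a configurable centre (misclicks into the water
volume). All-zero parameters are the bit-exact identity.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full default system
(26 roots, ≈ 560 segments, grids around 250 × 210 × 340 voxels);
distance matrices are computed vectorised in one shot. Monte-Carlo
checks use 20 seeds per condition and the brute-force matching oracle
runs on instances up to 5 × 5 roots, where exhaustive enumeration is
cheap. Ties in nearest-segment and nearest-root selection break on the
lowest index. Zero-length segments are rejected at validation;
the distance kernel additionally guards degenerate input behind an
explicit point-to-segment fallback flag. Score components are defined
as 0 on zero denominators. Voxelization clips (with a warning) roots
extending beyond the requested grid.

## Known limitations

* The two-phase segment-correspondence rule is one concrete reading of
  an under-determined procedure; direction of phase 1 and the phase-2
  tolerance are configurable rather than asserted as canonical.
* The cumulative root distance's length weighting is a design choice;
  sum and unweighted-mean modes exist but change the meaning of the
  threshold.
* SNR is meaningful only under this package's definition; comparisons
  with scanner SNR figures are not.
* The generator produces first-order laterals only; higher-order
  architectures exercise the model and matcher through hand-built
  fixtures, not the generator.
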