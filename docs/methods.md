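# Methods

## Scope and model

`lyothick` quantifies the encapsulating-wall thickness of freeze-dried
porous matrices from segmented 3D images and relates it to the storage
stability of embedded bacteria. The two measurements are deliberately
simple and transparent: local thickness by maximal inscribed spheres, and
half-lives by two-point exponential decay. Everything else in the package
exists to make those two measurements testable end to end.

## Local thickness by maximal inscribed digital balls

Local thickness at a point of the material phase is the diameter of the
largest sphere fully inscribed in the material that contains the point
(Hildebrand & Rüegsegger's definition, the one behind the "blobs" of
porous-media local-thickness tools).

On a voxel grid the package realizes this with *digital balls*: sets of
voxels whose centres lie within a Euclidean radius of a ball centre. Two
choices matter and are fixed as follows.

**Centre grid.** Ball centres live on the half-voxel-refined grid — voxel
centres plus face, edge and body midpoints. A symmetric ball centred on a
voxel centre always spans an odd number of voxels, so walls an even number
of voxels thick could never carry their true thickness; centres between
voxel planes make both parities exactly representable. In doubled integer
coordinates (voxel centres at even triples, ball centres at any integer
triple):

* `e(c)` = Euclidean distance from centre `c` to the nearest pore voxel
  centre. `e(c)²` is an integer, computed exactly.
* The maximal ball at `c` is every voxel strictly closer than `e(c)`; by
  construction it is contained in the material.
* Its **diameter** (in voxels) is the smallest axis span of the ball: along
  each axis, the count of voxel positions reachable given that voxel
  offsets from the centre must match the centre's coordinate parity on
  *every* axis (so the reach along one axis is limited by the minimal
  parity offsets of the other two). This reproduces closed-form cases
  exactly: an n-voxel slab maps to n for every n, a digital ball of 9-voxel
  extent maps to 9, an isolated voxel to 1.

The per-voxel thickness is the maximum diameter over all maximal balls
covering the voxel, times the voxel size. The implementation computes
`e²` with a Euclidean distance transform on the refined grid and paints
balls per parity class with vectorized shifts; an exhaustive oracle
(`lyothick.reference`) enumerates every centre and tests containment and
coverage by brute force, and the test suite requires voxel-for-voxel
agreement on random volumes. Cost grows with the cube of the wall radius
in voxels; the algorithm is intended for thin-walled structures (walls up
to ~10 voxels) at moderate volume sizes, which is the regime freeze-dried
matrices occupy at the voxel sizes where their walls are resolvable.

**Boundary rule.** Everything outside the imaged volume counts as pore by
default: inscribed spheres must fit inside the imaged material, the
conservative choice for cropped wedge scans. `boundary="ignore"` treats
the outside as material instead, for volumes known to continue beyond the
field of view.

## Thickness distribution, d_vol and mode

Thickness values are binned into half-open classes `[j·w, (j+1)·w)` (last
bin closed) with default width w = 0.5 µm and origin 0, matching the
granularity at which modes of such distributions are usually reported.
Class representative `d_j` is the bin midpoint.

Two volume weightings are implemented because the transformation from a
count distribution to a volume-weighted one is ambiguous in common
practice:

* `voxel_volume` (default): every material voxel contributes its volume to
  its thickness class; `ΣV_j` then equals the total material volume
  exactly, a conservation property the tests assert.
* `blob_volume`: each maximal inscribed ball contributes an ideal sphere
  volume `(π/6)d_j³`. Maximal balls are counted by a deterministic greedy
  pass (descending diameter; a ball counts when it covers a voxel not yet
  covered at its diameter or larger). This pass visits balls one at a
  time and is intended for modest volumes.

The volume-weighted mean is `d_vol = Σ d_j V_j / Σ V_j`; the mode is the
class with maximal `V_j`, ties broken toward the larger diameter so that a
flat-topped distribution reports its upper shoulder.

**Resolution floor.** No positive thickness below one voxel is ever
reported. A sample whose mode class reaches down to the voxel size is
flagged *sub-resolution* rather than quantified: structures at or below
the voxel size alias into that class and carry no stable signal, as the
acceptance checks demonstrate with 0.5 µm walls imaged at 0.64 µm voxels.

## Segmentation

The filter is a cubic median with reflective boundaries. For an even
window (the conventional 4×4×4 default) there is no central voxel; the
neighbourhood spans offsets `{-w/2, …, w/2−1}` per axis, the standard
n-dimensional filter convention, and this origin choice is documented
because different packages disagree. Reflection padding avoids darkened
rims that would bias thin-wall segmentation. Thresholding defaults to
Otsu — deterministic and parameter-free — with a manual override.
Anisotropic voxels are rejected rather than resampled, since resampling
would silently change thickness values. In the phantom-recovery tests the
median window is 3, scaled to the thinnest feature present (a 4-wide
window straddles a 2-voxel wall and can erase it).

## Viability decay

The decay constant λ (days) over a window is computed from the window's
endpoint counts only; intermediate points never affect it, which keeps
windowed estimates (0–28 d, 28–56 d — "month" windows bound to sampling
days, not calendar months) strictly comparable. `t_half = ln(2)·λ`. The
relation is sometimes printed as `t_half = ln(2)/λ` with λ nevertheless
defined as a time constant; that form is dimensionally inconsistent and
the product form is used throughout. Equal endpoint counts yield an
infinite half-life flagged `no_decay`; growth yields a negative value
flagged `growth`; counts at or below a configurable limit of detection are
rejected, never imputed. A log-linear least-squares fit over all points in
a window is available as a labelled alternative (`loglinear_fit`), never
the default.

## Synthetic phantoms and simulated viability

The generators define the study conditions for every test:

* **Parallel plates**: alternating slabs and gaps along z; exact material
  fraction and wall thickness. µm→voxel conversion rounds half away from
  zero. Default test walls are 2–7 voxels at 0.64 µm voxels (≈1.3–4.5 µm),
  the range where real freeze-dried walls sit after annealing.
* **Radial lamellae**: planar half-plane sheets through the central axis,
  clipped to a cylinder — a 2.5D stand-in for sheets oriented toward a
  pellet centre, chosen for its analytic area ratio. Sheets merge near the
  axis (as in real pellets); a warning is emitted when the rim gap is
  smaller than the wall.
* **Spherical pores**: random single-diameter pores carved until a target
  porosity is reached, emulating a fine ~5 µm pore structure; achieved
  porosity is recorded.
* **Rendering**: two grey levels, Gaussian partial-volume blur, additive
  Gaussian noise, seeded. Default recovery tests use 10 % contrast noise
  and 0.5 voxel blur.
* **Viability**: `C(t) = c0·(1−drop)·2^(−t/t_half)` for t>0 with `C(0) =
  c0` exactly; the single multiplicative initial drop mimics the rapid
  early loss seen on top of first-order storage decay without inventing
  kinetics. Count noise is multiplicative log-normal with unit median
  (plate counts are positive and right-skewed; the median curve stays on
  the noiseless decay). Default half-lives in synthetic studies span
  ~4–20 days, the range typical of accelerated storage panels.

What the phantoms do *not* emulate: X-ray physics (beam hardening, rings),
curved or branching walls, wall-thickness gradients, partial-volume
anisotropy, or correlated plating errors. Passing tests therefore
demonstrate correctness of the measurement chain on known geometry, not
fidelity of any particular scan.

## Association stage

Pearson and Spearman coefficients plus a least-squares line are reported
per storage group; neither statistic is privileged. Groups need at least
three numeric samples and nonzero variance, otherwise the result is an
explicit NaN with an `undefined` flag. Sub-resolution samples are excluded
from the numeric association and counted separately. No p-values are
emitted by default: group sizes in studies of this kind are a handful of
samples, so inference would be decorative.

## Numerical choices and degenerate inputs

* Distance transforms: `scipy.ndimage.distance_transform_edt`; squared
  distances are exact integers (verified against all-pairs search).
* All generators and the pipeline are bit-reproducible given their seeds;
  rerunning a config yields byte-identical summaries.
* Constant volumes are rejected by Otsu; all-pore masks are rejected by
  the distance and thickness maps; empty thickness maps are rejected by
  the distribution; reversed or missing half-life windows are errors that
  name the offending timepoint.
* Conservation `ΣV_j = material volume` is exact in voxel counts; the
  floating-point volume sum agrees to better than 1e-12 relative.

## Known limitations

* Local thickness cost scales with wall radius cubed; very open structures
  (inscribed spheres of tens of voxels) are out of the intended regime.
* The blob-counting rule for `blob_volume` weighting is one reasonable
  definition of "number of blobs", not the only one; the default voxel
  weighting does not depend on it.
* The sub-resolution flag is a heuristic on the mode class; heterogeneous
  samples mixing resolved and unresolved structure can evade it.
* Only isotropic voxels are supported.
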