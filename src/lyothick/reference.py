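"""Exhaustive reference implementations used to validate the fast algorithms.

These deliberately naive routines enumerate every candidate explicitly --
every pore voxel for distance maps, every (centre, radius) digital ball for
local thickness -- and serve as independent oracles in the test suite and
the acceptance checks.  They share only the *definition* of the digital
ball space with :mod:`lyothick.thickness`, not its algorithm: distances are
computed by all-pairs search rather than a distance transform, and balls
are tested for containment and coverage one centre chunk at a time.

Complexity is O(centres x voxels) per volume; intended for volumes of a few
thousand voxels.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["exhaustive_distance_map", "exhaustive_local_thickness"]


def _pore_positions_doubled(mask: np.ndarray) -> np.ndarray:
    """Pore voxel centres, in doubled coordinates, including the virtual
    one-voxel outside layer (outside counts as pore)."""
    padded = np.pad(mask, 1, constant_values=False)
    coords = np.argwhere(~padded)  # padded index
    return (2 * (coords - 1)).astype(np.float64)  # doubled position of voxel (index - 1)


def _pairwise_sq_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between small-integer points.

    All intermediate values are exactly representable in float64, so the
    result is an exact integer-valued float array.
    """
    return (a * a).sum(axis=1)[:, None] + (b * b).sum(axis=1)[None, :] - 2.0 * (a @ b.T)


def exhaustive_distance_map(mask: np.ndarray) -> np.ndarray:
    """All-pairs nearest-pore distance per material voxel, in voxel units."""
    pores = _pore_positions_doubled(mask)
    out = np.zeros(mask.shape, dtype=float)
    for idx in np.argwhere(mask):
        d2 = ((pores - 2.0 * idx) ** 2).sum(axis=1)
        out[tuple(idx)] = math.sqrt(d2.min()) / 2.0
    return out


def _ball_diameter(x: int, parity: tuple[int, int, int]) -> int:
    """Diameter (voxel count spanned) of the maximal digital ball with
    squared open radius ``x`` at a centre of the given coordinate parity.

    Voxel offsets from the centre carry the centre parity on every axis, so
    the reach along one axis is limited by the minimal parity offsets of
    the other two.
    """
    if x < 0:
        return 0
    par_sum = sum(parity)
    spans = []
    for p in parity:
        xa = x - (par_sum - p)
        if xa < p * p:
            return 0
        t = math.isqrt(xa)
        if t % 2 != p:
            t -= 1
        if t < p:
            return 0
        spans.append(t + 1)
    return min(spans)


def exhaustive_local_thickness(mask: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Brute-force local thickness in voxel units.

    Enumerates every ball centre on the half-voxel grid, finds its squared
    distance to the nearest pore voxel by exhaustive search, and assigns the
    resulting maximal-ball diameter to every voxel the ball covers, keeping
    the voxel-wise maximum.
    """
    nz, ny, nx = mask.shape
    pores = _pore_positions_doubled(mask)
    vox_pos = 2.0 * np.argwhere(np.ones(mask.shape, dtype=bool))  # all voxels, C order
    # all half-grid centres from just outside the first voxel to just outside the last
    axes = [np.arange(-1, 2 * (n - 1) + 2) for n in (nz, ny, nx)]
    centres = (
        np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3).astype(np.float64)
    )

    flat = np.zeros(mask.size, dtype=np.int32)
    for lo in range(0, len(centres), chunk):
        cs = centres[lo : lo + chunk]
        d2_pore = _pairwise_sq_dist(cs, pores).min(axis=1)
        x = d2_pore - 1  # squared open radius
        diam = np.array(
            [
                _ball_diameter(int(xi), (int(cc[0]) % 2, int(cc[1]) % 2, int(cc[2]) % 2))
                for xi, cc in zip(x, cs)
            ],
            dtype=np.int32,
        )
        keep = diam > 0
        if not keep.any():
            continue
        cs, x, diam = cs[keep], x[keep], diam[keep]
        covered = _pairwise_sq_dist(cs, vox_pos) <= x[:, None]
        contrib = np.where(covered, diam[:, None], 0).max(axis=0)
        np.maximum(flat, contrib, out=flat)
    return flat.reshape(mask.shape)
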