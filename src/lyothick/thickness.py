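"""Local thickness maps and volume-weighted thickness distributions.

Local thickness at a material point is the diameter of the largest sphere
fully inscribed in the material phase that contains the point
(Hildebrand/Ruegsegger).  On a voxel grid this package realizes the sphere
as a *digital ball*: a set of voxels whose centres lie within a Euclidean
radius of a ball centre.  Ball centres live on the half-voxel-refined grid
(voxel centres plus face, edge and body midpoints), which is what lets a
wall an even number of voxels thick carry its exact thickness -- a
voxel-centred symmetric ball can only span an odd voxel count.

Working in doubled integer coordinates (voxel centres at even triples, ball
centres at any integer triple):

* ``e(c)`` is the Euclidean distance from centre ``c`` to the nearest pore
  voxel centre, with everything outside the imaged volume counted as pore
  (spheres must fit inside the imaged material; configurable).
* The maximal digital ball at ``c`` is every voxel strictly closer than
  ``e(c)``; it is automatically contained in the material.
* Its diameter, in voxels, is the count of voxel positions it spans along
  an axis, which depends only on ``e(c)^2`` (an integer) and the parity of
  the centre coordinates; for mixed-parity centres the smallest axis count
  is taken.

The per-voxel thickness is the maximum diameter over all maximal balls
covering the voxel, converted to micrometres.  The thickness histogram is
volume-weighted: by default each material voxel contributes its volume to
its thickness class (``voxel_volume``); alternatively each maximal ball
("blob") contributes an ideal sphere volume (``blob_volume``).  The
volume-weighted mean is

    d_vol = sum_j d_j V_j / sum_j V_j

over thickness classes j with representative diameter d_j and class volume
V_j, and the mode is the class with maximal V_j (ties toward the larger
diameter).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import BinaryVolume

__all__ = [
    "ThicknessMap",
    "ThicknessDistribution",
    "euclidean_distance_map",
    "local_thickness_map",
    "thickness_distribution",
    "volume_weighted_mean",
    "distribution_mode",
    "is_sub_resolution",
]


@dataclass
class ThicknessMap:
    """Per-voxel local thickness in micrometres (0 on pore voxels)."""

    values: np.ndarray
    voxel_um: float
    method_note: str = ""
    #: Maximal-ball counts keyed by diameter in voxels (populated on request).
    blob_counts_vox: dict[int, int] | None = None

    @property
    def values_voxels(self) -> np.ndarray:
        return self.values / self.voxel_um

    @property
    def material_mask(self) -> np.ndarray:
        return self.values > 0


@dataclass
class ThicknessDistribution:
    """Binned thickness classes with number counts and volume weights.

    Bins are half-open ``[edge_j, edge_{j+1})`` with the last bin closed;
    ``d_j`` is the bin midpoint.  Under ``voxel_volume`` weighting the total
    volume equals material_voxel_count * voxel_um^3 exactly.
    """

    bin_edges: np.ndarray
    number_count: np.ndarray
    class_volume: np.ndarray
    voxel_um: float
    weighting_mode: str = "voxel_volume"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.number_count = np.asarray(self.number_count)
        self.class_volume = np.asarray(self.class_volume, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.bin_edges) != len(self.class_volume) + 1:
            raise ValueError("need len(bin_edges) == number of classes + 1")
        if np.any(self.class_volume < 0) or np.any(self.number_count < 0):
            raise ValueError("counts and volumes must be nonnegative")

    @property
    def class_diameter(self) -> np.ndarray:
        """Bin-representative diameters d_j (midpoints), in um."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_volume(self) -> float:
        return float(self.class_volume.sum())

    @property
    def d_vol(self) -> float:
        return volume_weighted_mean(self)

    @property
    def mode_um(self) -> float:
        return distribution_mode(self)


def euclidean_distance_map(mask: BinaryVolume, boundary: str = "pore") -> np.ndarray:
    """Distance (um) from each material voxel centre to the nearest pore voxel centre.

    Pore voxels map to 0.  With ``boundary='pore'`` (default) the first
    virtual voxel layer outside the volume counts as pore, so distances near
    the volume faces are bounded; ``'ignore'`` treats the outside as
    material.
    """
    if not mask.mask.any():
        raise ValueError("mask contains no material voxels")
    if boundary == "pore":
        padded = np.pad(mask.mask, 1, constant_values=False)
        dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    elif boundary == "ignore":
        dist = ndimage.distance_transform_edt(mask.mask)
    else:
        raise ValueError(f"boundary must be 'pore' or 'ignore', got {boundary!r}")
    return dist * mask.voxel_um


def _isqrt_array(x: np.ndarray) -> np.ndarray:
    """Elementwise floor(sqrt(x)) for nonnegative integer arrays, exactly."""
    s = np.floor(np.sqrt(x.astype(np.float64))).astype(np.int64)
    s += (s + 1) ** 2 <= x
    s -= s**2 > x
    return s


def _axis_span(x: np.ndarray, axis_parity: int, other_parity_sum: int) -> np.ndarray:
    """Voxel count a maximal ball spans along one axis.

    ``x`` is the squared open radius (e^2 - 1) in doubled units.  Voxel
    offsets from the centre must match the centre parity on *every* axis,
    so the reach along one axis is limited by the minimal parity offsets of
    the other two: count = (largest t >= 0 with t = axis_parity mod 2 and
    t^2 <= x - other_parity_sum) + 1, or 0 when no such t exists.
    """
    xa = x - other_parity_sum
    t = _isqrt_array(np.maximum(xa, 0))
    if axis_parity == 0:
        t = t - (t % 2)
        return np.where(xa >= 0, t + 1, 0).astype(np.int32)
    t = t - 1 + (t % 2)
    return np.where((xa >= 1) & (t >= 1), t + 1, 0).astype(np.int32)


def _refined_pore_distance_sq(mask: np.ndarray, boundary: str) -> np.ndarray:
    """Squared distance (doubled units) from every half-grid point to the nearest pore voxel.

    The refined grid covers doubled positions -2..2(n-1)+2 per axis; pore
    voxel centres (and, for boundary='pore', the virtual outside layer) sit
    on the even sub-lattice.
    """
    pad_value = boundary != "pore"
    padded = np.pad(mask, 1, constant_values=pad_value)
    shape = tuple(2 * s + 3 for s in mask.shape)
    grid = np.ones(shape, dtype=bool)
    grid[0::2, 0::2, 0::2] = padded
    dist = ndimage.distance_transform_edt(grid)
    return np.round(dist * dist).astype(np.int64)


def local_thickness_map(
    mask: BinaryVolume, boundary: str = "pore", count_blobs: bool = False
) -> ThicknessMap:
    """Local thickness: largest inscribed digital ball containing each voxel.

    Exact with respect to the digital-ball definition above (verified
    against an exhaustive enumeration oracle).  ``count_blobs=True``
    additionally counts maximal inscribed balls per diameter class with a
    deterministic greedy pass (descending diameter; a ball counts when it
    covers a voxel not yet covered at its diameter or larger) -- needed for
    ``blob_volume``-weighted distributions.  The greedy pass visits balls
    one by one and is intended for modest volume sizes.
    """
    if boundary not in ("pore", "ignore"):
        raise ValueError(f"boundary must be 'pore' or 'ignore', got {boundary!r}")
    m = mask.mask
    if not m.any():
        raise ValueError("mask contains no material voxels")
    nz, ny, nx = m.shape
    e_sq = _refined_pore_distance_sq(m, boundary)
    tmap = np.zeros(m.shape, dtype=np.int32)
    blob_records: list[tuple[int, int, tuple[np.ndarray, ...]]] = []

    for parity in itertools.product((0, 1), repeat=3):
        sub = e_sq[parity[0]::2, parity[1]::2, parity[2]::2]
        x = sub - 1  # squared open radius per centre; -1 where centre is a pore position
        # ball diameter = smallest axis span
        par_sum = sum(parity)
        counts = [_axis_span(x, parity[i], par_sum - parity[i]) for i in range(3)]
        diam = np.minimum(np.minimum(counts[0], counts[1]), counts[2])
        active = diam > 0
        if not active.any():
            continue
        max_x = int(x[active].max())
        if max_x < 0:
            continue
        radius = int(np.floor(np.sqrt(max_x)))
        n_axes = (nz, ny, nx)
        sub_shape = sub.shape
        # offsets of the centre's parity within the open radius
        deltas = []
        for dz in range(-radius, radius + 1):
            if (dz - parity[0]) % 2:
                continue
            for dy in range(-radius, radius + 1):
                if (dy - parity[1]) % 2:
                    continue
                rem = max_x - dz * dz - dy * dy
                if rem < 0:
                    continue
                for dx in range(-radius, radius + 1):
                    if (dx - parity[2]) % 2:
                        continue
                    r2 = dz * dz + dy * dy + dx * dx
                    if r2 <= max_x:
                        deltas.append((dz, dy, dx, r2))
        for dz, dy, dx, r2 in deltas:
            # voxel index p_i = s_i + (parity_i + delta_i)/2 - 1
            off = [(parity[0] + dz) // 2 - 1, (parity[1] + dy) // 2 - 1, (parity[2] + dx) // 2 - 1]
            src = []
            dst = []
            ok = True
            for i in range(3):
                lo = max(0, -off[i])
                hi = min(sub_shape[i], n_axes[i] - off[i])
                if lo >= hi:
                    ok = False
                    break
                src.append(slice(lo, hi))
                dst.append(slice(lo + off[i], hi + off[i]))
            if not ok:
                continue
            contrib = np.where(x[tuple(src)] >= r2, diam[tuple(src)], 0)
            region = tmap[tuple(dst)]
            np.maximum(region, contrib, out=region)
        if count_blobs:
            idx = np.nonzero(active)
            blob_records.append((parity, x, idx, diam))  # type: ignore[arg-type]

    values = tmap.astype(np.float64) * mask.voxel_um
    note = (
        "maximal inscribed digital balls, half-voxel centre grid, "
        f"boundary={boundary}"
    )
    result = ThicknessMap(values=values, voxel_um=mask.voxel_um, method_note=note)
    if count_blobs:
        result.blob_counts_vox = _count_blobs(m.shape, blob_records)
    return result


def _count_blobs(shape, blob_records) -> dict[int, int]:
    """Greedy maximal-ball count per diameter class (descending diameter)."""
    centres = []  # (diam, x, parity, centre subgrid index)
    for parity, x, idx, diam in blob_records:
        for k in range(len(idx[0])):
            s = (int(idx[0][k]), int(idx[1][k]), int(idx[2][k]))
            centres.append((int(diam[s]), int(x[s]), parity, s))
    # descending diameter, then larger ball, then deterministic position order
    centres.sort(key=lambda rec: (-rec[0], -rec[1], rec[2], rec[3]))
    level = np.zeros(shape, dtype=np.int32)
    counts: dict[int, int] = {}
    offsets_cache: dict[tuple, np.ndarray] = {}
    for diam, x, parity, s in centres:
        key = (x, parity)
        if key not in offsets_cache:
            radius = int(np.floor(np.sqrt(x)))
            offs = []
            for dz in range(-radius, radius + 1):
                if (dz - parity[0]) % 2:
                    continue
                for dy in range(-radius, radius + 1):
                    if (dy - parity[1]) % 2:
                        continue
                    for dx in range(-radius, radius + 1):
                        if (dx - parity[2]) % 2:
                            continue
                        if dz * dz + dy * dy + dx * dx <= x:
                            offs.append(
                                (
                                    (parity[0] + dz) // 2 - 1,
                                    (parity[1] + dy) // 2 - 1,
                                    (parity[2] + dx) // 2 - 1,
                                )
                            )
            offsets_cache[key] = np.array(offs, dtype=np.int64)
        offs = offsets_cache[key]
        p = offs + np.array(s, dtype=np.int64)
        valid = np.all((p >= 0) & (p < np.array(shape)), axis=1)
        p = p[valid]
        if p.size == 0:
            continue
        vox = (p[:, 0], p[:, 1], p[:, 2])
        if np.any(level[vox] < diam):
            counts[diam] = counts.get(diam, 0) + 1
            np.maximum.at(level, vox, diam)
    return counts


def thickness_distribution(
    tmap: ThicknessMap, bin_width_um: float = 0.5, weighting: str = "voxel_volume"
) -> ThicknessDistribution:
    """Bin a thickness map into a volume-weighted distribution.

    ``voxel_volume``: V_j = (material voxels with thickness in bin j) *
    voxel_um^3.  ``blob_volume``: V_j = n_j * (pi/6) * d_j^3 with n_j the
    maximal-ball count of class j (requires a map computed with
    ``count_blobs=True``).
    """
    if not bin_width_um > 0:
        raise ValueError("bin_width_um must be positive")
    vals = tmap.values[tmap.values > 0]
    if vals.size == 0:
        raise ValueError("thickness map contains no material voxels")
    n_bins = int(np.floor(vals.max() / bin_width_um)) + 1
    edges = np.arange(n_bins + 1) * bin_width_um
    idx = np.minimum((vals / bin_width_um).astype(int), n_bins - 1)
    voxel_counts = np.bincount(idx, minlength=n_bins)

    if weighting == "voxel_volume":
        number_count = voxel_counts
        class_volume = voxel_counts * tmap.voxel_um**3
    elif weighting == "blob_volume":
        if tmap.blob_counts_vox is None:
            raise ValueError(
                "blob_volume weighting requires a map computed with count_blobs=True"
            )
        number_count = np.zeros(n_bins, dtype=int)
        for diam_vox, n in tmap.blob_counts_vox.items():
            d_um = diam_vox * tmap.voxel_um
            j = min(int(d_um / bin_width_um), n_bins - 1)
            number_count[j] += n
        mids = 0.5 * (edges[:-1] + edges[1:])
        class_volume = number_count * (np.pi / 6.0) * mids**3
    else:
        raise ValueError(f"weighting must be 'voxel_volume' or 'blob_volume', got {weighting!r}")

    return ThicknessDistribution(
        bin_edges=edges,
        number_count=number_count,
        class_volume=class_volume,
        voxel_um=tmap.voxel_um,
        weighting_mode=weighting,
    )


def volume_weighted_mean(dist: ThicknessDistribution) -> float:
    """Volume-weighted mean thickness d_vol = sum(d_j V_j) / sum(V_j), in um."""
    total = dist.class_volume.sum()
    if not total > 0:
        raise ValueError("total class volume is zero")
    return float((dist.class_diameter * dist.class_volume).sum() / total)


def distribution_mode(dist: ThicknessDistribution) -> float:
    """Midpoint of the class with maximal volume weight; ties go to the larger diameter."""
    if not np.any(dist.class_volume > 0):
        raise ValueError("distribution has no nonzero class")
    v = dist.class_volume
    j = len(v) - 1 - int(np.argmax(v[::-1]))
    return float(dist.class_diameter[j])


def is_sub_resolution(dist: ThicknessDistribution) -> bool:
    """True when the dominant thickness class reaches down to one voxel.

    A one-voxel mode is indistinguishable from unresolved structure: no
    positive thickness below one voxel is ever reported, so structures at
    or below the voxel size pile up in the class containing ``voxel_um``.
    The test is on the mode bin's lower edge so it is independent of where
    midpoints fall relative to the voxel size.
    """
    v = dist.class_volume
    j = len(v) - 1 - int(np.argmax(v[::-1]))
    return float(dist.bin_edges[j]) <= dist.voxel_um + 1e-12


def distribution_to_frame(dist: ThicknessDistribution):
    """Tabulate as ``bin_lo_um,bin_hi_um,d_j_um,n_j,V_j_um3,volume_fraction``."""
    import pandas as pd

    total = dist.total_volume
    return pd.DataFrame(
        {
            "bin_lo_um": dist.bin_edges[:-1],
            "bin_hi_um": dist.bin_edges[1:],
            "d_j_um": dist.class_diameter,
            "n_j": dist.number_count,
            "V_j_um3": dist.class_volume,
            "volume_fraction": dist.class_volume / total if total > 0 else 0.0,
        }
    )
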