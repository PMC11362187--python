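"""Synthetic 3D structures and viability series with known ground truth.

Freeze-dried pellet microstructure (sheet-like walls oriented toward the
pellet centre, fine pores of a few micrometres) is emulated by three phantom
families with closed-form wall thickness, so segmentation and local-thickness
recovery can be validated end to end.  A matching generator produces CFU/g
time courses following first-order (exponential) viability decay with an
optional rapid initial loss, mimicking accelerated-storage data.

All generators are deterministic given their spec (seeded); micrometre →
voxel conversion uses round-half-away-from-zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import BinaryVolume, Volume3D
from .viability import ViabilitySeries

__all__ = [
    "PhantomSpec",
    "RenderSpec",
    "DecaySpec",
    "um_to_voxels",
    "make_parallel_plate_phantom",
    "make_radial_lamellae_phantom",
    "make_spherical_pore_phantom",
    "render_greyscale",
    "simulate_viability_series",
]

GEOMETRIES = ("parallel_plates", "radial_lamellae", "spherical_pores")


def um_to_voxels(length_um: float, voxel_um: float) -> int:
    """Convert a physical length to voxels, rounding half away from zero."""
    x = length_um / voxel_um
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class PhantomSpec:
    """Geometric recipe for a ground-truth phantom.

    ``spacing_um`` is the pore gap between walls (or the pore diameter for
    ``spherical_pores``).  Sub-voxel walls (``wall_um < voxel_um``) are
    permitted only with ``allow_sub_voxel=True``, used to probe resolution
    failure deliberately.
    """

    geometry: str
    wall_um: float
    spacing_um: float
    voxel_um: float
    shape_voxels: tuple[int, int, int]
    seed: int = 0
    allow_sub_voxel: bool = False

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}")
        if not self.voxel_um > 0:
            raise ValueError("voxel_um must be positive")
        if self.wall_um < self.voxel_um and not self.allow_sub_voxel:
            raise ValueError(
                f"wall_um={self.wall_um} is below the voxel size {self.voxel_um} um; "
                "sub-voxel walls require allow_sub_voxel=True (resolution-failure tests only)"
            )
        if len(self.shape_voxels) != 3 or any(s < 8 for s in self.shape_voxels):
            raise ValueError(f"shape_voxels must be three integers >= 8, got {self.shape_voxels}")


@dataclass
class RenderSpec:
    """Greyscale rendering of a mask: contrast levels, partial-volume blur, noise."""

    material_level: float = 200.0
    pore_level: float = 20.0
    noise_sd: float = 0.0
    blur_sigma_voxels: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.material_level > self.pore_level:
            raise ValueError("material_level must exceed pore_level")
        if self.noise_sd < 0 or self.blur_sigma_voxels < 0:
            raise ValueError("noise_sd and blur_sigma_voxels must be >= 0")


@dataclass
class DecaySpec:
    """Exponential-decay CFU series: C(t) = c0 * (1 - drop) * 2^(-t / t_half).

    The initial drop is a single multiplicative step applied for t > 0,
    emulating the rapid early viability loss seen on top of first-order
    storage decay.  Multiplicative log-normal noise has unit median so the
    median curve is the noiseless one.
    """

    c0: float
    half_life_days: float
    timepoints_days: tuple[float, ...] = (0.0, 7.0, 14.0, 28.0, 56.0)
    initial_drop_fraction: float = 0.0
    noise_cv: float = 0.0
    seed: int = 0
    batch: str = "batch1"
    condition: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.c0 > 0:
            raise ValueError("c0 must be positive")
        if not self.half_life_days > 0:
            raise ValueError("half_life_days must be positive")
        t = np.asarray(self.timepoints_days, dtype=float)
        if t.size < 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints_days must be nonnegative and strictly increasing")
        if not 0 <= self.initial_drop_fraction < 1:
            raise ValueError("initial_drop_fraction must be in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def make_parallel_plate_phantom(spec: PhantomSpec) -> BinaryVolume:
    """Alternating solid slabs and pore gaps along the first (z) axis.

    Material fraction equals wall/(wall+spacing) of the discretized pattern
    when the z extent is a whole number of periods.
    """
    if spec.geometry != "parallel_plates":
        raise ValueError("spec.geometry must be 'parallel_plates'")
    wall_vox = um_to_voxels(spec.wall_um, spec.voxel_um)
    gap_vox = um_to_voxels(spec.spacing_um, spec.voxel_um)
    if wall_vox < 1:
        raise ValueError(
            f"wall_um={spec.wall_um} um rounds to 0 voxels at voxel_um={spec.voxel_um}: "
            "wall is below resolution"
        )
    if gap_vox < 1:
        raise ValueError(
            f"spacing_um={spec.spacing_um} um rounds to 0 voxels at voxel_um={spec.voxel_um}: "
            "pore gap is below resolution"
        )
    period = wall_vox + gap_vox
    z = np.arange(spec.shape_voxels[0]) % period
    plane_is_material = z < wall_vox
    mask = np.broadcast_to(
        plane_is_material[:, None, None], spec.shape_voxels
    ).copy()
    return BinaryVolume(
        mask=mask,
        voxel_um=spec.voxel_um,
        threshold_used="manual/none",
        meta={
            "phantom": "parallel_plates",
            "wall_voxels": wall_vox,
            "spacing_voxels": gap_vox,
            "wall_um_discretized": wall_vox * spec.voxel_um,
            "spec": spec,
        },
    )


def make_radial_lamellae_phantom(spec: PhantomSpec, n_sheets: int) -> BinaryVolume:
    """Planar sheets radiating from the volume's central z-axis.

    Emulates the sheet-like walls oriented toward the pellet centre seen in
    freeze-dried pellets.  Each sheet is a half-plane through the axis; a
    voxel is material when its centre lies within ``wall_um/2`` (Euclidean,
    in um) of an ideal sheet and inside the inscribed cylinder.  Sheets
    necessarily merge near the axis; if the angular gap at the rim is smaller
    than the wall thickness a merging warning is emitted.
    """
    if spec.geometry != "radial_lamellae":
        raise ValueError("spec.geometry must be 'radial_lamellae'")
    if n_sheets < 3:
        raise ValueError("n_sheets must be >= 3")
    nz, ny, nx = spec.shape_voxels
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius_um = min(ny, nx) / 2.0 * spec.voxel_um
    rim_gap_um = 2 * np.pi * radius_um / n_sheets
    if rim_gap_um < spec.wall_um:
        warnings.warn(
            f"angular gap at the rim ({rim_gap_um:.2f} um) is smaller than the wall "
            f"thickness ({spec.wall_um:.2f} um): sheets merge throughout the volume",
            stacklevel=2,
        )

    yy, xx = np.meshgrid(
        (np.arange(ny) - cy) * spec.voxel_um,
        (np.arange(nx) - cx) * spec.voxel_um,
        indexing="ij",
    )
    r = np.hypot(yy, xx)
    angles = 2 * np.pi * np.arange(n_sheets) / n_sheets
    half_wall = spec.wall_um / 2.0
    near_sheet = np.zeros((ny, nx), dtype=bool)
    for th in angles:
        u = np.array([np.cos(th), np.sin(th)])  # (y, x) direction of the half-plane
        proj = yy * u[0] + xx * u[1]
        # distance to half-plane: perpendicular where the projection is
        # forward, distance to the axis otherwise
        perp = np.abs(yy * u[1] - xx * u[0])
        dist = np.where(proj >= 0, perp, r)
        near_sheet |= dist <= half_wall
    section = near_sheet & (r <= radius_um)
    mask = np.broadcast_to(section[None, :, :], (nz, ny, nx)).copy()
    return BinaryVolume(
        mask=mask,
        voxel_um=spec.voxel_um,
        threshold_used="manual/none",
        meta={"phantom": "radial_lamellae", "n_sheets": n_sheets, "radius_um": radius_um,
              "spec": spec},
    )


def make_spherical_pore_phantom(
    spec: PhantomSpec, target_porosity: float, seed: int | None = None
) -> BinaryVolume:
    """Solid block minus randomly centred spherical pores of one diameter.

    Pores of ``spacing_um`` diameter (the fine ~5 um pores of non-annealed
    freeze-dried structure) are carved at uniformly random centres until the
    measured porosity reaches ``target_porosity``.  Achieved porosity is
    returned in ``meta``.
    """
    if spec.geometry != "spherical_pores":
        raise ValueError("spec.geometry must be 'spherical_pores'")
    if not 0 <= target_porosity < 1:
        raise ValueError("target_porosity must be in [0, 1)")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = spec.shape_voxels
    mask = np.ones(shape, dtype=bool)
    pore_radius_vox = um_to_voxels(spec.spacing_um, spec.voxel_um) / 2.0
    if target_porosity > 0 and pore_radius_vox < 0.5:
        raise ValueError("pore diameter rounds below one voxel: pores are below resolution")
    n_total = int(np.prod(shape))
    ball_vol = max(1.0, 4.0 / 3.0 * np.pi * pore_radius_vox**3)
    max_attempts = int(1e4 * n_total / ball_vol)
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    attempts = 0
    while mask.mean() > 1.0 - target_porosity:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"target porosity {target_porosity} unreachable after {attempts} pore placements"
            )
        c = rng.uniform(0, np.array(shape) - 1)
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        mask &= d2 > pore_radius_vox**2
        attempts += 1
    return BinaryVolume(
        mask=mask,
        voxel_um=spec.voxel_um,
        threshold_used="manual/none",
        meta={
            "phantom": "spherical_pores",
            "achieved_porosity": 1.0 - float(mask.mean()),
            "target_porosity": target_porosity,
            "n_pores": attempts,
            "spec": spec,
        },
    )


def render_greyscale(mask: BinaryVolume, render: RenderSpec) -> Volume3D:
    """Render a mask as a greyscale volume with blur and additive noise.

    Emulates uCT contrast: material and pore at two grey levels, Gaussian
    partial-volume blur, then additive Gaussian noise.  Deterministic for a
    fixed ``render.seed``.
    """
    data = np.where(mask.mask, render.material_level, render.pore_level).astype(np.float64)
    if render.blur_sigma_voxels > 0:
        data = ndimage.gaussian_filter(data, sigma=render.blur_sigma_voxels, mode="nearest")
    if render.noise_sd > 0:
        rng = np.random.default_rng(render.seed)
        data = data + rng.normal(0.0, render.noise_sd, size=data.shape)
    return Volume3D(
        data=data,
        voxel_um=mask.voxel_um,
        provenance=f"rendered phantom ({mask.meta.get('phantom', 'mask')}, seed={render.seed})",
    )


def simulate_viability_series(spec: DecaySpec) -> ViabilitySeries:
    """CFU/g time course under exponential decay with an optional initial drop.

    C(0) = c0 exactly (no noise); for t > 0,
    C(t) = c0 * (1 - initial_drop_fraction) * 2^(-t / half_life_days),
    multiplied by unit-median log-normal noise of coefficient of variation
    ``noise_cv``.
    """
    t = np.asarray(spec.timepoints_days, dtype=float)
    counts = spec.c0 * (1.0 - spec.initial_drop_fraction) * 2.0 ** (-t / spec.half_life_days)
    counts[t == 0] = spec.c0
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = np.exp(rng.normal(0.0, sigma, size=t.shape))  # unit median
        noise[t == 0] = 1.0
        counts = counts * noise
    return ViabilitySeries(times=t, counts=counts, batch=spec.batch, condition=spec.condition)
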