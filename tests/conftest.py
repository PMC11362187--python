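"""Shared fixtures: small ground-truth masks built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from lyothick.volumes import BinaryVolume


def slab_mask(wall_voxels: int, shape=(0, 30, 30), pad: int = 2) -> np.ndarray:
    """A single solid slab of ``wall_voxels`` planes along z, pore elsewhere.

    The z extent defaults to wall + 2*pad so the slab sits away from the
    volume boundary; lateral extent is wide relative to the wall.
    """
    nz = shape[0] or wall_voxels + 2 * pad
    m = np.zeros((nz, shape[1], shape[2]), dtype=bool)
    m[pad : pad + wall_voxels] = True
    return m


def digital_ball_mask(radius_voxels: int, margin: int = 2) -> tuple[np.ndarray, tuple[int, int, int]]:
    """A digital ball (voxel centres within the given radius) in empty space."""
    n = 2 * (radius_voxels + margin) + 1
    c = n // 2
    zz, yy, xx = np.ogrid[:n, :n, :n]
    mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_voxels**2
    return mask, (c, c, c)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_masks(rng):
    """Random binary volumes with material fraction 0.2-0.8."""

    def _make(n_volumes: int, side: int = 16):
        out = []
        for _ in range(n_volumes):
            frac = rng.uniform(0.2, 0.8)
            out.append(rng.random((side, side, side)) < frac)
        return out

    return _make


def as_binary(mask: np.ndarray, voxel_um: float = 1.0) -> BinaryVolume:
    return BinaryVolume(mask=mask, voxel_um=voxel_um)
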