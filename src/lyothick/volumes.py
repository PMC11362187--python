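"""Core in-memory containers for 3D tomographic data.

A :class:`Volume3D` is a greyscale reconstruction (axes ordered ``(z, y, x)``)
with an isotropic physical voxel size; a :class:`BinaryVolume` is the
segmented material/pore mask derived from it.  Both carry ``voxel_um`` so
every downstream thickness quantity is reported in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Volume3D", "BinaryVolume"]


@dataclass
class Volume3D:
    """Greyscale 3D image with a physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Scalar intensities; must be finite.
    voxel_um : float
        Isotropic voxel edge length in micrometres.
    provenance : str
        Free text describing where the volume came from (file path or
        generator spec).
    """

    data: np.ndarray
    voxel_um: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 2:
            raise ValueError(f"all axes must have >= 2 voxels, got shape {self.data.shape}")
        if not self.voxel_um > 0:
            raise ValueError(f"voxel_um must be positive, got {self.voxel_um}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """Segmented material (True) / pore (False) mask.

    ``threshold_used`` records the grey level that produced the mask, or a
    string such as ``"manual/none"`` for generated or hand-made masks.
    ``meta`` holds generator bookkeeping (e.g. achieved porosity).
    """

    mask: np.ndarray
    voxel_um: float
    threshold_used: float | str = "manual/none"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            raise ValueError(f"mask must be boolean, got dtype {self.mask.dtype}")
        if self.mask.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.mask.ndim}")
        if not self.voxel_um > 0:
            raise ValueError(f"voxel_um must be positive, got {self.voxel_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def material_voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def material_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def porosity(self) -> float:
        return 1.0 - self.material_fraction
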