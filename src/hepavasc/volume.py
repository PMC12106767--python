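"""Core in-memory containers: grey-value volumes and binary masks.

All 3-D grids are indexed ``(z, y, x)`` and carry a single isotropic voxel
size in micrometres, matching the reconstructed phase-contrast CT volumes
the pipeline was designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Volume3D", "VesselMask", "NoduleMask"]

_PROVENANCES = {"frangi", "threshold", "merged", "small", "large", "truth"}


@dataclass
class Volume3D:
    """Isotropic 3-D grey-value volume.

    Parameters
    ----------
    data:
        3-D array of grey values (dimensionless, typically normalised to
        [0, 1]).
    voxel_size:
        Isotropic voxel edge length in micrometres.
    """

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0 µm, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite grey values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(self.voxel_size) ** 3


@dataclass
class VesselMask:
    """Binary vessel mask aligned to a :class:`Volume3D`."""

    data: np.ndarray
    voxel_size: float
    provenance: str = "truth"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0 µm, got {self.voxel_size}")
        if self.provenance not in _PROVENANCES:
            raise ValueError(
                f"unknown provenance {self.provenance!r}; expected one of {sorted(_PROVENANCES)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(self.voxel_size) ** 3

    def count(self) -> int:
        return int(self.data.sum())


# A nodule (metastasis) mask has the same mechanics as a vessel mask; the
# alias keeps signatures self-documenting.
@dataclass
class NoduleMask:
    """Binary metastatic-nodule mask aligned to a :class:`Volume3D`."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0 µm, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def check_aligned(*grids) -> None:
    """Raise if the given volumes/masks disagree in shape or voxel size."""
    shapes = {g.shape for g in grids}
    sizes = {round(float(g.voxel_size), 9) for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch between grids: {sorted(shapes)}")
    if len(sizes) > 1:
        raise ValueError(f"voxel-size mismatch between grids: {sorted(sizes)}")
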