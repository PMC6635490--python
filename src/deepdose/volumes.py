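"""Shared in-memory containers for 3-D volumes on a common voxel grid.

All volumes in the pipeline are plain ``float64``/``int`` numpy arrays indexed
``[x, y, z]`` together with the physical voxel size in millimetres and a units
tag.  Grid equality (shape and voxel size) is enforced at every multi-volume
operation; there is no silent resampling anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Units tags accepted on disk and in memory.
KNOWN_UNITS = ("Bq/mL", "HU", "g/cm3", "Gy", "Gy/s", "label", "MBq·s",
               "Gy/(MBq·s)", "dimensionless")


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass
class Volume:
    """A 3-D scalar field with voxel geometry and a mandatory units tag.

    Parameters
    ----------
    data:
        3-D array, indexed ``[x, y, z]``.
    voxel_size:
        Physical voxel edge lengths in mm, ``(dx, dy, dz)``.
    units:
        One of :data:`KNOWN_UNITS`.
    meta:
        Free-form provenance (stage name, seed, config hash, time stamp ...).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    units: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.units not in KNOWN_UNITS:
            raise ValueError(f"unknown units tag {self.units!r}; expected one of {KNOWN_UNITS}")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (1 mL = 1 cm^3 = 1000 mm^3)."""
        return self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size, other.voxel_size)

    def with_data(self, data: np.ndarray, units: Optional[str] = None, **meta) -> "Volume":
        out = replace(self, data=data, units=units or self.units)
        out.meta = {**self.meta, **meta}
        return out


@dataclass
class DoseMap(Volume):
    """Absorbed dose (Gy) or dose rate (Gy/s) with per-voxel relative uncertainty."""

    rel_uncertainty: Optional[np.ndarray] = None
    n_histories: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.rel_uncertainty is not None:
            self.rel_uncertainty = np.asarray(self.rel_uncertainty)
            if self.rel_uncertainty.shape != self.data.shape:
                raise GridMismatchError("rel_uncertainty grid differs from dose grid")


def check_same_grid(*volumes: Volume) -> None:
    """Raise :class:`GridMismatchError` naming both grids on any mismatch."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_grid(v):
            raise GridMismatchError(
                f"grid mismatch: {ref.shape} @ {ref.voxel_size} mm "
                f"vs {v.shape} @ {v.voxel_size} mm"
            )
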