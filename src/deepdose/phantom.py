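"""Synthetic co-registered PET/CT phantoms with dynamic time-activity behaviour.

Real dynamic PET/CT patient volumes are replaced by geometric phantoms: a set
of ellipsoid/cuboid "organs" on a voxel grid, each carrying a material tag
(air, lung, adipose, soft tissue, bone), an initial activity concentration in
Bq/mL and an effective clearance half-time.  The phantom generator produces
four aligned volumes — activity, CT number (HU), mass density and integer organ
labels — plus dynamic frames in which each organ decays mono-exponentially.

The HU→density mapping is a small five-class piecewise-linear table in the
style of a stylised Schneider calibration; the breakpoints are listed in
:data:`MATERIAL_TABLE` so the oracle stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .volumes import Volume, check_same_grid

# ---------------------------------------------------------------------------
# Material table (five classes).  HU is the nominal CT number assigned to
# phantom voxels of that material; density in g/cm^3.  The HU→density mapping
# interpolates linearly between these breakpoints and extrapolates above bone.
# ---------------------------------------------------------------------------
MATERIAL_TABLE: dict[str, dict[str, float]] = {
    "air": {"hu": -1000.0, "density": 0.00121},
    "lung": {"hu": -740.0, "density": 0.26},
    "adipose": {"hu": -98.0, "density": 0.95},
    "soft": {"hu": 0.0, "density": 1.000},
    "bone": {"hu": 1200.0, "density": 1.85},
}

GA68_HALF_LIFE_MIN = 67.71  # physical half-life of Ga-68

_HU_BREAKS = np.array([MATERIAL_TABLE[m]["hu"] for m in ("air", "lung", "adipose", "soft", "bone")])
_RHO_BREAKS = np.array(
    [MATERIAL_TABLE[m]["density"] for m in ("air", "lung", "adipose", "soft", "bone")]
)


def hu_to_density(hu) -> np.ndarray | float:
    """Convert CT numbers (HU) to mass density (g/cm^3).

    Piecewise-linear and monotone non-decreasing through the breakpoints of
    :data:`MATERIAL_TABLE` (water at HU 0 → 1.000 g/cm^3 by definition of the
    HU scale).  Values below −1000 HU clamp to air density; values above the
    bone breakpoint extrapolate with the adipose→bone slope.
    """
    hu_arr = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu_arr)):
        raise ValueError("HU values must be finite")
    clamped = np.clip(hu_arr, _HU_BREAKS[0], None)
    # np.interp is flat beyond the last breakpoint; extend linearly instead.
    rho = np.interp(clamped, _HU_BREAKS, _RHO_BREAKS)
    slope = (_RHO_BREAKS[-1] - _RHO_BREAKS[-2]) / (_HU_BREAKS[-1] - _HU_BREAKS[-2])
    above = clamped > _HU_BREAKS[-1]
    rho = np.where(above, _RHO_BREAKS[-1] + slope * (clamped - _HU_BREAKS[-1]), rho)
    if np.isscalar(hu) or np.ndim(hu) == 0:
        return float(rho)
    return rho


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------


@dataclass
class OrganSpec:
    """One geometric organ: an ellipsoid or axis-aligned cuboid.

    ``center`` and ``semi_axes`` are in voxel coordinates (may be fractional);
    for a cuboid the semi-axes are half edge lengths.  ``activity`` is the
    initial activity concentration in Bq/mL and ``half_time_min`` the effective
    clearance half-time (physical + biological) in minutes; ``np.inf`` means no
    clearance.
    """

    label: int
    shape: Literal["ellipsoid", "cuboid"]
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    material: str = "soft"
    activity: float = 0.0
    half_time_min: float = GA68_HALF_LIFE_MIN
    name: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "cuboid"):
            raise ValueError(f"unknown primitive {self.shape!r}")
        if self.material not in MATERIAL_TABLE:
            raise ValueError(f"unknown material {self.material!r}")
        if self.activity < 0:
            raise ValueError("activity concentration must be >= 0")
        if self.label <= 0:
            raise ValueError("organ labels must be positive integers (0 = background)")
        if not self.name:
            self.name = f"organ{self.label}"


@dataclass
class PhantomSpec:
    grid_dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (2.67, 2.67, 5.0)
    organs: Sequence[OrganSpec] = field(default_factory=list)
    background_material: str = "air"
    background_activity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(d) <= 0 for d in self.grid_dims):
            raise ValueError("grid_dims must be positive")
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if self.background_material not in MATERIAL_TABLE:
            raise ValueError(f"unknown material {self.background_material!r}")
        for organ in self.organs:
            lo = np.array(organ.center) - np.array(organ.semi_axes)
            hi = np.array(organ.center) + np.array(organ.semi_axes)
            if np.any(lo < -0.5) or np.any(hi > np.array(self.grid_dims) - 0.5):
                raise ValueError(f"organ {organ.name!r} extends outside the grid")


@dataclass
class Phantom:
    """The four aligned volumes a phantom spec generates."""

    activity: Volume  # Bq/mL
    ct: Volume  # HU
    density: Volume  # g/cm^3
    labels: Volume  # integer organ labels, 0 = background
    spec: PhantomSpec = None  # type: ignore[assignment]


def _organ_mask(organ: OrganSpec, dims: tuple[int, int, int]) -> np.ndarray:
    ix, iy, iz = np.meshgrid(*[np.arange(d, dtype=float) for d in dims], indexing="ij")
    cx, cy, cz = organ.center
    ax, ay, az = organ.semi_axes
    if organ.shape == "ellipsoid":
        return ((ix - cx) / ax) ** 2 + ((iy - cy) / ay) ** 2 + ((iz - cz) / az) ** 2 <= 1.0
    return (np.abs(ix - cx) <= ax) & (np.abs(iy - cy) <= ay) & (np.abs(iz - cz) <= az)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise a phantom spec into activity / CT / density / label volumes.

    Voxels covered by several organs are assigned wholly to the *last-listed*
    covering organ (no sub-voxel fractions).  CT numbers are the nominal HU of
    each voxel's material; density follows from :func:`hu_to_density`, so the
    two volumes are consistent by construction.  Output is deterministic.
    """
    dims = spec.grid_dims
    labels = np.zeros(dims, dtype=np.int32)
    activity = np.full(dims, float(spec.background_activity))
    ct = np.full(dims, MATERIAL_TABLE[spec.background_material]["hu"])
    for organ in spec.organs:
        mask = _organ_mask(organ, dims)
        if not mask.any():
            raise ValueError(f"organ {organ.name!r} covers zero voxels")
        labels[mask] = organ.label
        activity[mask] = organ.activity
        ct[mask] = MATERIAL_TABLE[organ.material]["hu"]
    density = hu_to_density(ct)
    vs = spec.voxel_size
    meta = {"stage": "phantom", "seed": spec.seed}
    return Phantom(
        activity=Volume(activity, vs, "Bq/mL", dict(meta)),
        ct=Volume(ct, vs, "HU", dict(meta)),
        density=Volume(np.asarray(density), vs, "g/cm3", dict(meta)),
        labels=Volume(labels, vs, "label", dict(meta)),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Dynamic series
# ---------------------------------------------------------------------------

#: Default imaging schedule: frame start times in minutes post-injection.
DEFAULT_TIME_POINTS_MIN = (1.0, 4.0, 7.0, 10.0, 15.0, 30.0, 46.0, 62.0)


@dataclass
class DynamicSeries:
    time_points_min: tuple[float, ...]
    frames: list[Volume]

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points_min, dtype=float)
        if t.ndim != 1 or len(t) != len(self.frames):
            raise ValueError("one frame per time point required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        check_same_grid(*self.frames)
        self.time_points_min = tuple(float(x) for x in t)


def make_dynamic_series(
    phantom: Phantom, time_points_min: Sequence[float] = DEFAULT_TIME_POINTS_MIN
) -> DynamicSeries:
    """Generate activity frames at the requested times.

    Each organ's concentration is scaled by ``2**(-t / T_eff)`` with its own
    effective half-time; background activity decays with the physical Ga-68
    half-life.  Frame 0 of the phantom is the t = 0 distribution.
    """
    for organ in phantom.spec.organs:
        if not organ.half_time_min > 0:
            raise ValueError(f"organ {organ.name!r} has non-positive half-time")
    labels = phantom.labels.data
    base = phantom.activity.data
    frames = []
    for t in time_points_min:
        frame = base * 2.0 ** (-float(t) / GA68_HALF_LIFE_MIN)  # background default
        for organ in phantom.spec.organs:
            decay = 2.0 ** (-float(t) / organ.half_time_min) if np.isfinite(organ.half_time_min) else 1.0
            sel = labels == organ.label
            frame[sel] = base[sel] * decay
        frames.append(phantom.activity.with_data(frame, time_min=float(t)))
    return DynamicSeries(tuple(float(t) for t in time_points_min), frames)


def total_mass_g(density: Volume) -> float:
    """Total phantom mass in grams (density g/cm^3 × voxel volume cm^3)."""
    return float(density.data.sum() * density.voxel_volume_ml)
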