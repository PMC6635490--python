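"""Patch extraction/assembly for patch-based dose-rate learning.

A static PET/CT/dose-rate volume triplet is divided into fixed-size
overlapping 3-D patches (default 48×48×24) on a regular offset grid
(default 7 voxels transverse, 5 axial).  Patches containing less than a
configurable fraction (default 1/8) of "imaged body" voxels are excluded; the
body is a thresholded-HU mask reduced to its largest connected component.
Predicted patches are reassembled into a volume by uniform averaging over
covering patches.

Coordinates are 0-based with inclusive start / exclusive end throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volumes import Volume, check_same_grid

DEFAULT_PATCH_DIMS = (48, 48, 24)
DEFAULT_OFFSETS = (7, 7, 5)
DEFAULT_MIN_BODY_FRACTION = 1.0 / 8.0
DEFAULT_BODY_HU_THRESHOLD = -500.0


@dataclass(frozen=True)
class PatchIndex:
    """One patch: inclusive-start corner plus fixed dims."""

    corner: tuple[int, int, int]
    dims: tuple[int, int, int]
    body_fraction: float = 1.0

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(c, c + d) for c, d in zip(self.corner, self.dims))  # type: ignore[return-value]


@dataclass
class PatchSet:
    """Aligned stacks of PET / CT / dose patches plus their indices."""

    indices: list[PatchIndex]
    pet: np.ndarray  # (n, px, py, pz)
    ct: np.ndarray
    dose: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.indices)
        for name, stack in (("pet", self.pet), ("ct", self.ct), ("dose", self.dose)):
            if stack is not None and stack.shape[0] != n:
                raise ValueError(f"{name} stack has {stack.shape[0]} patches, expected {n}")

    def __len__(self) -> int:
        return len(self.indices)

    @staticmethod
    def concatenate(sets: Sequence["PatchSet"]) -> "PatchSet":
        indices = [ix for s in sets for ix in s.indices]
        dose = None
        if all(s.dose is not None for s in sets):
            dose = np.concatenate([s.dose for s in sets])
        return PatchSet(indices,
                        np.concatenate([s.pet for s in sets]),
                        np.concatenate([s.ct for s in sets]),
                        dose,
                        {"merged_from": [s.provenance for s in sets]})


def make_body_mask(
    ct: Volume,
    hu_threshold: float = DEFAULT_BODY_HU_THRESHOLD,
    fill_holes: bool = True,
) -> np.ndarray:
    """Binary body mask: HU above threshold, largest connected component.

    With ``fill_holes`` (default) interior cavities below the threshold —
    lungs, bowel gas — are filled slice-independently in 3-D, so "body" means
    the whole imaged body part, not just soft tissue.
    """
    raw = ct.data > hu_threshold
    if not raw.any():
        raise ValueError("empty body mask: no voxels above the HU threshold")
    labelled, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labelled, index=np.arange(1, n + 1))
        raw = labelled == (1 + int(np.argmax(sizes)))
    if fill_holes:
        raw = ndimage.binary_fill_holes(raw)
    return raw


def enumerate_patches(
    volume_dims: tuple[int, int, int],
    patch_dims: tuple[int, int, int] = DEFAULT_PATCH_DIMS,
    offsets: tuple[int, int, int] = DEFAULT_OFFSETS,
    mask: Optional[np.ndarray] = None,
    min_fraction: float = DEFAULT_MIN_BODY_FRACTION,
) -> list[PatchIndex]:
    """All in-bounds patch corners on the regular offset grid.

    Corners are at (o_x·i, o_y·j, o_z·k) for non-negative integers keeping
    the patch inside the volume; ordering is lexicographic by corner.  When a
    mask is given, patches whose body fraction is below ``min_fraction`` are
    discarded.  No extra boundary-flush patches are added.
    """
    if any(p > v for p, v in zip(patch_dims, volume_dims)):
        raise ValueError(f"patch {patch_dims} larger than volume {volume_dims}")
    if mask is not None and mask.shape != tuple(volume_dims):
        raise ValueError("mask shape does not match volume dims")
    patch_vox = int(np.prod(patch_dims))
    out: list[PatchIndex] = []
    for cx in range(0, volume_dims[0] - patch_dims[0] + 1, offsets[0]):
        for cy in range(0, volume_dims[1] - patch_dims[1] + 1, offsets[1]):
            for cz in range(0, volume_dims[2] - patch_dims[2] + 1, offsets[2]):
                idx = PatchIndex((cx, cy, cz), tuple(patch_dims))
                if mask is None:
                    out.append(idx)
                    continue
                frac = float(mask[idx.slices()].sum()) / patch_vox
                if frac >= min_fraction:
                    out.append(PatchIndex((cx, cy, cz), tuple(patch_dims), frac))
    return out


def subsample_patches(
    indices: list[PatchIndex], cap: int, seed: int = 0
) -> list[PatchIndex]:
    """Uniform random subsample to at most ``cap`` patches (order preserved)."""
    if len(indices) <= cap:
        return list(indices)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(indices), size=cap, replace=False))
    return [indices[i] for i in keep]


def extract(
    pet: Volume,
    ct: Volume,
    dose: Optional[Volume],
    indices: list[PatchIndex],
    provenance: Optional[dict] = None,
) -> PatchSet:
    """Crop aligned PET/CT(/dose) patches.  No normalisation is applied here."""
    vols = [v for v in (pet, ct, dose) if v is not None]
    check_same_grid(*vols)
    for idx in indices:
        if any(c < 0 or c + d > s for c, d, s in zip(idx.corner, idx.dims, pet.shape)):
            raise ValueError(f"patch {idx.corner}+{idx.dims} out of bounds for {pet.shape}")
    def crop(vol: Volume) -> np.ndarray:
        if not indices:
            return np.empty((0, 0, 0, 0))
        return np.stack([vol.data[idx.slices()] for idx in indices])
    return PatchSet(
        list(indices),
        crop(pet),
        crop(ct),
        crop(dose) if dose is not None else None,
        provenance or {},
    )


def assemble_prediction(
    indices: list[PatchIndex],
    predicted: np.ndarray,
    volume_dims: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Reassemble patch predictions by uniform averaging over covering patches.

    Returns ``(volume, coverage_count)``.  Voxels covered by no patch are
    zero in the output and zero in the coverage map; callers decide whether
    that matters (a warning report is produced by :func:`coverage_report`).
    """
    if len(indices) != predicted.shape[0]:
        raise ValueError("one predicted patch per index required")
    acc = np.zeros(volume_dims)
    cover = np.zeros(volume_dims, dtype=np.int32)
    for idx, patch in zip(indices, predicted):
        sl = idx.slices()
        acc[sl] += patch
        cover[sl] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cover > 0, acc / np.maximum(cover, 1), 0.0)
    return out, cover


def coverage_report(cover: np.ndarray, body_mask: np.ndarray) -> dict:
    """Summary of body voxels not covered by any patch."""
    uncovered = int(((cover == 0) & body_mask).sum())
    return {
        "body_voxels": int(body_mask.sum()),
        "uncovered_body_voxels": uncovered,
        "fully_covered": uncovered == 0,
    }
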