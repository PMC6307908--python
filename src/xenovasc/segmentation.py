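"""Thresholded 3D object detection and the graft area of interest (AOI).

Fluorescent objects are voxels at or above an intensity threshold, grouped
into 3D connected components (default 26-connectivity, i.e. diagonal-touching
voxels connect) and filtered by a minimum object volume. Volumes are exact:
voxel count × voxel volume, with anisotropy carried in the voxel volume —
no sub-voxel interpolation or resampling.

Both intensity and size thresholds are inclusive (``>=``): an object of
exactly the minimum volume is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import measure

from .exceptions import EmptyObjectSetError, UnknownRoleError
from .image_io import VolumetricStack

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class ObjectSet:
    """Labelled connected components surviving the intensity/size filters.

    ``labels`` is a 3D integer grid: 0 = background, k >= 1 = object id.
    Objects are labelled 1..K in decreasing volume order, ties broken by
    smallest centroid z, then y, then x. ``volumes`` and ``centroids`` are
    indexed by ``k - 1`` and expressed in µm³ and µm (voxel-centre
    coordinates) respectively.
    """

    labels: np.ndarray
    volumes: np.ndarray  # (K,) µm³
    centroids: np.ndarray  # (K, 3) µm, (z, y, x)
    voxel_size: tuple[float, float, float]
    source_channel: str
    thresholds_used: tuple[float, float, int]  # (min_intensity, min_volume, connectivity)
    _z_slices: dict[int, frozenset[int]] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def is_empty(self) -> bool:
        return len(self.volumes) == 0

    @property
    def total_volume(self) -> float:
        """Summed object volume in µm³."""
        return float(self.volumes.sum()) if len(self.volumes) else 0.0

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def mask(self) -> np.ndarray:
        return self.labels > 0

    def z_slices(self, object_id: int) -> frozenset[int]:
        """Set of z indices occupied by the given object."""
        if object_id not in self._z_slices:
            occ = (self.labels == object_id).any(axis=(1, 2))
            self._z_slices[object_id] = frozenset(np.nonzero(occ)[0].tolist())
        return self._z_slices[object_id]

    def to_table(self):
        """Object table as a pandas DataFrame (id, volume, centroid)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "object_id": np.arange(1, len(self) + 1),
                "volume_um3": self.volumes,
                "centroid_z_um": self.centroids[:, 0] if len(self) else [],
                "centroid_y_um": self.centroids[:, 1] if len(self) else [],
                "centroid_x_um": self.centroids[:, 2] if len(self) else [],
            }
        )


@dataclass
class AOI:
    """3D area of interest: an axis-aligned voxel box or an explicit mask.

    Box bounds are inclusive voxel-index ranges per axis. In physical terms
    the box spans ``[lo * d, (hi + 1) * d]`` µm per axis, and a point exactly
    on a boundary face lies inside (inclusive bounds).
    """

    mode: Literal["bounding_box", "mask"]
    voxel_size: tuple[float, float, float]
    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    mask_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode == "bounding_box":
            if self.bounds is None:
                raise ValueError("bounding_box AOI needs bounds")
        elif self.mode == "mask":
            if self.mask_grid is None:
                raise ValueError("mask AOI needs a boolean grid")
            self.mask_grid = np.asarray(self.mask_grid, dtype=bool)
        else:
            raise ValueError(f"unknown AOI mode {self.mode!r}")

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def volume(self) -> float:
        """AOI volume in µm³ (box: side-length product; mask: voxel count)."""
        if self.mode == "bounding_box":
            n = 1
            for lo, hi in self.bounds:  # type: ignore[union-attr]
                n *= hi - lo + 1
            return n * self.voxel_volume
        return int(self.mask_grid.sum()) * self.voxel_volume  # type: ignore[union-attr]

    def as_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean grid of the AOI on the given stack shape."""
        if self.mode == "mask":
            if self.mask_grid.shape != tuple(shape):  # type: ignore[union-attr]
                raise ValueError("mask AOI shape does not match stack shape")
            return self.mask_grid  # type: ignore[return-value]
        out = np.zeros(shape, dtype=bool)
        (z0, z1), (y0, y1), (x0, x1) = self.bounds  # type: ignore[misc]
        out[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1] = True
        return out

    def contains_point(self, point_um, tol: float = 1e-9) -> bool:
        """Whether a physical point (z, y, x in µm) lies in the AOI.

        Boundary faces are inclusive; for mask mode a point on a shared face
        counts if any adjacent voxel is in the mask.
        """
        p = np.asarray(point_um, dtype=float).reshape(3)
        vs = np.asarray(self.voxel_size)
        if self.mode == "bounding_box":
            lo = np.array([b[0] for b in self.bounds]) * vs  # type: ignore[union-attr]
            hi = (np.array([b[1] for b in self.bounds]) + 1) * vs  # type: ignore[union-attr]
            return bool(np.all(p >= lo - tol) and np.all(p <= hi + tol))
        grid = self.mask_grid  # type: ignore[assignment]
        cand_per_axis = []
        for axis in range(3):
            lo_idx = int(np.floor((p[axis] - tol) / vs[axis]))
            hi_idx = int(np.floor((p[axis] + tol) / vs[axis]))
            cand_per_axis.append({c for c in (lo_idx, hi_idx) if 0 <= c < grid.shape[axis]})
        for z in cand_per_axis[0]:
            for y in cand_per_axis[1]:
                for x in cand_per_axis[2]:
                    if grid[z, y, x]:
                        return True
        return False


def _label_and_filter(
    channel: np.ndarray,
    voxel_size: tuple[float, float, float],
    min_intensity: float,
    min_volume: float,
    connectivity: int,
    source_channel: str,
    restrict_mask: np.ndarray | None = None,
) -> ObjectSet:
    if channel.size == 0:
        raise EmptyObjectSetError("cannot segment an empty stack")
    if not (min_intensity > 0 and min_volume > 0):
        raise ValueError("intensity and volume thresholds must be strictly positive")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")

    foreground = channel >= min_intensity
    if restrict_mask is not None:
        foreground = foreground & restrict_mask

    raw = measure.label(foreground, connectivity=_CONNECTIVITY_RANK[connectivity])
    dz, dy, dx = voxel_size
    voxel_volume = dz * dy * dx

    counts = np.bincount(raw.ravel())
    ids = np.nonzero(counts)[0]
    ids = ids[ids > 0]
    keep = ids[counts[ids] * voxel_volume >= min_volume]

    if keep.size == 0:
        return ObjectSet(
            labels=np.zeros_like(raw),
            volumes=np.empty(0),
            centroids=np.empty((0, 3)),
            voxel_size=voxel_size,
            source_channel=source_channel,
            thresholds_used=(float(min_intensity), float(min_volume), connectivity),
        )

    # index-space centroids, converted to voxel-centre physical coordinates
    idx_centroids = np.array(ndimage.center_of_mass(foreground, raw, keep), dtype=float)
    phys_centroids = (idx_centroids + 0.5) * np.array(voxel_size)
    volumes = counts[keep] * voxel_volume

    order = np.lexsort(
        (phys_centroids[:, 2], phys_centroids[:, 1], phys_centroids[:, 0], -volumes)
    )
    relabel = np.zeros(raw.max() + 1, dtype=np.int32)
    for new_id, pos in enumerate(order, start=1):
        relabel[keep[pos]] = new_id
    return ObjectSet(
        labels=relabel[raw],
        volumes=volumes[order],
        centroids=phys_centroids[order],
        voxel_size=voxel_size,
        source_channel=source_channel,
        thresholds_used=(float(min_intensity), float(min_volume), connectivity),
    )


def threshold_objects(
    stack: VolumetricStack,
    role: str,
    min_intensity: float,
    min_volume: float,
    connectivity: int = 26,
) -> ObjectSet:
    """Detect objects in one channel: threshold, label, size-filter.

    Voxels with intensity >= ``min_intensity`` are foreground; connected
    components under ``connectivity`` with volume >= ``min_volume`` µm³ are
    retained and labelled 1..K in decreasing volume order.
    """
    channel = stack.channel(role)  # raises UnknownRoleError
    return _label_and_filter(
        channel, stack.voxel_size, min_intensity, min_volume, connectivity, role
    )


def build_aoi(objects: ObjectSet, mode: str = "bounding_box") -> AOI:
    """Build the area of interest encompassing all detected objects.

    ``bounding_box`` gives the minimal axis-aligned box containing every
    object voxel (the workflow used for graft quantitation); ``mask`` gives
    the union of the object voxels themselves.
    """
    if mode == "mask":
        return AOI(mode="mask", voxel_size=objects.voxel_size, mask_grid=objects.mask())
    if mode != "bounding_box":
        raise ValueError(f"unknown AOI mode {mode!r}")
    if objects.is_empty:
        raise EmptyObjectSetError("cannot build a bounding-box AOI from zero objects")
    occupied = np.nonzero(objects.labels > 0)
    bounds = tuple((int(axis.min()), int(axis.max())) for axis in occupied)
    return AOI(mode="bounding_box", voxel_size=objects.voxel_size, bounds=bounds)  # type: ignore[arg-type]


def vessels_in_aoi(
    stack: VolumetricStack,
    aoi: AOI,
    min_intensity: float,
    min_volume: float,
    connectivity: int = 26,
    role: str = "vessel",
) -> ObjectSet:
    """Detect vessel objects restricted to (clipped at) the AOI.

    Identical algorithm to :func:`threshold_objects`, but voxels outside the
    AOI are masked out *before* component labelling, so objects straddling
    the AOI boundary contribute only their in-AOI voxels.
    """
    channel = stack.channel(role)
    restrict = aoi.as_mask(stack.shape)
    return _label_and_filter(
        channel, stack.voxel_size, min_intensity, min_volume, connectivity, role, restrict
    )
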