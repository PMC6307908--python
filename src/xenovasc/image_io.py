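"""Multichannel stack containers plus TIFF / annotation / metrics I/O.

Conventions
-----------
* Axis order is ``(z, y, x)``, 0-based voxel indices.
* A physical position is the voxel-centre coordinate in µm:
  ``position = (index + 0.5) * voxel_size`` per axis.
* On disk a static stack is a multi-dimensional TIFF with axes ``(C, Z, Y, X)``
  and a time-lapse is ``(T, C, Z, Y, X)``; voxel size and channel roles are
  always supplied explicitly by the caller and override any file metadata.
* Annotations (CCV reference point/axis, per-frame vessel-tip positions,
  analysis window) are a JSON document — the quantities the original study
  supplied by manual selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import (
    AnnotationError,
    ChannelCountMismatchError,
    NonPositiveVoxelSizeError,
    TrajectoryGapError,
    UnknownRoleError,
    ZeroAxisError,
)

ROLES = ("graft", "vessel", "macrophage")


def _validate_voxel_size(voxel_size: Sequence[float]) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise NonPositiveVoxelSizeError(
            f"voxel_size must be three strictly positive values (dz, dy, dx), got {voxel_size!r}"
        )
    return vs  # type: ignore[return-value]


@dataclass
class VolumetricStack:
    """One multichannel 3D intensity grid with anisotropic voxel size.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Nonnegative intensities, one 3D grid per channel.
    channel_roles : mapping of role name to channel index
        Roles are a subset of {'graft', 'vessel', 'macrophage'}; the mapping
        must be injective and every index must exist in ``voxels``.
    voxel_size : (dz, dy, dx) in µm, each > 0.
    """

    voxels: np.ndarray
    channel_roles: Mapping[str, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be (C, Z, Y, X), got shape {self.voxels.shape}")
        self.voxel_size = _validate_voxel_size(self.voxel_size)
        n_channels = self.voxels.shape[0]
        self.channel_roles = dict(self.channel_roles)
        for role, idx in self.channel_roles.items():
            if role not in ROLES:
                raise UnknownRoleError(f"unknown channel role {role!r}; expected one of {ROLES}")
            if not (0 <= int(idx) < n_channels):
                raise ChannelCountMismatchError(
                    f"role {role!r} maps to channel {idx}, but the stack has {n_channels} channel(s)"
                )
        indices = list(self.channel_roles.values())
        if len(set(indices)) != len(indices):
            raise ValueError(f"channel_roles must be injective, got {self.channel_roles!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape (Z, Y, X)."""
        return self.voxels.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid along (z, y, x) in µm."""
        return tuple(n * s for n, s in zip(self.shape, self.voxel_size))  # type: ignore[return-value]

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise UnknownRoleError(
                f"stack declares roles {sorted(self.channel_roles)}, not {role!r}"
            )
        return self.voxels[self.channel_roles[role]]


@dataclass
class TimelapseStack:
    """An ordered sequence of identically shaped VolumetricStack frames."""

    frames: list[VolumetricStack]
    frame_interval: float  # minutes

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a TimelapseStack needs at least one frame")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be strictly positive minutes")
        first = self.frames[0]
        for f in self.frames[1:]:
            if f.shape != first.shape or f.voxel_size != first.voxel_size:
                raise ValueError("all frames must share grid dimensions and voxel size")
            if dict(f.channel_roles) != dict(first.channel_roles):
                raise ValueError("all frames must share channel roles")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        """Acquisition time of each frame in minutes from the first."""
        return np.arange(len(self.frames)) * self.frame_interval


@dataclass
class AnnotationSet:
    """Manually supplied reference geometry: CCV point/axis and tip trajectory.

    ``ccv_axis`` points in the direction of increasing distance from the
    common cardinal vein and is stored unit-normalised. ``tip_trajectory``
    maps frame index to the tip position (z, y, x) in µm and must cover every
    frame of ``analysis_window`` when a window is given.
    """

    ccv_point: np.ndarray
    ccv_axis: np.ndarray
    tip_trajectory: dict[int, np.ndarray] = field(default_factory=dict)
    analysis_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.ccv_point = np.asarray(self.ccv_point, dtype=float).reshape(3)
        axis = np.asarray(self.ccv_axis, dtype=float).reshape(3)
        norm = float(np.linalg.norm(axis))
        if norm < 1e-9:
            raise ZeroAxisError("ccv_axis has (near-)zero length and cannot define a direction")
        self.ccv_axis = axis / norm
        self.tip_trajectory = {
            int(f): np.asarray(p, dtype=float).reshape(3)
            for f, p in sorted(self.tip_trajectory.items())
        }
        if self.analysis_window is not None:
            first, last = (int(v) for v in self.analysis_window)
            if last < first:
                raise AnnotationError(f"analysis_window {self.analysis_window!r} is reversed")
            self.analysis_window = (first, last)
            missing = [f for f in range(first, last + 1) if f not in self.tip_trajectory]
            if missing:
                raise TrajectoryGapError(
                    f"tip trajectory missing frame(s) {missing} inside analysis window "
                    f"({first}, {last})"
                )

    def tip(self, frame: int) -> np.ndarray:
        if frame not in self.tip_trajectory:
            raise TrajectoryGapError(f"no tip position annotated for frame {frame}")
        return self.tip_trajectory[frame]

    @property
    def window_frames(self) -> list[int]:
        if self.analysis_window is None:
            return sorted(self.tip_trajectory)
        first, last = self.analysis_window
        return list(range(first, last + 1))


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(stack: VolumetricStack, path) -> None:
    """Write a stack as a (C, Z, Y, X) TIFF (float32, deterministic bytes)."""
    tifffile.imwrite(
        str(path), np.asarray(stack.voxels, dtype=np.float32), photometric="minisblack"
    )


def read_stack(path, channel_roles: Mapping[str, int], voxel_size) -> VolumetricStack:
    """Read a multichannel TIFF written page-per-slice.

    The grid equals the file's pixel data bit-exactly; geometry metadata
    (voxel size, channel roles) is taken from the explicit arguments, never
    inferred from file headers.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image file: {p}")
    voxel_size = _validate_voxel_size(voxel_size)
    arr = tifffile.imread(str(p))
    if arr.ndim == 3:
        arr = arr[np.newaxis]  # single-channel stack
    if arr.ndim != 4:
        raise ValueError(f"expected a (C, Z, Y, X) or (Z, Y, X) TIFF, got shape {arr.shape}")
    n_channels = arr.shape[0]
    bad = {r: i for r, i in channel_roles.items() if not (0 <= int(i) < n_channels)}
    if bad:
        raise ChannelCountMismatchError(
            f"file has {n_channels} channel(s) but roles {bad!r} point past them"
        )
    return VolumetricStack(arr, channel_roles, voxel_size)


def write_timelapse(tl: TimelapseStack, path) -> None:
    data = np.stack([np.asarray(f.voxels, dtype=np.float32) for f in tl.frames])
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_timelapse(path, channel_roles, voxel_size, frame_interval: float) -> TimelapseStack:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image file: {p}")
    arr = tifffile.imread(str(p))
    if arr.ndim != 5:
        raise ValueError(f"expected a (T, C, Z, Y, X) TIFF, got shape {arr.shape}")
    frames = [VolumetricStack(arr[t], channel_roles, voxel_size) for t in range(arr.shape[0])]
    return TimelapseStack(frames, frame_interval)


# ---------------------------------------------------------------------------
# Annotation I/O (JSON)
#
# Schema:
# {
#   "ccv_point_um": [z, y, x],
#   "ccv_axis":     [z, y, x],
#   "analysis_window": [first_frame, last_frame],   # optional
#   "tips": [{"frame": 0, "z_um": ..., "y_um": ..., "x_um": ...}, ...]
# }


def read_annotations(path) -> AnnotationSet:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such annotation file: {p}")
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"annotation file {p} is not valid JSON: {exc}") from exc
    try:
        point = doc["ccv_point_um"]
        axis = doc["ccv_axis"]
    except KeyError as exc:
        raise AnnotationError(f"annotation file {p} lacks required field {exc}") from exc
    tips = {
        int(row["frame"]): (float(row["z_um"]), float(row["y_um"]), float(row["x_um"]))
        for row in doc.get("tips", [])
    }
    window = doc.get("analysis_window")
    return AnnotationSet(
        ccv_point=point,
        ccv_axis=axis,
        tip_trajectory=tips,
        analysis_window=tuple(window) if window is not None else None,
    )


def write_annotations(annotations: AnnotationSet, path) -> None:
    doc = {
        "ccv_point_um": [float(v) for v in annotations.ccv_point],
        "ccv_axis": [float(v) for v in annotations.ccv_axis],
        "tips": [
            {"frame": f, "z_um": float(p[0]), "y_um": float(p[1]), "x_um": float(p[2])}
            for f, p in sorted(annotations.tip_trajectory.items())
        ],
    }
    if annotations.analysis_window is not None:
        doc["analysis_window"] = list(annotations.analysis_window)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Metric tables (CSV)


def write_metrics(records: Sequence[Mapping], path, fieldnames: Sequence[str] | None = None) -> None:
    """Write metric records as CSV: header row + one record per row.

    Floats are serialised with enough digits that a read-back round-trip is
    exact to well under 1e-6 relative. An empty record list produces a
    header-only file (pass ``fieldnames`` to fix the schema in that case).
    """
    df = pd.DataFrame(list(records), columns=list(fieldnames) if fieldnames else None)
    df.to_csv(path, index=False, float_format="%.12g")


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path)
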