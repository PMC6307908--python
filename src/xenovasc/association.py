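"""Frame-by-frame macrophage scoring at the angiogenic vs control region.

The angiogenic region is a disc of configurable radius (default 10 µm) in
the xy plane, centred on the annotated tip of the growing vessel and
replicated over the optical z-sections occupied by that vessel under the
disc. The control region is a disc of the same radius placed a fixed
distance away (default 25 µm, centre-to-centre) but still within the graft.
A macrophage is scored present in a region only if its centroid falls inside
the disc *and* its object occupies at least one of the region's z-sections —
the same-optical-section co-localisation rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import NoAdmissibleControlError, TipOutOfBoundsError
from .segmentation import ObjectSet

_TOL = 1e-9


@dataclass(frozen=True)
class RegionSpec:
    """A disc-shaped scoring region: xy centre, radius, z-section set."""

    centre_yx: tuple[float, float]  # µm
    radius: float  # µm
    z_slices: frozenset[int]
    kind: Literal["angiogenic", "control"]

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("region radius must be strictly positive")
        if not self.z_slices:
            raise ValueError("region needs at least one z slice")


@dataclass(frozen=True)
class FrameScore:
    """Macrophage presence/count in one region at one frame."""

    frame: int
    region_kind: str
    present: bool
    count: int

    def __post_init__(self) -> None:
        if self.present != (self.count >= 1):
            raise ValueError("present must equal (count >= 1)")


def disc_pixel_mask(
    shape_yx: tuple[int, int],
    voxel_size_yx: tuple[float, float],
    centre_yx: Sequence[float],
    radius: float,
) -> np.ndarray:
    """Boolean (Y, X) mask of pixels whose centre lies within the disc."""
    ny, nx = shape_yx
    dy, dx = voxel_size_yx
    yc = (np.arange(ny) + 0.5) * dy
    xc = (np.arange(nx) + 0.5) * dx
    d2 = (yc[:, None] - centre_yx[0]) ** 2 + (xc[None, :] - centre_yx[1]) ** 2
    return d2 <= radius**2 + _TOL


def angiogenic_region(
    tip_um: Sequence[float],
    vessel_objects: ObjectSet,
    radius: float,
    grid_shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> RegionSpec:
    """Scoring disc centred on the vessel tip.

    The region's z-sections are those occupied — within the disc footprint —
    by the vessel object nearest the tip; if no vessel voxel falls under the
    disc, the tip's own z-section is used.
    """
    tip = np.asarray(tip_um, dtype=float).reshape(3)
    extent = np.array(grid_shape) * np.array(voxel_size)
    if np.any(tip < -_TOL) or np.any(tip > extent + _TOL):
        raise TipOutOfBoundsError(f"tip {tip.tolist()} outside volume extent {extent.tolist()}")
    dz = voxel_size[0]
    tip_z_index = max(0, min(int(tip[0] / dz), grid_shape[0] - 1))

    foot = disc_pixel_mask(grid_shape[1:], voxel_size[1:], tip[1:], radius)
    in_disc = (vessel_objects.labels > 0) & foot[np.newaxis, :, :]
    vox = np.argwhere(in_disc)
    if vox.shape[0] == 0:
        return RegionSpec((float(tip[1]), float(tip[2])), radius, frozenset({tip_z_index}), "angiogenic")

    pos = (vox + 0.5) * np.asarray(voxel_size)
    dist = np.linalg.norm(pos - tip, axis=1)
    labels_here = vessel_objects.labels[tuple(vox.T)]
    # nearest object: minimal distance over its in-disc voxels; ties -> smallest id
    best_label, best_dist = None, math.inf
    for lab in np.unique(labels_here):
        d = float(dist[labels_here == lab].min())
        if d < best_dist - _TOL or (abs(d - best_dist) <= _TOL and (best_label is None or lab < best_label)):
            best_label, best_dist = int(lab), d
    z_slices = frozenset(np.unique(vox[labels_here == best_label, 0]).tolist())
    return RegionSpec((float(tip[1]), float(tip[2])), radius, z_slices, "angiogenic")


def place_control_region(
    angio: RegionSpec,
    graft_mask: np.ndarray,
    vessel_mask: np.ndarray,
    offset: float,
    voxel_size: tuple[float, float, float],
    offset_mode: str = "centre",
    angle_step_deg: int = 15,
) -> RegionSpec:
    """Deterministic placement of the matched control disc.

    Candidate centres sit at the offset distance from the angiogenic centre,
    at angles 0°, 15°, ..., 345° in the xy plane. A candidate is admissible
    iff its whole disc lies within the graft's xy footprint on the region's
    z-sections; among admissible candidates the one farthest from any vessel
    voxel (on those sections) wins, ties going to the smallest angle.
    """
    if not offset > 0:
        raise ValueError("control offset must be strictly positive")
    centre_dist = offset if offset_mode == "centre" else offset + 2.0 * angio.radius
    dy, dx = voxel_size[1], voxel_size[2]
    zs = sorted(angio.z_slices)
    footprint = np.asarray(graft_mask, dtype=bool)[zs].any(axis=0)
    ny, nx = footprint.shape
    extent_y, extent_x = ny * dy, nx * dx

    vessel_yx = np.argwhere(np.asarray(vessel_mask, dtype=bool)[zs].any(axis=0))
    vessel_pos = (vessel_yx + 0.5) * np.array([dy, dx]) if vessel_yx.size else None

    best: tuple[float, int, tuple[float, float]] | None = None  # (score, angle, centre)
    for angle in range(0, 360, angle_step_deg):
        theta = math.radians(angle)
        cy = angio.centre_yx[0] + centre_dist * math.sin(theta)
        cx = angio.centre_yx[1] + centre_dist * math.cos(theta)
        if (
            cy - angio.radius < -_TOL
            or cx - angio.radius < -_TOL
            or cy + angio.radius > extent_y + _TOL
            or cx + angio.radius > extent_x + _TOL
        ):
            continue  # disc extends beyond the imaged field
        disc = disc_pixel_mask((ny, nx), (dy, dx), (cy, cx), angio.radius)
        if not footprint[disc].all():
            continue  # disc leaves the graft footprint
        if vessel_pos is None:
            score = math.inf
        else:
            score = float(
                np.min(np.hypot(vessel_pos[:, 0] - cy, vessel_pos[:, 1] - cx))
            )
        if best is None or score > best[0] + _TOL:
            best = (score, angle, (cy, cx))
    if best is None:
        raise NoAdmissibleControlError(
            f"no control disc of radius {angio.radius} µm fits in the graft at offset "
            f"{offset} µm; use a larger graft or a smaller offset/radius"
        )
    return RegionSpec(best[2], angio.radius, angio.z_slices, "control")


def score_frame(
    macrophage_objects: ObjectSet,
    region: RegionSpec,
    frame: int = 0,
) -> FrameScore:
    """Count macrophages present in the region at one frame.

    A macrophage counts iff its centroid's (y, x) lies within the disc
    (distance <= radius, inclusive) and its object occupies at least one of
    the region's z-sections.
    """
    count = 0
    for k in range(1, len(macrophage_objects) + 1):
        cy, cx = macrophage_objects.centroids[k - 1][1:]
        d = math.hypot(cy - region.centre_yx[0], cx - region.centre_yx[1])
        if d <= region.radius + _TOL and macrophage_objects.z_slices(k) & region.z_slices:
            count += 1
    return FrameScore(frame=frame, region_kind=region.kind, present=count >= 1, count=count)


def association_summary(scores: Iterable[FrameScore]) -> dict[str, dict[str, float]]:
    """Per-region-kind summary: % frames with a macrophage, mean count/frame."""
    by_kind: dict[str, list[FrameScore]] = {}
    for s in scores:
        by_kind.setdefault(s.region_kind, []).append(s)
    if not by_kind:
        raise ValueError("no frame scores to summarise")
    out = {}
    for kind, ss in by_kind.items():
        n = len(ss)
        out[kind] = {
            "n_frames": n,
            "percent_frames_present": 100.0 * sum(s.present for s in ss) / n,
            "mean_count_per_frame": float(np.mean([s.count for s in ss])),
        }
    return out
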