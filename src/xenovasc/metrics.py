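"""Graft vascularisation metrics, macrophage counts, secretion index.

The headline quantity is percentage graft vascularisation: total vessel
object volume inside the graft area of interest, divided by total graft
object volume, × 100. The regional breakdown splits the graft into three
equal-volume sections — proximal, middle, distal — ordered by projection
onto the CCV axis, and reports the vascularised percentage of each section.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyGraftError
from .image_io import AnnotationSet
from .segmentation import AOI, ObjectSet


@dataclass
class GraftMetrics:
    """Per-graft quantitation record."""

    graft_volume: float  # µm³
    vessel_volume: float  # µm³
    percent_vascularisation: float  # %
    region_percent: tuple[float, float, float] | None = None  # (proximal, middle, distal)
    macrophage_count: int | None = None
    macrophages_per_volume: float | None = None  # per norm_volume µm³

    def as_record(self, **extra) -> dict:
        rec = {
            "graft_volume_um3": self.graft_volume,
            "vessel_volume_um3": self.vessel_volume,
            "percent_vascularisation": self.percent_vascularisation,
        }
        if self.region_percent is not None:
            rec["percent_proximal"], rec["percent_middle"], rec["percent_distal"] = (
                self.region_percent
            )
        if self.macrophage_count is not None:
            rec["macrophage_count"] = self.macrophage_count
            rec["macrophages_per_volume"] = self.macrophages_per_volume
        rec.update(extra)
        return rec


@dataclass
class RegionalBreakdown:
    """Equal-volume tripartition of the graft along the CCV axis.

    ``region_labels`` marks each graft voxel 1 (proximal), 2 (middle) or
    3 (distal); 0 is non-graft. Percentages are per-region vessel volume over
    per-region graft volume, × 100.
    """

    percent: tuple[float, float, float]
    graft_volumes: tuple[float, float, float]  # µm³ per region
    vessel_volumes: tuple[float, float, float]
    region_labels: np.ndarray


@dataclass
class SecretionRecord:
    """VEGFA secretion normalised to total protein content."""

    vegfa_concentration: float  # pg/ml
    total_protein: float  # µg
    secretion_index: float

    @classmethod
    def from_measurements(cls, vegfa: float, protein: float) -> "SecretionRecord":
        return cls(vegfa, protein, secretion_index(vegfa, protein))


def percent_vascularisation(graft: ObjectSet, vessels: ObjectSet) -> GraftMetrics:
    """Total vessel volume over total graft volume, as a percentage.

    With a bounding-box AOI the vessel volume can in principle exceed the
    graft volume (vessels in box corners outside the graft mask); such values
    are reported as > 100% with a warning, never clipped.
    """
    if graft.is_empty:
        raise EmptyGraftError("no graft objects detected; vascularisation undefined")
    graft_volume = graft.total_volume
    vessel_volume = vessels.total_volume
    percent = 100.0 * vessel_volume / graft_volume
    if percent > 100.0:
        warnings.warn(
            f"vessel volume exceeds graft volume ({percent:.1f}%); this can happen with a "
            "bounding-box AOI — consider aoi_mode='mask'",
            stacklevel=2,
        )
    return GraftMetrics(graft_volume, vessel_volume, percent)


def _partition_sizes(n: int) -> tuple[int, int, int]:
    """Split n voxels into three runs differing by <= 1, remainder proximal-first."""
    base, r = divmod(n, 3)
    return (base + (1 if r >= 1 else 0), base + (1 if r >= 2 else 0), base)


def regional_vascularisation(
    graft_mask: np.ndarray,
    vessel_mask: np.ndarray,
    annotations: AnnotationSet,
    voxel_size,
    mode: str = "axis",
    partition: str = "volume",
) -> RegionalBreakdown:
    """Vascularised percentage of the proximal, middle and distal graft thirds.

    Each graft voxel gets a scalar coordinate ``s``: for ``mode='axis'`` the
    projection of its centre onto the CCV axis relative to the CCV point; for
    ``mode='radial'`` the Euclidean distance from the CCV point. Voxels are
    sorted ascending by ``s`` (ties by z, y, x index) and cut into three
    consecutive runs. ``partition='volume'`` makes the runs equal-sized to
    within one voxel (remainder voxels going to the proximal-most regions);
    ``partition='length'`` instead cuts the ``s`` range into three equal
    intervals. Vessel voxels inside the graft mask inherit the region of
    their voxel; vessel voxels outside the graft mask are ignored here.
    """
    graft_mask = np.asarray(graft_mask, dtype=bool)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if graft_mask.shape != vessel_mask.shape:
        raise ValueError("graft and vessel masks must share geometry")
    idx = np.argwhere(graft_mask)
    if idx.shape[0] == 0:
        raise EmptyGraftError("empty graft mask; regional partition undefined")
    vs = np.asarray(voxel_size, dtype=float)
    pos = (idx + 0.5) * vs
    if mode == "axis":
        s = (pos - annotations.ccv_point) @ annotations.ccv_axis
    elif mode == "radial":
        s = np.linalg.norm(pos - annotations.ccv_point, axis=1)
    else:
        raise ValueError(f"unknown regional mode {mode!r}")

    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], s))
    n = idx.shape[0]
    region_of_sorted = np.empty(n, dtype=np.int8)
    if partition == "volume":
        n1, n2, _ = _partition_sizes(n)
        region_of_sorted[:n1] = 1
        region_of_sorted[n1 : n1 + n2] = 2
        region_of_sorted[n1 + n2 :] = 3
    elif partition == "length":
        s_sorted = s[order]
        lo, hi = s_sorted[0], s_sorted[-1]
        if hi == lo:
            region_of_sorted[:] = 1
        else:
            frac = (s_sorted - lo) / (hi - lo)
            region_of_sorted = np.minimum((frac * 3).astype(np.int8), 2) + 1
    else:
        raise ValueError(f"unknown partition rule {partition!r}")

    region_labels = np.zeros(graft_mask.shape, dtype=np.int8)
    region_labels[tuple(idx[order].T)] = region_of_sorted

    voxel_volume = float(np.prod(vs))
    vessel_in_graft = vessel_mask & graft_mask
    graft_volumes = []
    vessel_volumes = []
    percent = []
    for r in (1, 2, 3):
        in_region = region_labels == r
        gv = int(in_region.sum()) * voxel_volume
        vv = int((in_region & vessel_in_graft).sum()) * voxel_volume
        graft_volumes.append(gv)
        vessel_volumes.append(vv)
        percent.append(100.0 * vv / gv if gv > 0 else float("nan"))
    return RegionalBreakdown(
        percent=tuple(percent),  # type: ignore[arg-type]
        graft_volumes=tuple(graft_volumes),  # type: ignore[arg-type]
        vessel_volumes=tuple(vessel_volumes),  # type: ignore[arg-type]
        region_labels=region_labels,
    )


def count_macrophages(
    macrophage_objects: ObjectSet,
    graft_aoi: AOI,
    graft_volume: float,
    norm_volume: float = 1e5,
) -> tuple[int, float]:
    """Graft-associated macrophage count and its per-volume normalisation.

    A macrophage is graft-associated iff its centroid lies inside the AOI
    (boundary faces inclusive). The normalised value is
    ``count × norm_volume / graft_volume`` — by default counts per 10⁵ µm³.
    """
    if not graft_volume > 0:
        raise EmptyGraftError("graft volume must be positive to normalise macrophage counts")
    count = sum(
        1 for centroid in macrophage_objects.centroids if graft_aoi.contains_point(centroid)
    )
    return count, count * norm_volume / graft_volume


def secretion_index(vegfa_concentration: float, total_protein: float) -> float:
    """VEGFA secretion divided by total protein content.

    Replicates are normalised per well and then averaged — the mean of two
    per-well indices equals the index of mean measurements only when the
    protein contents are equal.
    """
    if not total_protein > 0:
        raise ValueError(f"total protein must be strictly positive, got {total_protein!r}")
    return vegfa_concentration / total_protein


def mean_secretion_index(pairs) -> float:
    """Mean of per-well secretion indices over (vegfa, protein) pairs."""
    indices = [secretion_index(v, p) for v, p in pairs]
    if not indices:
        raise ValueError("need at least one (vegfa, protein) pair")
    return float(np.mean(indices))
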