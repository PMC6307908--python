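"""End-to-end analyses: static vascularisation and time-lapse association.

These functions chain segmentation, metric computation and scoring for one
input at a time; the CLI wraps them with file I/O. Everything is
deterministic given inputs and configuration, and every output record
carries the configuration fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import tracks as trk
from .config import AnalysisConfig
from .image_io import AnnotationSet, TimelapseStack, VolumetricStack
from .metrics import GraftMetrics, count_macrophages, percent_vascularisation, regional_vascularisation
from .segmentation import build_aoi, threshold_objects, vessels_in_aoi


@dataclass
class StaticResult:
    metrics: GraftMetrics
    config_fingerprint: str

    def as_record(self, **extra) -> dict:
        return self.metrics.as_record(config_fingerprint=self.config_fingerprint, **extra)


@dataclass
class TimelapseResult:
    frame_scores: list[assoc.FrameScore]
    summary: dict
    tracks: list[trk.Track]
    intervals: list[trk.ContactInterval]
    speed_comparisons: list[trk.SpeedComparison]
    config_fingerprint: str
    control_centres: dict[int, tuple[float, float]] = field(default_factory=dict)

    def frames_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "frame": s.frame,
                    "region": s.region_kind,
                    "present": int(s.present),
                    "count": s.count,
                    "config_fingerprint": self.config_fingerprint,
                }
                for s in self.frame_scores
            ]
        )

    def intervals_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "track_id": iv.track_id,
                    "tip_id": iv.tip_id,
                    "start_frame": iv.start_frame,
                    "end_frame": iv.end_frame,
                    "duration_min": iv.duration,
                    "is_tipcell": int(iv.is_tipcell),
                    "config_fingerprint": self.config_fingerprint,
                }
                for iv in self.intervals
            ],
            columns=[
                "track_id",
                "tip_id",
                "start_frame",
                "end_frame",
                "duration_min",
                "is_tipcell",
                "config_fingerprint",
            ],
        )

    def speeds_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "track_id": sc.track_id,
                    "speed_during_um_per_min": sc.speed_during,
                    "speed_after_um_per_min": sc.speed_after,
                    "window_min": sc.window,
                    "config_fingerprint": self.config_fingerprint,
                }
                for sc in self.speed_comparisons
            ],
            columns=[
                "track_id",
                "speed_during_um_per_min",
                "speed_after_um_per_min",
                "window_min",
                "config_fingerprint",
            ],
        )


def analyse_static(
    stack: VolumetricStack,
    config: AnalysisConfig = AnalysisConfig(),
    annotations: AnnotationSet | None = None,
) -> StaticResult:
    """Graft volume, vessel volume, % vascularisation, optional extras.

    Regional percentages are computed when annotations (CCV point/axis) are
    supplied; macrophage counts when the stack declares a macrophage channel.
    """
    graft = threshold_objects(
        stack, "graft", config.graft_min_intensity, config.graft_min_volume, config.connectivity
    )
    aoi = build_aoi(graft, config.aoi_mode)
    vessels = vessels_in_aoi(
        stack, aoi, config.vessel_min_intensity, config.vessel_min_volume, config.connectivity
    )
    metrics = percent_vascularisation(graft, vessels)

    if annotations is not None:
        breakdown = regional_vascularisation(
            graft.mask(), vessels.mask(), annotations, stack.voxel_size
        )
        metrics.region_percent = breakdown.percent

    if "macrophage" in stack.channel_roles:
        macrophages = threshold_objects(
            stack,
            "macrophage",
            config.macrophage_min_intensity,
            config.macrophage_min_volume,
            config.connectivity,
        )
        count, per_vol = count_macrophages(
            macrophages, aoi, metrics.graft_volume, config.macrophage_norm_volume
        )
        metrics.macrophage_count = count
        metrics.macrophages_per_volume = per_vol

    return StaticResult(metrics, config.fingerprint())


def analyse_timelapse(
    timelapse: TimelapseStack,
    annotations: AnnotationSet,
    config: AnalysisConfig = AnalysisConfig(),
    link_max_step: float | None = None,
) -> TimelapseResult:
    """Score angiogenic vs control regions per frame and analyse tracks.

    For each frame in the analysis window: segment vessels and macrophages,
    centre the angiogenic disc on the annotated tip, place the control disc,
    and score macrophage presence in both. Macrophage detections are then
    linked into tracks, classified by tip-contact duration, and compared for
    during- vs after-contact migration speed.
    """
    frames = annotations.window_frames
    if not frames:
        raise ValueError("annotations carry no tip positions to analyse")
    first = frames[0]
    voxel_size = timelapse.frames[0].voxel_size

    scores: list[assoc.FrameScore] = []
    detections: list[np.ndarray] = []
    control_centres: dict[int, tuple[float, float]] = {}
    if frames[-1] >= len(timelapse.frames):
        raise ValueError(
            f"analysis window extends to frame {frames[-1]} but the movie has "
            f"{len(timelapse.frames)} frames"
        )
    for f in frames:
        stack = timelapse.frames[f]
        vessels = threshold_objects(
            stack, "vessel", config.vessel_min_intensity, config.vessel_min_volume, config.connectivity
        )
        macrophages = threshold_objects(
            stack,
            "macrophage",
            config.macrophage_min_intensity,
            config.macrophage_min_volume,
            config.connectivity,
        )
        graft_mask = stack.channel("graft") >= config.graft_min_intensity
        angio = assoc.angiogenic_region(
            annotations.tip(f), vessels, config.angiogenic_radius, stack.shape, voxel_size
        )
        control = assoc.place_control_region(
            angio,
            graft_mask,
            vessels.mask(),
            config.control_offset,
            voxel_size,
            offset_mode=config.control_offset_mode,
        )
        control_centres[f] = control.centre_yx
        scores.append(assoc.score_frame(macrophages, angio, frame=f))
        scores.append(assoc.score_frame(macrophages, control, frame=f))
        detections.append(macrophages.centroids)

    summary = assoc.association_summary(scores)

    if link_max_step is None:
        # generous default: a macrophage rarely travels farther than the
        # control offset within one frame
        link_max_step = config.control_offset
    tracks = trk.link_tracks(detections, max_step=link_max_step, first_frame=first)

    tip_traj = {f: annotations.tip(f) for f in frames}
    intervals: list[trk.ContactInterval] = []
    speed_comparisons: list[trk.SpeedComparison] = []
    for track in tracks:
        if not any(int(f) in tip_traj for f in track.frames):
            continue
        ivs = trk.contact_intervals(
            track,
            tip_traj,
            contact_radius=config.effective_contact_radius,
            frame_interval=timelapse.frame_interval,
            tipcell_min_duration=config.tipcell_min_duration,
        )
        intervals.extend(ivs)
        for iv in ivs:
            if iv.is_tipcell and track.last_frame > iv.end_frame:
                speed_comparisons.append(
                    trk.speed_comparison(track, iv, timelapse.frame_interval)
                )

    tipcell_tracks = {iv.track_id for iv in intervals if iv.is_tipcell}
    summary["tipcell"] = {
        "n_tracks": len(tracks),
        "n_tipcell_tracks": len(tipcell_tracks),
        "mean_tipcell_duration_min": (
            float(np.mean([iv.duration for iv in intervals if iv.is_tipcell]))
            if tipcell_tracks
            else float("nan")
        ),
    }
    return TimelapseResult(
        frame_scores=scores,
        summary=summary,
        tracks=tracks,
        intervals=intervals,
        speed_comparisons=speed_comparisons,
        config_fingerprint=config.fingerprint(),
        control_centres=control_centres,
    )
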