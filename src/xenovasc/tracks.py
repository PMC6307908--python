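"""Macrophage track building, tip-contact classification, speed comparison.

A tip-cell macrophage is one that stays within the contact radius of a
growing vessel's distal tip for at least 40 min. Contact duration is the
time *spanned* by a maximal run of consecutive contact frames:
``(run length - 1) × frame interval`` — a single-frame sighting spans 0 min,
and at the study's 10-min cadence a ≥ 40 min contact needs five consecutive
contact frames. Migration speed is compared between the contact window and
an equally long window immediately after contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import NoTipCellTracksError, ZeroWindowError

_FORBIDDEN = 1e12


@dataclass
class Track:
    """A gap-free time-indexed sequence of one macrophage's centroids (µm)."""

    track_id: int
    frames: np.ndarray  # (T,) consecutive ints
    points: np.ndarray  # (T, 3) µm, (z, y, x)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.points = np.asarray(self.points, dtype=float).reshape(len(self.frames), 3)
        if len(self.frames) == 0:
            raise ValueError("a track needs at least one point")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("track frames must be strictly increasing and consecutive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    def point_at(self, frame: int) -> np.ndarray:
        return self.points[frame - self.first_frame]


@dataclass
class ContactInterval:
    """One maximal run of consecutive frames in contact with a vessel tip."""

    track_id: int
    tip_id: int
    start_frame: int
    end_frame: int
    duration: float  # minutes spanned
    is_tipcell: bool


@dataclass
class SpeedComparison:
    """Migration speed during vs immediately after one tip contact."""

    track_id: int
    speed_during: float  # µm/min
    speed_after: float  # µm/min
    window: float  # minutes (identical for both speeds)


def link_tracks(
    detections: Sequence[np.ndarray],
    max_step: float,
    first_frame: int = 0,
) -> list[Track]:
    """Frame-to-frame nearest-neighbour linking by optimal assignment.

    ``detections[t]`` is an (M_t, 3) array of centroids (µm) at frame
    ``first_frame + t``. Each consecutive frame pair is matched by the
    assignment minimising total displacement (exact Hungarian solution),
    with links longer than ``max_step`` µm forbidden. Unmatched detections
    start new tracks; a track that finds no match ends (no gap closing).
    Deterministic: ties are resolved by the solver's fixed ordering and new
    track ids follow detection order.
    """
    if not max_step > 0:
        raise ValueError("max_step must be strictly positive")
    tracks: list[dict] = []
    active: list[int] = []  # indices into tracks
    next_id = 0
    for t, det in enumerate(detections):
        det = np.asarray(det, dtype=float).reshape(-1, 3)
        frame = first_frame + t
        matched_det = set()
        if active and det.shape[0]:
            last_pts = np.array([tracks[i]["points"][-1] for i in active])
            cost = np.linalg.norm(last_pts[:, None, :] - det[None, :, :], axis=2)
            cost = np.where(cost <= max_step, cost, _FORBIDDEN)
            rows, cols = linear_sum_assignment(cost)
            still_active = set()
            for r, c in zip(rows, cols):
                if cost[r, c] < _FORBIDDEN:
                    tracks[active[r]]["points"].append(det[c])
                    tracks[active[r]]["frames"].append(frame)
                    matched_det.add(int(c))
                    still_active.add(active[r])
            active = [i for i in active if i in still_active]
        else:
            active = []
        for c in range(det.shape[0]):
            if c not in matched_det:
                tracks.append({"id": next_id, "frames": [frame], "points": [det[c]]})
                active.append(len(tracks) - 1)
                next_id += 1
    return [
        Track(tr["id"], np.array(tr["frames"]), np.array(tr["points"])) for tr in tracks
    ]


def contact_intervals(
    track: Track,
    tip_trajectory: Mapping[int, np.ndarray],
    contact_radius: float = 10.0,
    frame_interval: float = 10.0,
    tipcell_min_duration: float = 40.0,
    tip_id: int = 0,
) -> list[ContactInterval]:
    """Maximal runs of consecutive frames within the contact radius of a tip.

    Contact at a frame means the 3D distance between the track point and the
    tip position is <= ``contact_radius`` (inclusive). Frames where the tip
    is not annotated are non-contact. ``duration`` is the spanned time
    ``(run length - 1) × frame_interval``; an interval is tip-cell when
    duration >= ``tipcell_min_duration`` (inclusive).
    """
    overlap = [f for f in track.frames if int(f) in tip_trajectory]
    if not overlap:
        raise ValueError("track and tip trajectory share no frames")
    intervals: list[ContactInterval] = []
    run_start: int | None = None
    prev_contact_frame: int | None = None

    def close_run(last: int) -> None:
        duration = (last - run_start) * frame_interval  # type: ignore[operator]
        intervals.append(
            ContactInterval(
                track_id=track.track_id,
                tip_id=tip_id,
                start_frame=run_start,  # type: ignore[arg-type]
                end_frame=last,
                duration=duration,
                is_tipcell=duration >= tipcell_min_duration,
            )
        )

    for frame, point in zip(track.frames, track.points):
        f = int(frame)
        tip = tip_trajectory.get(f)
        in_contact = tip is not None and float(
            np.linalg.norm(point - np.asarray(tip, dtype=float))
        ) <= contact_radius + 1e-9
        if in_contact:
            if run_start is None:
                run_start = f
            prev_contact_frame = f
        elif run_start is not None:
            close_run(prev_contact_frame)  # type: ignore[arg-type]
            run_start = None
    if run_start is not None:
        close_run(prev_contact_frame)  # type: ignore[arg-type]
    return intervals


def speed_comparison(
    track: Track,
    interval: ContactInterval,
    frame_interval: float = 10.0,
) -> SpeedComparison:
    """Path-length speed during contact vs an equal window after contact.

    The during-window is [start_frame, end_frame]; the after-window the same
    number of frames immediately following. If the track ends early, both
    windows are truncated equally (the during-window keeping its tail, i.e.
    the frames nearest the contact end) so the comparison stays matched.
    """
    k = interval.end_frame - interval.start_frame
    avail_after = track.last_frame - interval.end_frame
    k_eff = min(k, avail_after)
    if k_eff <= 0:
        raise ZeroWindowError(
            "speed comparison needs a positive-length window on both sides of contact end"
        )

    def path_speed(f0: int, f1: int) -> float:
        i0 = f0 - track.first_frame
        i1 = f1 - track.first_frame
        steps = np.diff(track.points[i0 : i1 + 1], axis=0)
        return float(np.linalg.norm(steps, axis=1).sum()) / ((f1 - f0) * frame_interval)

    during = path_speed(interval.end_frame - k_eff, interval.end_frame)
    after = path_speed(interval.end_frame, interval.end_frame + k_eff)
    return SpeedComparison(track.track_id, during, after, k_eff * frame_interval)


def revisit_fraction(intervals: Sequence[ContactInterval]) -> float:
    """Fraction of tip-cell macrophages contacting >= 2 distinct vessel tips.

    A track is a tip-cell macrophage if any of its intervals is tip-cell;
    it counts as a revisitor if its tip-cell intervals touch at least two
    distinct tip identities.
    """
    tipcell_tips: dict[int, set[int]] = {}
    for iv in intervals:
        if iv.is_tipcell:
            tipcell_tips.setdefault(iv.track_id, set()).add(iv.tip_id)
    if not tipcell_tips:
        raise NoTipCellTracksError("no tip-cell tracks; revisit fraction undefined")
    multi = sum(1 for tips in tipcell_tips.values() if len(tips) >= 2)
    return multi / len(tipcell_tips)
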