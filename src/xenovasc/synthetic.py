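"""Synthetic xenograft image generator with exact ground truth.

Emulates the study's imaging conditions so every pipeline stage can be
tested against known truth without any acquired data:

* a static multichannel confocal z-stack (5-µm optical sections) holding an
  ellipsoidal graft, tubular vessels sprouting from the common-cardinal-vein
  (CCV) side, and point-like macrophages;
* a time-lapse (8-µm sections, 10-min frames) in which one designated vessel
  elongates frame by frame while macrophages perform a random walk inside
  the graft, stochastically pausing ("dwelling") at the vessel tip — the
  behaviour whose quantification defines tip-cell macrophages.

Everything is deterministic under a fixed seed. The realised vascular
fraction, macrophage tracks, and dwell events are recorded exactly in
:class:`GroundTruth`.

Geometry is deliberately minimal (ellipsoid + capsules + spheres): enough to
exercise AOI construction, regional partitioning and tip tracking, with no
claim to morphological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .exceptions import UnreachableFractionError
from .image_io import AnnotationSet, TimelapseStack, VolumetricStack

CHANNEL_ROLES = {"graft": 0, "vessel": 1, "macrophage": 2}


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the generator; defaults mirror the study conditions.

    Static stacks use 5-µm z-sections, time-lapse 8-µm sections at 10-min
    frames (the acquisition settings of the original experiments); the xy
    pixel defaults to 0.6 µm, a typical confocal sampling the original study
    does not state. Intensities (graft 1000, vessel 800, macrophage 600,
    arbitrary detector units) sit well above the 250/100-unit detection
    thresholds by construction, so the clean preset is exactly recoverable.
    """

    shape: tuple[int, int, int] = (24, 96, 96)  # (Z, Y, X) voxels
    voxel_size: tuple[float, float, float] = (5.0, 0.6, 0.6)  # µm
    # graft
    graft_centre_um: tuple[float, float, float] | None = None  # default: grid centre
    graft_semiaxes_um: tuple[float, float, float] = (40.0, 20.0, 20.0)
    graft_intensity: float = 1000.0
    # CCV reference: plane x = 0, distance increasing along +x
    # vessels
    n_vessels: int = 3
    vessel_radius_um: float = 4.0
    vessel_intensity: float = 800.0
    target_vessel_fraction: float = 0.25
    # macrophages
    n_macrophages: int = 8
    macrophage_radius_um: float = 5.0
    macrophage_intensity: float = 600.0
    # noise
    noise_sigma_frac: float = 0.0  # additive Gaussian, fraction of each channel's intensity
    poisson_noise: bool = False
    # time-lapse dynamics
    n_frames: int = 24
    frame_interval: float = 10.0  # minutes
    elongation_um_per_frame: float = 1.0
    sigma_free_um: float = 1.5  # per-axis step s.d. of the free random walk, µm/frame
    sigma_dwell_um: float = 0.2  # per-axis jitter while dwelling, µm/frame
    dwell_prob: float = 0.75  # per-frame capture probability within the capture radius
    capture_radius_um: float = 15.0
    dwell_duration_min: float = 70.0  # motivated by the ~1 h contacts seen in vivo
    n_initial_dwellers: int = 1  # macrophages that begin the movie in a dwell
    persistence: float = 0.4  # AR(1) velocity memory of the free walk; 0 = memoryless

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size) or any(n <= 0 for n in self.shape):
            raise ValueError("grid dims and voxel size must be strictly positive")
        if any(a <= 0 for a in self.graft_semiaxes_um):
            raise ValueError("graft semi-axes must be strictly positive")
        if self.sigma_dwell_um > self.sigma_free_um:
            raise ValueError("sigma_dwell must not exceed sigma_free")
        if not 0.0 <= self.dwell_prob <= 1.0:
            raise ValueError("dwell_prob must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def centre_um(self) -> np.ndarray:
        if self.graft_centre_um is not None:
            return np.asarray(self.graft_centre_um, dtype=float)
        return 0.5 * np.array(self.shape) * np.array(self.voxel_size)


def timelapse_params(**overrides) -> GeneratorParams:
    """Defaults for time-lapse generation: 8-µm sections, wider xy field."""
    base = dict(
        shape=(10, 144, 144),
        voxel_size=(8.0, 0.6, 0.6),
        graft_semiaxes_um=(32.0, 38.0, 38.0),
        n_macrophages=5,
    )
    base.update(overrides)
    return GeneratorParams(**base)


def preset_params(name: str, mode: Literal["static", "timelapse"] = "static", **overrides) -> GeneratorParams:
    """Named presets: ``clean`` (no noise), ``noisy`` (5% Gaussian),
    ``null-dwell`` (time-lapse with no tip-dwelling behaviour)."""
    make = timelapse_params if mode == "timelapse" else GeneratorParams
    if name == "clean":
        return make(**overrides)
    if name == "noisy":
        overrides.setdefault("noise_sigma_frac", 0.05)
        return make(**overrides)
    if name == "null-dwell":
        if mode != "timelapse":
            raise ValueError("the null-dwell preset is a time-lapse preset")
        overrides.setdefault("dwell_prob", 0.0)
        overrides.setdefault("n_initial_dwellers", 0)
        # memoryless walk: Metropolis rejection makes the uniform distribution
        # on the graft exactly stationary, so this preset is a true null
        overrides.setdefault("persistence", 0.0)
        return make(**overrides)
    raise ValueError(f"unknown preset {name!r}; expected clean, noisy or null-dwell")


@dataclass
class DwellEvent:
    track_id: int
    tip_id: int
    start_frame: int
    end_frame: int  # last dwelling frame, inclusive


@dataclass
class GroundTruth:
    """Exact record of everything the generator planted."""

    graft_volume_um3: float
    graft_voxel_count: int
    vessel_fraction: float  # realised vessel-in-graft volume fraction
    vessel_volume_um3: float
    region_vessel_fractions: tuple[float, float, float] | None
    graft_mask: np.ndarray
    vessel_mask: np.ndarray
    ccv_point_um: np.ndarray
    ccv_axis: np.ndarray
    macrophage_positions_um: np.ndarray | None = None  # static: (M, 3)
    tracks_um: np.ndarray | None = None  # time-lapse: (M, T, 3)
    tip_trajectory_um: dict[int, np.ndarray] | None = None
    dwell_events: list[DwellEvent] = field(default_factory=list)
    frame_interval: float | None = None

    def annotations(self) -> AnnotationSet:
        """AnnotationSet equivalent to what a user would supply manually."""
        tips = self.tip_trajectory_um or {}
        window = (min(tips), max(tips)) if tips else None
        return AnnotationSet(
            ccv_point=self.ccv_point_um,
            ccv_axis=self.ccv_axis,
            tip_trajectory=tips,
            analysis_window=window,
        )


# ---------------------------------------------------------------------------
# geometry helpers


def _voxel_centres(params: GeneratorParams):
    vs = np.array(params.voxel_size)
    z = (np.arange(params.shape[0]) + 0.5) * vs[0]
    y = (np.arange(params.shape[1]) + 0.5) * vs[1]
    x = (np.arange(params.shape[2]) + 0.5) * vs[2]
    return z, y, x


def _graft_mask(params: GeneratorParams) -> np.ndarray:
    z, y, x = _voxel_centres(params)
    cz, cy, cx = params.centre_um
    az, ay, ax = params.graft_semiaxes_um
    return (
        ((z[:, None, None] - cz) / az) ** 2
        + ((y[None, :, None] - cy) / ay) ** 2
        + ((x[None, None, :] - cx) / ax) ** 2
    ) <= 1.0


def _inside_ellipsoid(p: np.ndarray, params: GeneratorParams) -> bool:
    rel = (p - params.centre_um) / np.asarray(params.graft_semiaxes_um)
    return float(rel @ rel) <= 1.0


def _sample_in_graft(rng: np.random.Generator, params: GeneratorParams) -> np.ndarray:
    centre = params.centre_um
    semi = np.asarray(params.graft_semiaxes_um)
    for _ in range(10_000):
        p = centre + semi * rng.uniform(-1.0, 1.0, 3)
        if _inside_ellipsoid(p, params):
            return p
    raise RuntimeError("rejection sampling failed; degenerate graft geometry")


def _render_sphere(channel: np.ndarray, params: GeneratorParams, centre_um, radius: float, intensity: float) -> None:
    """Set voxels whose centre lies within the sphere; additive-free (max)."""
    vs = np.array(params.voxel_size)
    lo = np.maximum(((np.asarray(centre_um) - radius) / vs).astype(int), 0)
    hi = np.minimum(((np.asarray(centre_um) + radius) / vs).astype(int) + 1, params.shape)
    if np.any(lo >= hi):
        return
    zz = (np.arange(lo[0], hi[0]) + 0.5) * vs[0]
    yy = (np.arange(lo[1], hi[1]) + 0.5) * vs[1]
    xx = (np.arange(lo[2], hi[2]) + 0.5) * vs[2]
    d2 = (
        (zz[:, None, None] - centre_um[0]) ** 2
        + (yy[None, :, None] - centre_um[1]) ** 2
        + (xx[None, None, :] - centre_um[2]) ** 2
    )
    sub = channel[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    np.maximum(sub, np.where(d2 <= radius**2, intensity, 0.0), out=sub)


def _apply_noise(channels: np.ndarray, params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_sigma_frac <= 0 and not params.poisson_noise:
        return channels
    out = channels.astype(float)
    intensities = (params.graft_intensity, params.vessel_intensity, params.macrophage_intensity)
    for c, level in enumerate(intensities):
        if params.poisson_noise:
            out[c] = rng.poisson(np.maximum(out[c], 0.0)).astype(float)
        if params.noise_sigma_frac > 0:
            out[c] = out[c] + rng.normal(0.0, params.noise_sigma_frac * level, out[c].shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# vessel construction: exact planted fraction with tube-shaped growth


def _vessel_growth_order(
    params: GeneratorParams,
    graft_idx: np.ndarray,
    centrelines_zy: np.ndarray,
) -> np.ndarray:
    """Deterministic order in which graft voxels vascularise.

    Vessels are capsules parallel to +x rooted on the CCV plane (x = 0).
    Voxels within the tube radius of a centreline fill in order of distance
    from the CCV plane (tube elongation); remaining graft voxels follow in
    order of distance to the nearest centreline (tube thickening), so any
    prefix of the order is a connected, tube-like vessel system and the
    planted fraction can be realised to the voxel.
    """
    vs = np.array(params.voxel_size)
    pos = (graft_idx + 0.5) * vs
    d_zy = np.linalg.norm(
        pos[:, None, :2] - centrelines_zy[None, :, :], axis=2
    )  # (N voxels, n vessels)
    rmin = d_zy.min(axis=1)
    covered = rmin <= params.vessel_radius_um
    key_primary = np.where(covered, 0, 1)
    key_secondary = np.where(covered, pos[:, 2], rmin)
    key_tertiary = pos[:, 2]
    return np.lexsort(
        (graft_idx[:, 2], graft_idx[:, 1], graft_idx[:, 0], key_tertiary, key_secondary, key_primary)
    )


def _region_fractions(
    graft_idx: np.ndarray,
    vessel_sel: np.ndarray,
    params: GeneratorParams,
    ccv_point: np.ndarray,
    ccv_axis: np.ndarray,
) -> tuple[float, float, float]:
    """Planted per-third vessel fractions along the CCV axis (equal-volume cuts)."""
    vs = np.array(params.voxel_size)
    pos = (graft_idx + 0.5) * vs
    s = (pos - ccv_point) @ ccv_axis
    order = np.lexsort((graft_idx[:, 2], graft_idx[:, 1], graft_idx[:, 0], s))
    n = len(order)
    base, r = divmod(n, 3)
    sizes = (base + (1 if r >= 1 else 0), base + (1 if r >= 2 else 0), base)
    is_vessel = np.zeros(n, dtype=bool)
    is_vessel[vessel_sel] = True
    fracs = []
    start = 0
    for size in sizes:
        run = order[start : start + size]
        fracs.append(float(is_vessel[run].sum()) / size if size else float("nan"))
        start += size
    return tuple(fracs)  # type: ignore[return-value]


def generate_static(params: GeneratorParams, seed: int) -> tuple[VolumetricStack, GroundTruth]:
    """Render one static stack and its exact ground truth.

    The vessel channel realises exactly ``round(f * N)`` vascularised graft
    voxels for target fraction ``f`` over ``N`` graft voxels, so the planted
    fraction is recorded to the voxel quantum.
    """
    if not 0.0 <= params.target_vessel_fraction <= 1.0:
        raise UnreachableFractionError(
            f"target vessel fraction {params.target_vessel_fraction!r} outside [0, 1]"
        )
    rng = np.random.default_rng(seed)
    graft_mask = _graft_mask(params)
    graft_idx = np.argwhere(graft_mask)
    n = graft_idx.shape[0]
    if n == 0:
        raise UnreachableFractionError("graft ellipsoid contains no voxels on this grid")

    centre = params.centre_um
    ccv_point = np.array([centre[0], centre[1], 0.0])
    ccv_axis = np.array([0.0, 0.0, 1.0])  # +x in (z, y, x) components

    # vessel centrelines: (z, y) roots scattered around the graft centre
    offsets = rng.uniform(-0.5, 0.5, size=(params.n_vessels, 2)) * np.array(
        params.graft_semiaxes_um[:2]
    )
    centrelines_zy = centre[:2][None, :] + offsets

    target_count = int(round(params.target_vessel_fraction * n))
    vessel_mask = np.zeros(params.shape, dtype=bool)
    vessel_sel = np.empty(0, dtype=int)
    if target_count > 0:
        order = _vessel_growth_order(params, graft_idx, centrelines_zy)
        vessel_sel = order[:target_count]
        vessel_mask[tuple(graft_idx[vessel_sel].T)] = True

    # macrophages: well-separated positions inside the graft
    positions = []
    min_sep = 2.0 * params.macrophage_radius_um + 2.0
    for _ in range(params.n_macrophages):
        for _attempt in range(200):
            p = _sample_in_graft(rng, params)
            if all(np.linalg.norm(p - q) >= min_sep for q in positions):
                positions.append(p)
                break
        else:
            positions.append(p)  # crowded graft: accept the last draw
    positions_arr = np.array(positions).reshape(-1, 3)

    channels = np.zeros((3, *params.shape), dtype=float)
    channels[CHANNEL_ROLES["graft"]][graft_mask] = params.graft_intensity
    channels[CHANNEL_ROLES["vessel"]][vessel_mask] = params.vessel_intensity
    for p in positions_arr:
        _render_sphere(
            channels[CHANNEL_ROLES["macrophage"]],
            params,
            p,
            params.macrophage_radius_um,
            params.macrophage_intensity,
        )
    channels = _apply_noise(channels, params, rng)

    voxel_volume = float(np.prod(params.voxel_size))
    stack = VolumetricStack(channels.astype(np.float32), dict(CHANNEL_ROLES), params.voxel_size)
    truth = GroundTruth(
        graft_volume_um3=n * voxel_volume,
        graft_voxel_count=n,
        vessel_fraction=target_count / n,
        vessel_volume_um3=target_count * voxel_volume,
        region_vessel_fractions=_region_fractions(graft_idx, vessel_sel, params, ccv_point, ccv_axis),
        graft_mask=graft_mask,
        vessel_mask=vessel_mask,
        ccv_point_um=ccv_point,
        ccv_axis=ccv_axis,
        macrophage_positions_um=positions_arr,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# time-lapse


def _tip_trajectory(params: GeneratorParams, tip_zy: np.ndarray) -> dict[int, np.ndarray]:
    """Designated vessel tip advancing along +x, capped inside the graft."""
    centre = params.centre_um
    start_x = centre[2] - 12.0
    max_x = centre[2] + 12.0
    tips = {}
    for f in range(params.n_frames):
        x = min(start_x + f * params.elongation_um_per_frame, max_x)
        tips[f] = np.array([tip_zy[0], tip_zy[1], x])
    return tips


def simulate_tracks(
    params: GeneratorParams, seed: int
) -> tuple[np.ndarray, dict[int, np.ndarray], list[DwellEvent]]:
    """Simulate macrophage motion only (no rendering).

    Returns ``(tracks, tip_trajectory, dwell_events)`` where ``tracks`` has
    shape (n_macrophages, n_frames, 3) in µm. Free motion is a persistent
    random walk (AR(1) velocity with memory ``persistence``) restricted to
    the graft ellipsoid by rejection: a step leaving the ellipsoid is not
    taken and the velocity is reversed. With ``persistence = 0`` this is a
    Metropolis chain whose stationary distribution is exactly uniform on the
    graft — the correct null for region scoring. While dwelling, a
    macrophage stays anchored at the tip position where the dwell began,
    with ``sigma_dwell`` jitter, until its duration elapses; on dissociation
    it departs radially away from the tip at the free-walk speed scale
    (macrophages resume directed migration on leaving the vessel), which
    keeps contact ends crisp.
    """
    rng = np.random.default_rng(seed)
    dz = params.voxel_size[0]
    # vessel centreline fixed at the slice-centre z nearest the graft centre
    centre = params.centre_um
    z_slice = round(centre[0] / dz - 0.5)
    z_slice = min(max(z_slice, 0), params.shape[0] - 1)
    tip_zy = np.array([(z_slice + 0.5) * dz, centre[1]])
    tips = _tip_trajectory(params, tip_zy)

    duration_frames = max(1, int(round(params.dwell_duration_min / params.frame_interval)))
    m = params.n_macrophages
    tracks = np.zeros((m, params.n_frames, 3))
    events: list[DwellEvent] = []
    pos = np.array([_sample_in_graft(rng, params) for _ in range(m)]).reshape(m, 3)
    velocity = rng.normal(0.0, params.sigma_free_um, (m, 3))
    dwell_left = np.zeros(m, dtype=int)
    anchor = np.zeros((m, 3))
    dwell_start = np.zeros(m, dtype=int)
    escape_pending = np.zeros(m, dtype=bool)

    for k in range(min(params.n_initial_dwellers, m)):
        dwell_left[k] = duration_frames
        anchor[k] = tips[0]
        dwell_start[k] = 0

    for f in range(params.n_frames):
        tip = tips[f]
        for k in range(m):
            if dwell_left[k] > 0:
                pos[k] = anchor[k] + rng.normal(0.0, params.sigma_dwell_um, 3)
                dwell_left[k] -= 1
                if dwell_left[k] == 0:
                    events.append(DwellEvent(k, 0, int(dwell_start[k]), f))
                    escape_pending[k] = True
            else:
                captured = (
                    not escape_pending[k]
                    and params.dwell_prob > 0
                    and float(np.linalg.norm(pos[k] - tip)) <= params.capture_radius_um
                    and rng.random() < params.dwell_prob
                )
                if captured:
                    anchor[k] = tip
                    dwell_start[k] = f
                    dwell_left[k] = duration_frames
                    pos[k] = anchor[k] + rng.normal(0.0, params.sigma_dwell_um, 3)
                    dwell_left[k] -= 1
                    if dwell_left[k] == 0:
                        events.append(DwellEvent(k, 0, f, f))
                        escape_pending[k] = True
                else:
                    if escape_pending[k]:
                        away = pos[k] - tip
                        norm = float(np.linalg.norm(away))
                        direction = away / norm if norm > 1e-9 else np.array([0.0, 0.0, -1.0])
                        velocity[k] = 2.0 * params.sigma_free_um * direction
                        escape_pending[k] = False
                    else:
                        velocity[k] = params.persistence * velocity[k] + rng.normal(
                            0.0, params.sigma_free_um, 3
                        )
                    proposal = pos[k] + velocity[k]
                    if _inside_ellipsoid(proposal, params):
                        pos[k] = proposal
                    else:
                        velocity[k] = -velocity[k]
            tracks[k, f] = pos[k]
    # close any dwell still running at the movie end
    for k in range(m):
        if dwell_left[k] > 0:
            events.append(DwellEvent(k, 0, int(dwell_start[k]), params.n_frames - 1))
    return tracks, tips, events


def generate_timelapse(params: GeneratorParams, seed: int) -> tuple[TimelapseStack, GroundTruth]:
    """Render a full time-lapse with one elongating vessel and walking macrophages."""
    if params.n_frames < 2:
        raise ValueError("a time-lapse needs n_frames >= 2")
    tracks, tips, events = simulate_tracks(params, seed)
    render_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    graft_mask = _graft_mask(params)
    graft_idx = np.argwhere(graft_mask)
    voxel_volume = float(np.prod(params.voxel_size))
    z, y, x = _voxel_centres(params)
    tip0 = tips[0]

    frames = []
    last_vessel_mask = None
    for f in range(params.n_frames):
        tip = tips[f]
        # capsule from the CCV plane (x=0) to the tip, radius vessel_radius
        within_r = (
            (z[:, None] - tip[0]) ** 2 + (y[None, :] - tip[1]) ** 2
        ) <= params.vessel_radius_um**2
        ahead = x <= tip[2]
        vessel_mask = within_r[:, :, None] & ahead[None, None, :]
        cap = (
            (z[:, None, None] - tip[0]) ** 2
            + (y[None, :, None] - tip[1]) ** 2
            + (x[None, None, :] - tip[2]) ** 2
        ) <= params.vessel_radius_um**2
        vessel_mask |= cap
        last_vessel_mask = vessel_mask

        channels = np.zeros((3, *params.shape), dtype=float)
        channels[CHANNEL_ROLES["graft"]][graft_mask] = params.graft_intensity
        channels[CHANNEL_ROLES["vessel"]][vessel_mask] = params.vessel_intensity
        for k in range(params.n_macrophages):
            _render_sphere(
                channels[CHANNEL_ROLES["macrophage"]],
                params,
                tracks[k, f],
                params.macrophage_radius_um,
                params.macrophage_intensity,
            )
        channels = _apply_noise(channels, params, render_rng)
        frames.append(
            VolumetricStack(channels.astype(np.float32), dict(CHANNEL_ROLES), params.voxel_size)
        )

    n = graft_idx.shape[0]
    vessel_in_graft = int((last_vessel_mask & graft_mask).sum())
    centre = params.centre_um
    truth = GroundTruth(
        graft_volume_um3=n * voxel_volume,
        graft_voxel_count=n,
        vessel_fraction=vessel_in_graft / n,
        vessel_volume_um3=vessel_in_graft * voxel_volume,
        region_vessel_fractions=None,
        graft_mask=graft_mask,
        vessel_mask=last_vessel_mask,
        ccv_point_um=np.array([centre[0], centre[1], 0.0]),
        ccv_axis=np.array([0.0, 0.0, 1.0]),
        tracks_um=tracks,
        tip_trajectory_um=tips,
        dwell_events=events,
        frame_interval=params.frame_interval,
    )
    return TimelapseStack(frames, params.frame_interval), truth
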