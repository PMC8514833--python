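"""Synthetic study inputs: thermal-frame sequences and phantom scenes.

No recording of the original two-rat experiment is deposited, so this
module emulates it end to end: two warm elliptical bodies moving through a
cooler cage under a correlated random walk with a tunable contact
affinity, rendered as false-colour frames (body mostly in the red channel,
background in the blue channel) with Gaussian sensor noise.  Every frame
carries exact ground-truth poses, which is what makes the downstream
segmentation and posture statistics testable.

The same module also places two ellipsoid rat phantoms at a requested
relative posture (d, alpha, beta) on a voxel grid for the field solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import fdtd

#: Cage floor dimensions, mm (a 0.46 m x 0.30 m home cage).
DEFAULT_ARENA_MM = (460.0, 300.0)
#: Ellipse semi-axes of the adult rat body, mm (244.8 x 46.8 mm animal).
DEFAULT_HALF_LENGTH_MM = 122.4
DEFAULT_HALF_WIDTH_MM = 23.4


class PlacementError(ValueError):
    """Requested phantom pose is geometrically impossible (interpenetration)."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic thermal recording.

    The defaults are the study conditions: the real cage and animal
    dimensions, a 2 mm/pixel scale consistent with the few-millimetre
    centroid uncertainty of thermal tracking, and random-walk scales that
    produce smooth, trackable motion between frames.
    """

    arena_mm: tuple[float, float] = DEFAULT_ARENA_MM
    pixel_scale_mm: float = 2.0
    rat_half_length_mm: float = DEFAULT_HALF_LENGTH_MM
    rat_half_width_mm: float = DEFAULT_HALF_WIDTH_MM
    body_temp_level: int = 220
    background_level: int = 120
    noise_sd: float = 5.0
    contact_affinity: float = 0.55
    step_sd_mm: float = 6.0
    turn_sd_deg: float = 6.0
    n_frames: int = 100
    seed: int = 0
    initial_poses: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if min(self.arena_mm) <= 0 or self.pixel_scale_mm <= 0:
            raise ValueError("arena dimensions and pixel scale must be positive")
        if self.body_temp_level <= self.background_level:
            raise ValueError("body_temp_level must exceed background_level")
        if not 0.0 <= self.contact_affinity <= 1.0:
            raise ValueError("contact_affinity must lie in [0, 1]")
        if self.rat_half_length_mm < self.rat_half_width_mm:
            raise ValueError("rat_half_length must be >= rat_half_width")
        length, width = 2 * self.rat_half_length_mm, 2 * self.rat_half_width_mm
        if max(self.arena_mm) < length or min(self.arena_mm) < width:
            raise ValueError(
                f"arena {self.arena_mm} mm cannot contain a "
                f"{length:.1f} x {width:.1f} mm rat")

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered frames."""
        return (
            int(round(self.arena_mm[1] / self.pixel_scale_mm)),
            int(round(self.arena_mm[0] / self.pixel_scale_mm)),
        )


@dataclass(frozen=True)
class GroundTruthPose:
    """Exact poses of both rats in one frame."""

    frame_index: int
    centroids_mm: tuple[tuple[float, float], tuple[float, float]]
    orientations_deg: tuple[float, float]

    def __post_init__(self) -> None:
        for t in self.orientations_deg:
            if not 0.0 <= t < 180.0:
                raise ValueError("orientations must be folded to [0, 180)")


def _half_extents(theta_deg: float, hl: float, hw: float) -> tuple[float, float]:
    """Axis-aligned half extents of a rotated ellipse."""
    t = math.radians(theta_deg)
    ex = math.hypot(hl * math.cos(t), hw * math.sin(t))
    ey = math.hypot(hl * math.sin(t), hw * math.cos(t))
    return ex, ey


def _default_initial_poses(cfg: GeneratorConfig) -> np.ndarray:
    lx, ly = cfg.arena_mm
    return np.array(
        [[0.30 * lx, 0.38 * ly, 10.0], [0.70 * lx, 0.62 * ly, 150.0]]
    )


def _clamp_to_arena(state: np.ndarray, cfg: GeneratorConfig) -> None:
    lx, ly = cfg.arena_mm
    for r in range(2):
        ex, ey = _half_extents(state[r, 2], cfg.rat_half_length_mm,
                               cfg.rat_half_width_mm)
        state[r, 0] = np.clip(state[r, 0], ex, lx - ex)
        state[r, 1] = np.clip(state[r, 1], ey, ly - ey)


def _body_profile(cfg: GeneratorConfig, cx: float, cy: float, theta_deg: float,
                  xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    """Normalised thermal footprint of one body on the pixel grid.

    Flat at 1 inside 90% of the elliptical radius, then a linear falloff
    to 0 at the body boundary — a near-binary silhouette with a soft rim,
    which is what a slightly defocused thermal camera records.
    """
    t = math.radians(theta_deg)
    dx, dy = xg - cx, yg - cy
    u = (dx * math.cos(t) + dy * math.sin(t)) / cfg.rat_half_length_mm
    v = (-dx * math.sin(t) + dy * math.cos(t)) / cfg.rat_half_width_mm
    r = np.sqrt(u * u + v * v)
    return np.clip((1.0 - r) / 0.1, 0.0, 1.0)


def render_frame(cfg: GeneratorConfig, state: np.ndarray,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one RGB uint8 frame from a (2, 3) pose state [x, y, theta]."""
    rows, cols = cfg.frame_shape
    xs = (np.arange(cols) + 0.5) * cfg.pixel_scale_mm
    ys = (np.arange(rows) + 0.5) * cfg.pixel_scale_mm
    xg, yg = np.meshgrid(xs, ys)
    f = np.zeros((rows, cols))
    for r in range(2):
        # Temperature fields combine by per-pixel maximum, not addition.
        f = np.maximum(f, _body_profile(cfg, state[r, 0], state[r, 1],
                                        state[r, 2], xg, yg))
    red = 20.0 + (cfg.body_temp_level - 20.0) * f
    green = np.full_like(f, 30.0)
    blue = cfg.background_level * (1.0 - f) + 15.0 * f
    frame = np.stack([red, green, blue], axis=-1)
    if rng is not None and cfg.noise_sd > 0:
        frame = frame + rng.normal(0.0, cfg.noise_sd, frame.shape)
    return np.clip(frame, 0, 255).astype(np.uint8)


def generate_sequence(
    cfg: GeneratorConfig,
) -> tuple[list[np.ndarray], list[GroundTruthPose]]:
    """Simulate and render a seeded two-rat thermal sequence.

    Motion is a correlated random walk on (x, y, theta) with Gaussian
    steps; with probability ``contact_affinity`` a frame's translation is
    biased toward the other animal's centroid, which raises the fraction
    of frames the pair spends in contact.  Bodies never leave the arena,
    and centroids are kept at least 1.5 body half-widths apart so the
    silhouettes can touch and overlap but never coincide.
    """
    rng = np.random.default_rng(cfg.seed)
    state = np.array(cfg.initial_poses if cfg.initial_poses is not None
                     else _default_initial_poses(cfg), dtype=float)
    if state.shape != (2, 3):
        raise ValueError("initial_poses must provide (x, y, theta) per rat")
    _clamp_to_arena(state, cfg)

    min_sep = 1.5 * cfg.rat_half_width_mm
    frames: list[np.ndarray] = []
    truth: list[GroundTruthPose] = []
    for k in range(cfg.n_frames):
        frames.append(render_frame(cfg, state, rng))
        truth.append(
            GroundTruthPose(
                frame_index=k,
                centroids_mm=((state[0, 0], state[0, 1]),
                              (state[1, 0], state[1, 1])),
                orientations_deg=(state[0, 2] % 180.0, state[1, 2] % 180.0),
            )
        )
        if k == cfg.n_frames - 1:
            break
        step = rng.normal(0.0, cfg.step_sd_mm, size=(2, 2))
        biased = rng.random(2) < cfg.contact_affinity
        for r in range(2):
            if biased[r]:
                other = state[1 - r, :2]
                delta = other - state[r, :2]
                dist = np.hypot(*delta)
                if dist > 1e-9:
                    step[r] += cfg.step_sd_mm * delta / dist
        state[:, :2] += step
        state[:, 2] = (state[:, 2] + rng.normal(0.0, cfg.turn_sd_deg, 2)) % 180.0
        # Soft exclusion: bodies may touch/overlap but centroids never coincide.
        delta = state[1, :2] - state[0, :2]
        dist = np.hypot(*delta)
        if dist < min_sep:
            direction = delta / dist if dist > 1e-9 else np.array([1.0, 0.0])
            push = 0.5 * (min_sep - dist)
            state[0, :2] -= push * direction
            state[1, :2] += push * direction
        _clamp_to_arena(state, cfg)
    return frames, truth


def contact_fraction(truth: Sequence[GroundTruthPose],
                     threshold_mm: float) -> float:
    """Fraction of frames whose centroid distance is below ``threshold_mm``."""
    n = 0
    for t in truth:
        (x1, y1), (x2, y2) = t.centroids_mm
        if math.hypot(x2 - x1, y2 - y1) < threshold_mm:
            n += 1
    return n / len(truth)


def truth_to_records(truth: Sequence[GroundTruthPose]) -> list[dict]:
    """Flatten ground truth to (frame, rat_id, x_mm, y_mm, theta_deg) rows."""
    rows = []
    for t in truth:
        for rid in range(2):
            rows.append(
                {
                    "frame": t.frame_index,
                    "rat_id": rid + 1,
                    "x_mm": t.centroids_mm[rid][0],
                    "y_mm": t.centroids_mm[rid][1],
                    "theta_deg": t.orientations_deg[rid],
                }
            )
    return rows


# -- phantom scenes ----------------------------------------------------------

def build_phantom_scene(
    d_mm: float,
    alpha_deg: float,
    beta_deg: float,
    material: fdtd.Material | None = None,
    grid_step_mm: float = 2.0,
    half_length_mm: float = DEFAULT_HALF_LENGTH_MM,
    half_width_mm: float = DEFAULT_HALF_WIDTH_MM,
    margin_cells: int = 8,
    n_pml: int = 7,
) -> fdtd.Scene:
    """Voxelise two ellipsoid rat phantoms at relative posture (d, a, b).

    Phantom 1 sits at the origin with its long axis along Y; phantom 2's
    centre is displaced by ``d`` at angle ``alpha`` from the X-axis
    (X being perpendicular to phantom 1's long axis), with its own long
    axis rotated by ``beta``.  Both are prolate ellipsoids with circular
    cross-section (semi-axes half_width x half_length x half_width).
    Interpenetrating placements raise :class:`PlacementError`.
    """
    if grid_step_mm <= 0:
        raise ValueError("grid_step_mm must be positive")
    material = material or fdtd.MUSCLE_TWO_THIRDS
    a = math.radians(alpha_deg)
    center2 = (d_mm * math.cos(a), d_mm * math.sin(a), 0.0)
    phantoms = [
        fdtd.Ellipsoid(center_mm=(0.0, 0.0, 0.0),
                       semi_axes_mm=(half_width_mm, half_length_mm, half_width_mm),
                       yaw_deg=0.0),
        fdtd.Ellipsoid(center_mm=center2,
                       semi_axes_mm=(half_width_mm, half_length_mm, half_width_mm),
                       yaw_deg=beta_deg),
    ]
    try:
        return fdtd.build_scene(phantoms, material, grid_step_mm,
                                margin_cells=margin_cells, n_pml=n_pml)
    except fdtd.OverlapError as exc:
        raise PlacementError(
            f"phantoms interpenetrate at (d={d_mm}, alpha={alpha_deg}, "
            f"beta={beta_deg}): {exc}") from exc


def build_contact_scene(
    material: fdtd.Material | None = None,
    grid_step_mm: float = 2.0,
    half_length_mm: float = DEFAULT_HALF_LENGTH_MM,
    half_width_mm: float = DEFAULT_HALF_WIDTH_MM,
    **kwargs,
) -> fdtd.Scene:
    """Scene standing in for the merged d = 0 super-case.

    The two phantoms lie flank to flank (parallel, long axes along Y,
    centres one body width apart) — one configuration representing all 25
    closely-huddled posture cases.
    """
    return build_phantom_scene(
        d_mm=2.0 * half_width_mm, alpha_deg=0.0, beta_deg=0.0,
        material=material, grid_step_mm=grid_step_mm,
        half_length_mm=half_length_mm, half_width_mm=half_width_mm, **kwargs)
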