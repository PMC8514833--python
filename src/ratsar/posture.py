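"""Relative-posture characterisation and binning for a pair of tracked rats.

Each video frame reduces to a triple (d, alpha, beta):

* ``d`` — centre-to-centre distance between the two body ellipses, in mm;
* ``alpha`` — angle between the connecting line and the X-axis of a frame
  anchored on rat 1, whose Y-axis runs along rat 1's long (spine) axis;
* ``beta`` — angle between the two long axes.

Head and tail cannot be told apart in a thermal silhouette, and the two
animals are interchangeable, so both angles are folded into [0, 90] degrees.
Postures are binned on a 5 x 5 x 5 grid (distance in half-wavelength steps,
angles in 22.5-degree steps) giving 125 cases; the occupancy probabilities
``W_i`` of those cases weight the per-case SAR values downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import RatEllipse

#: Propagation speed used for wavelength bookkeeping (m/s).  The rounded
#: value keeps the conventional 166.7 mm wavelength at 1.8 GHz.
C_LIGHT = 3.0e8

N_BINS_PER_AXIS = 5
N_CASES = N_BINS_PER_AXIS**3


def wavelength(frequency_hz: float) -> float:
    """Free-space wavelength in millimetres for a CW frequency in Hz."""
    if frequency_hz <= 0:
        raise ValueError(f"frequency must be positive, got {frequency_hz}")
    return C_LIGHT / frequency_hz * 1e3


def fold_angle(angle_deg: float) -> float:
    """Fold an angle into [0, 90] degrees.

    The fold expresses two indistinguishabilities: head vs. tail of one
    animal (period 180 degrees) and the mirror symmetry between the two
    animals (reflection about 90 degrees).  Folding an already folded
    angle is a no-op.
    """
    a = abs(angle_deg) % 180.0
    if a > 90.0:
        a = 180.0 - a
    return a


@dataclass(frozen=True)
class PosturePair:
    """One frame's relative posture: distance and two folded angles."""

    d_mm: float
    alpha_deg: float
    beta_deg: float
    contact: bool = False
    reliable: bool = True

    def __post_init__(self) -> None:
        if self.d_mm < 0:
            raise ValueError("d must be non-negative")
        for name in ("alpha_deg", "beta_deg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 90.0:
                raise ValueError(f"{name} must lie in [0, 90], got {v}")


@dataclass(frozen=True)
class BinningScheme:
    """5 x 5 x 5 partition of (d, alpha, beta) space.

    Distance bins are half-open multiples of ``delta_d`` = lambda/2; the
    top bin absorbs everything beyond 2 lambda (the cage diagonal exceeds
    the nominal 2.5 lambda range, so a clamp is unavoidable).  Angle bins
    are 22.5-degree half-open intervals with 90 degrees clamped into the
    last bin.
    """

    wavelength_mm: float = field(default_factory=lambda: wavelength(1.8e9))
    delta_alpha_deg: float = 22.5
    delta_beta_deg: float = 22.5

    @property
    def delta_d_mm(self) -> float:
        return 0.5 * self.wavelength_mm

    @property
    def n_cases(self) -> int:
        return N_CASES


@dataclass(frozen=True)
class CaseBin:
    """Bin indices and the canonical 1..125 case identifier."""

    d_idx: int
    alpha_idx: int
    beta_idx: int

    def __post_init__(self) -> None:
        for name in ("d_idx", "alpha_idx", "beta_idx"):
            v = getattr(self, name)
            if not 0 <= v < N_BINS_PER_AXIS:
                raise ValueError(f"{name} out of range: {v}")

    @property
    def case_id(self) -> int:
        return case_id_from_indices(self.d_idx, self.alpha_idx, self.beta_idx)


def case_id_from_indices(d_idx: int, alpha_idx: int, beta_idx: int) -> int:
    """Enumerate (d, alpha, beta) bins as case IDs 1..125.

    beta varies fastest, then alpha, then d — case 1 is (0, 0, 0),
    case 26 is (0.5 lambda, 0, 0), case 125 is (2 lambda, 90, 90).
    """
    for v in (d_idx, alpha_idx, beta_idx):
        if not 0 <= v < N_BINS_PER_AXIS:
            raise ValueError("bin index out of range")
    return 25 * d_idx + 5 * alpha_idx + beta_idx + 1


def indices_from_case_id(case_id: int) -> tuple[int, int, int]:
    """Invert :func:`case_id_from_indices`."""
    if not 1 <= case_id <= N_CASES:
        raise ValueError(f"case_id must be in 1..{N_CASES}, got {case_id}")
    z = case_id - 1
    return z // 25, (z % 25) // 5, z % 5


def relative_posture(
    e1: RatEllipse, e2: RatEllipse, contact: bool = False
) -> PosturePair:
    """Reduce two fitted body ellipses to the (d, alpha, beta) triple.

    Rat 1 anchors the frame: its long axis is the local Y-axis and the
    perpendicular in-plane direction is X.  ``alpha`` is the angle of the
    centre-connecting line to that X-axis; ``beta`` the angle between the
    two long axes.  Both are folded into [0, 90].
    """
    dx = e2.x_mm - e1.x_mm
    dy = e2.y_mm - e1.y_mm
    d = math.hypot(dx, dy)

    t1 = math.radians(e1.orientation_deg)
    # Local axes anchored on rat 1: y_hat along the spine, x_hat perpendicular.
    y_hat = (math.cos(t1), math.sin(t1))
    x_hat = (math.sin(t1), -math.cos(t1))
    if d > 0:
        vx = dx * x_hat[0] + dy * x_hat[1]
        vy = dx * y_hat[0] + dy * y_hat[1]
        alpha = fold_angle(math.degrees(math.atan2(vy, vx)))
    else:
        alpha = 0.0
    beta = fold_angle(e2.orientation_deg - e1.orientation_deg)
    reliable = e1.orientation_reliable and e2.orientation_reliable
    return PosturePair(d_mm=d, alpha_deg=alpha, beta_deg=beta,
                       contact=contact, reliable=reliable)


def bin_posture(p: PosturePair, scheme: BinningScheme | None = None) -> CaseBin:
    """Assign a posture to its case bin.

    Bins are half-open ``[k*delta, (k+1)*delta)``; the top edge of each
    axis clamps into the last bin.  A contact frame (single merged
    silhouette) belongs to the d = 0 super-case regardless of distance.
    """
    scheme = scheme or BinningScheme()
    if p.contact:
        d_idx = 0
    else:
        d_idx = min(int(p.d_mm // scheme.delta_d_mm), N_BINS_PER_AXIS - 1)
    alpha_idx = min(int(p.alpha_deg // scheme.delta_alpha_deg), N_BINS_PER_AXIS - 1)
    beta_idx = min(int(p.beta_deg // scheme.delta_beta_deg), N_BINS_PER_AXIS - 1)
    return CaseBin(d_idx=d_idx, alpha_idx=alpha_idx, beta_idx=beta_idx)


@dataclass(frozen=True)
class PostureDistribution:
    """Occupancy probabilities over the 125 posture cases."""

    weights: np.ndarray
    frame_count: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_CASES,):
            raise ValueError(f"weights must have shape ({N_CASES},)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)

    def weight(self, case_id: int) -> float:
        indices_from_case_id(case_id)  # validates range
        return float(self.weights[case_id - 1])


def accumulate_distribution(bins: Iterable[CaseBin]) -> PostureDistribution:
    """Turn a sequence of case bins into an occupancy distribution W."""
    counts = np.zeros(N_CASES, dtype=np.int64)
    n = 0
    for b in bins:
        counts[b.case_id - 1] += 1
        n += 1
    if n == 0:
        raise ValueError("cannot accumulate a distribution from zero frames")
    return PostureDistribution(weights=counts / n, frame_count=n)


# -- table-level drivers ----------------------------------------------------

def case_label(case_id: int, scheme: BinningScheme | None = None) -> tuple[str, str, str]:
    """Human-readable (d, alpha, beta) labels of a case's lower bin edges."""
    scheme = scheme or BinningScheme()
    di, ai, bi = indices_from_case_id(case_id)
    d_lab = {0: "0", 1: "0.5λ", 2: "λ", 3: "1.5λ", 4: "2λ"}[di]
    return d_lab, f"{ai * scheme.delta_alpha_deg:g}°", f"{bi * scheme.delta_beta_deg:g}°"


def postures_from_tracks(
    tracks: pd.DataFrame, scheme: BinningScheme | None = None
) -> pd.DataFrame:
    """Compute the per-frame posture time series from a two-rat track table.

    ``tracks`` is the segmentation output: one row per (frame, rat_id) with
    columns ``x_mm, y_mm, theta_deg, semi_major_mm, semi_minor_mm,
    contact_flag``.  Returns one row per frame with columns ``frame, d_mm,
    d_over_lambda, alpha_deg, beta_deg, contact, case_id``.
    """
    scheme = scheme or BinningScheme()
    rows = []
    for frame, grp in tracks.groupby("frame", sort=True):
        grp = grp.sort_values("rat_id")
        if len(grp) != 2:
            raise ValueError(f"frame {frame}: expected 2 rat rows, got {len(grp)}")
        es = [
            RatEllipse(
                x_mm=r.x_mm, y_mm=r.y_mm,
                semi_major_mm=r.semi_major_mm, semi_minor_mm=r.semi_minor_mm,
                orientation_deg=r.theta_deg, pixel_count=int(getattr(r, "pixel_count", 9)),
            )
            for r in grp.itertuples()
        ]
        contact = bool(grp["contact_flag"].any())
        p = relative_posture(es[0], es[1], contact=contact)
        cb = bin_posture(p, scheme)
        rows.append(
            {
                "frame": int(frame),
                "d_mm": p.d_mm,
                "d_over_lambda": p.d_mm / scheme.wavelength_mm,
                "alpha_deg": p.alpha_deg,
                "beta_deg": p.beta_deg,
                "contact": contact,
                "case_id": cb.case_id,
            }
        )
    return pd.DataFrame(rows)


def distribution_table(
    dist: PostureDistribution, scheme: BinningScheme | None = None
) -> pd.DataFrame:
    """125-row table (case_id, d/alpha/beta labels, W_i)."""
    scheme = scheme or BinningScheme()
    recs = []
    for cid in range(1, N_CASES + 1):
        d_lab, a_lab, b_lab = case_label(cid, scheme)
        recs.append(
            {"case_id": cid, "d_label": d_lab, "alpha_label": a_lab,
             "beta_label": b_lab, "W": dist.weights[cid - 1]}
        )
    return pd.DataFrame(recs)


def distribution_from_case_ids(case_ids: Sequence[int]) -> PostureDistribution:
    """Distribution directly from a sequence of case identifiers."""
    bins = [CaseBin(*indices_from_case_id(int(c))) for c in case_ids]
    return accumulate_distribution(bins)
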