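"""Two-animal segmentation of false-colour thermal frames.

The chain mirrors a standard infrared-thermography tracking recipe:

1. grayscale by the red-minus-blue channel difference (warm bodies are
   rendered red, the cool cage floor blue, so R - B is high-contrast);
2. threshold binarisation (Otsu by default, manual override available);
3. marker-controlled watershed on the negated distance transform to
   separate touching silhouettes;
4. second-moment (covariance) ellipse fit per labelled animal, giving
   centroid, semi-axes and an orientation folded to [0, 180);
5. nearest-centroid identity tracking across frames.

All geometry is reported in millimetres via the frame's pixel scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

#: Default rat body size (mm): a 244.8 mm x 46.8 mm adult animal.
DEFAULT_BODY_LENGTH_MM = 244.8
DEFAULT_BODY_WIDTH_MM = 46.8

#: Eigenvalue ratio below which the covariance is close to isotropic and
#: the fitted direction is meaningless (curled posture, near-disc blob).
ORIENTATION_EIGRATIO_MIN = 1.2

#: Fraction of the distance-transform maximum that defines marker cores
#: for the watershed split of a merged silhouette.
_CORE_FRACTION = 0.7


class SegmentationError(ValueError):
    """Raised when a stage receives input it cannot process."""


@dataclass(frozen=True)
class GrayFrame:
    """Channel-difference grayscale image plus its pixel calibration."""

    data: np.ndarray
    pixel_scale_mm: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise SegmentationError("GrayFrame data must be 2-D")
        if d.min() < 0:
            raise SegmentationError("GrayFrame intensities must be non-negative")
        if self.pixel_scale_mm <= 0:
            raise SegmentationError("pixel_scale_mm must be positive")
        object.__setattr__(self, "data", d)


@dataclass(frozen=True)
class BinaryMask:
    """Foreground mask produced by :func:`binarize`."""

    mask: np.ndarray
    pixel_scale_mm: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != bool:
            raise SegmentationError("BinaryMask must be a 2-D boolean array")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class LabelMask:
    """Integer labels: 0 = background, 1..K = animals (K <= 2)."""

    labels: np.ndarray
    pixel_scale_mm: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise SegmentationError("LabelMask must be a 2-D integer array")
        k = int(lab.max(initial=0))
        present = set(np.unique(lab)) - {0}
        if present != set(range(1, k + 1)):
            raise SegmentationError("labels must be contiguous 1..K")
        if k > 2:
            raise SegmentationError("at most two animals are supported")
        object.__setattr__(self, "labels", lab)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))


@dataclass(frozen=True)
class RatEllipse:
    """Second-moment ellipse summary of one animal in one frame."""

    x_mm: float
    y_mm: float
    semi_major_mm: float
    semi_minor_mm: float
    orientation_deg: float
    pixel_count: int
    orientation_reliable: bool = True

    def __post_init__(self) -> None:
        if not (self.semi_major_mm >= self.semi_minor_mm > 0):
            raise SegmentationError("require semi_major >= semi_minor > 0")
        if not 0.0 <= self.orientation_deg < 180.0:
            raise SegmentationError("orientation must be folded to [0, 180)")

    @property
    def centroid_mm(self) -> tuple[float, float]:
        return (self.x_mm, self.y_mm)


def to_grayscale(frame: np.ndarray, pixel_scale_mm: float) -> GrayFrame:
    """Red-minus-blue channel difference, clamped at zero.

    Accepts an (H, W, 3) 8-bit frame; anything else — including a
    GrayFrame, which would make rerunning the step silently wrong — is
    rejected.
    """
    if isinstance(frame, (GrayFrame, BinaryMask, LabelMask)):
        raise SegmentationError("to_grayscale expects a raw RGB frame, "
                                f"got {type(frame).__name__}")
    arr = np.asarray(frame)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SegmentationError(f"expected an (H, W, 3) frame, got shape {arr.shape}")
    diff = arr[..., 0].astype(np.int16) - arr[..., 2].astype(np.int16)
    return GrayFrame(data=np.maximum(diff, 0).astype(np.uint8),
                     pixel_scale_mm=pixel_scale_mm)


def binarize(gray: GrayFrame, threshold: float | str = "auto") -> BinaryMask:
    """Threshold the grayscale frame; foreground = intensity > threshold.

    ``"auto"`` picks Otsu's threshold from the bimodal body/background
    histogram; a constant image has no such threshold and raises.
    """
    if not isinstance(gray, GrayFrame):
        raise SegmentationError("binarize expects a GrayFrame")
    data = gray.data
    if threshold == "auto":
        if data.min() == data.max():
            raise SegmentationError(
                "degenerate histogram: constant image has no automatic threshold")
        thr = float(threshold_otsu(data))
    else:
        thr = float(threshold)
    return BinaryMask(mask=data > thr, pixel_scale_mm=gray.pixel_scale_mm)


def _expected_body_area_px(pixel_scale_mm: float,
                           body_length_mm: float,
                           body_width_mm: float) -> float:
    return math.pi * (body_length_mm / 2) * (body_width_mm / 2) / pixel_scale_mm**2


def split_and_label(
    binary: BinaryMask,
    body_length_mm: float = DEFAULT_BODY_LENGTH_MM,
    body_width_mm: float = DEFAULT_BODY_WIDTH_MM,
) -> LabelMask:
    """Separate and label up to two animals in a foreground mask.

    Components smaller than 10% of one expected body area are treated as
    sensor noise and dropped.  Two or more surviving components reduce to
    plain connected-component labelling (the two largest are kept).  A
    single merged component is split by a marker-controlled watershed on
    the negated distance transform; markers are the connected cores where
    the distance transform exceeds 70% of its maximum, so a merged frame
    with two distinct body cores splits while a tight huddle stays one
    label and is flagged as contact downstream.
    """
    if not isinstance(binary, BinaryMask):
        raise SegmentationError("split_and_label expects a BinaryMask")
    mask = binary.mask
    if not mask.any():
        raise SegmentationError("empty mask: nothing to label")

    floor_px = 0.1 * _expected_body_area_px(
        binary.pixel_scale_mm, body_length_mm, body_width_mm)
    comp, ncomp = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, range(1, ncomp + 1))
    keep = [i + 1 for i, s in enumerate(sizes) if s >= floor_px]
    if not keep:
        raise SegmentationError("all components fall below the noise floor")

    if len(keep) >= 2:
        order = sorted(keep, key=lambda i: -sizes[i - 1])[:2]
        out = np.zeros_like(comp)
        for new, old in enumerate(order, start=1):
            out[comp == old] = new
        return LabelMask(labels=out, pixel_scale_mm=binary.pixel_scale_mm)

    only = keep[0]
    blob = comp == only
    dist = ndimage.distance_transform_edt(blob)
    cores, ncores = ndimage.label(dist > _CORE_FRACTION * dist.max())
    if ncores < 2:
        return LabelMask(labels=blob.astype(np.int32),
                         pixel_scale_mm=binary.pixel_scale_mm)
    if ncores > 2:
        core_sizes = ndimage.sum_labels(np.ones_like(cores), cores,
                                        range(1, ncores + 1))
        order = np.argsort(core_sizes)[::-1][:2] + 1
        markers = np.zeros_like(cores)
        markers[cores == order[0]] = 1
        markers[cores == order[1]] = 2
    else:
        markers = cores
    out = watershed(-dist, markers=markers, mask=blob).astype(np.int32)
    return LabelMask(labels=out, pixel_scale_mm=binary.pixel_scale_mm)


def fit_ellipse(labels: LabelMask, label_id: int) -> RatEllipse:
    """Second-moment ellipse of one labelled animal.

    The centroid is the pixel-position mean; the orientation is the
    principal eigenvector angle of the pixel-position covariance, folded
    to [0, 180); the semi-axes are twice the eigenvalue square roots
    (exact for a uniformly filled ellipse).  A near-isotropic covariance
    (eigenvalue ratio below 1.2) flags the orientation as unreliable.
    """
    if not isinstance(labels, LabelMask):
        raise SegmentationError("fit_ellipse expects a LabelMask")
    rows, cols = np.nonzero(labels.labels == label_id)
    n = rows.size
    if n < 5:
        raise SegmentationError(
            f"label {label_id} has {n} pixels; at least 5 are required")
    scale = labels.pixel_scale_mm
    # Pixel centres in mm; x runs along columns, y along rows.
    x = (cols + 0.5) * scale
    y = (rows + 0.5) * scale
    cx, cy = float(x.mean()), float(y.mean())
    # 1/12 is the variance of a unit square pixel footprint.
    cov = np.cov(np.vstack([x, y]), bias=True) + (scale**2 / 12.0) * np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    l_minor, l_major = float(evals[0]), float(evals[1])
    v = evecs[:, 1]
    theta = math.degrees(math.atan2(v[1], v[0])) % 180.0
    reliable = (l_major / max(l_minor, 1e-12)) >= ORIENTATION_EIGRATIO_MIN
    return RatEllipse(
        x_mm=cx, y_mm=cy,
        semi_major_mm=2.0 * math.sqrt(l_major),
        semi_minor_mm=2.0 * math.sqrt(l_minor),
        orientation_deg=theta,
        pixel_count=int(n),
        orientation_reliable=reliable,
    )


def track_identities(
    prev: tuple[RatEllipse, RatEllipse],
    curr: Sequence[RatEllipse],
) -> tuple[tuple[RatEllipse, RatEllipse], bool]:
    """Assign current-frame ellipses to the two identities of ``prev``.

    Two ellipses: the assignment (identity or swap) minimising summed
    centroid displacement wins.  One ellipse: the silhouettes merged, so
    both identities map to the single component and the frame is flagged
    as a contact frame.
    """
    if len(curr) == 1:
        return (curr[0], curr[0]), True
    if len(curr) != 2:
        raise SegmentationError("track_identities needs one or two ellipses")

    def dist(a: RatEllipse, b: RatEllipse) -> float:
        return math.hypot(a.x_mm - b.x_mm, a.y_mm - b.y_mm)

    straight = dist(prev[0], curr[0]) + dist(prev[1], curr[1])
    swapped = dist(prev[0], curr[1]) + dist(prev[1], curr[0])
    if swapped < straight:
        return (curr[1], curr[0]), False
    return (curr[0], curr[1]), False


def process_sequence(
    frames: Sequence[np.ndarray],
    pixel_scale_mm: float,
    threshold: float | str = "auto",
    body_length_mm: float = DEFAULT_BODY_LENGTH_MM,
    body_width_mm: float = DEFAULT_BODY_WIDTH_MM,
) -> pd.DataFrame:
    """Run the full chain over a frame sequence with identity tracking.

    Returns one row per (frame, rat_id) with the fitted ellipse in mm and
    a contact flag.  When an orientation is flagged unreliable, the
    previous frame's orientation for that identity is carried forward.
    """
    records: list[dict] = []
    prev_pair: tuple[RatEllipse, RatEllipse] | None = None
    last_theta = [None, None]  # type: list[float | None]
    for idx, frame in enumerate(frames):
        gray = to_grayscale(frame, pixel_scale_mm)
        mask = binarize(gray, threshold)
        labs = split_and_label(mask, body_length_mm, body_width_mm)
        ells = [fit_ellipse(labs, i) for i in range(1, labs.n_labels + 1)]
        if prev_pair is None:
            if len(ells) == 1:
                pair, contact = (ells[0], ells[0]), True
            else:
                pair, contact = (ells[0], ells[1]), False
        else:
            pair, contact = track_identities(prev_pair, ells)
        fixed = []
        for rid, e in enumerate(pair):
            if not e.orientation_reliable and last_theta[rid] is not None:
                e = replace(e, orientation_deg=last_theta[rid])
            else:
                last_theta[rid] = e.orientation_deg
            fixed.append(e)
            records.append(
                {
                    "frame": idx,
                    "rat_id": rid + 1,
                    "x_mm": e.x_mm,
                    "y_mm": e.y_mm,
                    "theta_deg": e.orientation_deg,
                    "semi_major_mm": e.semi_major_mm,
                    "semi_minor_mm": e.semi_minor_mm,
                    "pixel_count": e.pixel_count,
                    "contact_flag": contact,
                }
            )
        prev_pair = (fixed[0], fixed[1])
    return pd.DataFrame(records)
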