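"""Posture reduction, folding and 125-case binning."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ratsar import posture
from ratsar.segmentation import RatEllipse


def make_ellipse(x, y, theta, major=120.0, minor=23.0):
    return RatEllipse(x_mm=x, y_mm=y, semi_major_mm=major,
                      semi_minor_mm=minor, orientation_deg=theta % 180.0,
                      pixel_count=100)


# -- wavelength --------------------------------------------------------------

def test_wavelength_value():
    assert posture.wavelength(1.8e9) == pytest.approx(166.6667, abs=0.001)


def test_wavelength_rejects_nonpositive():
    with pytest.raises(ValueError):
        posture.wavelength(0.0)


# -- angle folding -----------------------------------------------------------

@given(st.floats(-720.0, 720.0, allow_nan=False))
def test_fold_angle_range(a):
    f = posture.fold_angle(a)
    assert 0.0 <= f <= 90.0


@given(st.floats(-720.0, 720.0, allow_nan=False))
def test_fold_angle_idempotent(a):
    f = posture.fold_angle(a)
    assert posture.fold_angle(f) == pytest.approx(f, abs=1e-9)


@given(st.floats(-360.0, 360.0, allow_nan=False))
def test_fold_angle_head_tail_period(a):
    assert posture.fold_angle(a + 180.0) == pytest.approx(
        posture.fold_angle(a), abs=1e-9)


@given(st.floats(-360.0, 360.0, allow_nan=False))
def test_fold_angle_mirror(a):
    assert posture.fold_angle(-a) == pytest.approx(
        posture.fold_angle(a), abs=1e-9)


def test_fold_angle_examples():
    assert posture.fold_angle(100.0) == pytest.approx(80.0)
    assert posture.fold_angle(270.0) == pytest.approx(90.0)
    assert posture.fold_angle(45.0) == pytest.approx(45.0)


# -- relative posture --------------------------------------------------------

def test_relative_posture_side_by_side():
    # Rat 1 spine along the image x-axis (theta = 0); rat 2 offset
    # perpendicular to the spine -> connecting line along local X, alpha 0.
    e1 = make_ellipse(100.0, 100.0, 0.0)
    e2 = make_ellipse(100.0, 180.0, 0.0)
    p = posture.relative_posture(e1, e2)
    assert p.d_mm == pytest.approx(80.0)
    assert p.alpha_deg == pytest.approx(0.0, abs=1e-9)
    assert p.beta_deg == pytest.approx(0.0, abs=1e-9)


def test_relative_posture_tip_to_tip():
    # Rat 2 displaced along rat 1's spine -> alpha folds to 90.
    e1 = make_ellipse(100.0, 100.0, 0.0)
    e2 = make_ellipse(350.0, 100.0, 90.0)
    p = posture.relative_posture(e1, e2)
    assert p.d_mm == pytest.approx(250.0)
    assert p.alpha_deg == pytest.approx(90.0)
    assert p.beta_deg == pytest.approx(90.0)


def test_relative_posture_symmetric_under_swap():
    # d and beta are symmetric in the two animals by construction.
    e1 = make_ellipse(100.0, 120.0, 30.0)
    e2 = make_ellipse(240.0, 200.0, 110.0)
    p12 = posture.relative_posture(e1, e2)
    p21 = posture.relative_posture(e2, e1)
    assert p12.d_mm == pytest.approx(p21.d_mm)
    assert p12.beta_deg == pytest.approx(p21.beta_deg)


def test_relative_posture_zero_distance():
    e = make_ellipse(50.0, 50.0, 10.0)
    p = posture.relative_posture(e, e)
    assert p.d_mm == 0.0
    assert p.alpha_deg == 0.0


def test_posture_pair_validation():
    with pytest.raises(ValueError):
        posture.PosturePair(d_mm=-1.0, alpha_deg=0.0, beta_deg=0.0)
    with pytest.raises(ValueError):
        posture.PosturePair(d_mm=1.0, alpha_deg=91.0, beta_deg=0.0)


# -- binning -----------------------------------------------------------------

def test_case_id_formula():
    assert posture.case_id_from_indices(0, 0, 0) == 1
    assert posture.case_id_from_indices(1, 0, 0) == 26
    assert posture.case_id_from_indices(4, 4, 4) == 125
    assert posture.case_id_from_indices(2, 3, 1) == 25 * 2 + 5 * 3 + 1 + 1


def test_case_id_rejects_out_of_range():
    with pytest.raises(ValueError):
        posture.case_id_from_indices(5, 0, 0)
    with pytest.raises(ValueError):
        posture.indices_from_case_id(0)
    with pytest.raises(ValueError):
        posture.indices_from_case_id(126)


def test_bin_edges_half_open():
    scheme = posture.BinningScheme()
    dd = scheme.delta_d_mm
    # Lower edge belongs to the bin, upper edge to the next.
    p_lo = posture.PosturePair(d_mm=dd, alpha_deg=22.5, beta_deg=0.0)
    b = posture.bin_posture(p_lo, scheme)
    assert (b.d_idx, b.alpha_idx) == (1, 1)
    p_hi = posture.PosturePair(d_mm=dd - 1e-9, alpha_deg=22.5 - 1e-9,
                               beta_deg=0.0)
    b = posture.bin_posture(p_hi, scheme)
    assert (b.d_idx, b.alpha_idx) == (0, 0)


def test_bin_top_edges_clamp():
    p = posture.PosturePair(d_mm=5000.0, alpha_deg=90.0, beta_deg=90.0)
    b = posture.bin_posture(p)
    assert (b.d_idx, b.alpha_idx, b.beta_idx) == (4, 4, 4)
    assert b.case_id == 125


def test_contact_forces_d_zero_bin():
    p = posture.PosturePair(d_mm=400.0, alpha_deg=50.0, beta_deg=10.0,
                            contact=True)
    b = posture.bin_posture(p)
    assert b.d_idx == 0


@given(st.integers(0, 4), st.integers(0, 4), st.integers(0, 4))
def test_bin_centres_round_trip(di, ai, bi):
    """A posture at a bin's interior maps back to that bin."""
    scheme = posture.BinningScheme()
    p = posture.PosturePair(
        d_mm=(di + 0.5) * scheme.delta_d_mm,
        alpha_deg=min((ai + 0.5) * 22.5, 90.0),
        beta_deg=min((bi + 0.5) * 22.5, 90.0),
    )
    b = posture.bin_posture(p, scheme)
    assert (b.d_idx, b.alpha_idx, b.beta_idx) == (di, ai, bi)


def test_case_label_examples():
    assert posture.case_label(1) == ("0", "0°", "0°")
    assert posture.case_label(125) == ("2λ", "90°", "90°")


# -- distribution ------------------------------------------------------------

def test_accumulate_distribution_counts():
    bins = [posture.CaseBin(0, 0, 0)] * 3 + [posture.CaseBin(4, 4, 4)]
    dist = posture.accumulate_distribution(bins)
    assert dist.frame_count == 4
    assert dist.weight(1) == pytest.approx(0.75)
    assert dist.weight(125) == pytest.approx(0.25)
    assert dist.weights.sum() == pytest.approx(1.0)


def test_accumulate_distribution_empty_raises():
    with pytest.raises(ValueError):
        posture.accumulate_distribution([])


def test_distribution_validation():
    w = np.zeros(125)
    with pytest.raises(ValueError):
        posture.PostureDistribution(weights=w, frame_count=0)  # sum != 1
    w[0] = 1.0
    d = posture.PostureDistribution(weights=w, frame_count=10)
    with pytest.raises(ValueError):
        d.weight(126)


def test_distribution_from_case_ids():
    dist = posture.distribution_from_case_ids([1, 1, 26, 125])
    assert dist.weight(26) == pytest.approx(0.25)


# -- table-level drivers -----------------------------------------------------

def test_postures_from_tracks_roundtrip():
    rows = []
    for frame, (x2, y2, t2, contact) in enumerate(
            [(100.0, 180.0, 0.0, False), (150.0, 100.0, 40.0, True)]):
        rows.append(dict(frame=frame, rat_id=1, x_mm=100.0, y_mm=100.0,
                         theta_deg=0.0, semi_major_mm=120.0,
                         semi_minor_mm=23.0, contact_flag=contact))
        rows.append(dict(frame=frame, rat_id=2, x_mm=x2, y_mm=y2,
                         theta_deg=t2, semi_major_mm=120.0,
                         semi_minor_mm=23.0, contact_flag=contact))
    out = posture.postures_from_tracks(pd.DataFrame(rows))
    assert list(out["frame"]) == [0, 1]
    assert out.loc[0, "d_mm"] == pytest.approx(80.0)
    assert out.loc[0, "alpha_deg"] == pytest.approx(0.0, abs=1e-9)
    assert bool(out.loc[1, "contact"])
    # Contact frame lands in the d = 0 super-case regardless of distance.
    di, _, _ = posture.indices_from_case_id(int(out.loc[1, "case_id"]))
    assert di == 0


def test_postures_from_tracks_rejects_bad_frame():
    df = pd.DataFrame([dict(frame=0, rat_id=1, x_mm=0.0, y_mm=0.0,
                            theta_deg=0.0, semi_major_mm=10.0,
                            semi_minor_mm=5.0, contact_flag=False)])
    with pytest.raises(ValueError):
        posture.postures_from_tracks(df)


def test_distribution_table_shape():
    dist = posture.distribution_from_case_ids([1])
    tab = posture.distribution_table(dist)
    assert len(tab) == 125
    assert tab["W"].sum() == pytest.approx(1.0)


def test_pipeline_distribution_properties(posture_distribution):
    dist, series = posture_distribution
    assert dist.weights.sum() == pytest.approx(1.0)
    assert (series["alpha_deg"].between(0, 90)).all()
    assert (series["beta_deg"].between(0, 90)).all()
    assert (series["d_mm"] >= 0).all()
    # Contact frames must sit in the d = 0 super-case.
    contact_cases = series.loc[series["contact"], "case_id"]
    assert (contact_cases <= 25).all()
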