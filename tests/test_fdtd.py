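"""FDTD solver: construction, verification ladder, SAR accounting.

The expensive configurations (distance sweeps, Rayleigh sphere, empty
scene) live in session fixtures shared with the acceptance tests; this
module holds the cheaper construction/validation properties plus the
angle-sweep physics.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ratsar import fdtd, synthetic

from conftest import SWEEP_GRID_MM


# -- materials and exposure --------------------------------------------------

def test_material_validation():
    with pytest.raises(ValueError):
        fdtd.Material(eps_r=0.5, sigma=1.0, rho=1000.0)
    with pytest.raises(ValueError):
        fdtd.Material(eps_r=4.0, sigma=-1.0, rho=1000.0)
    with pytest.raises(ValueError):
        fdtd.Material(eps_r=4.0, sigma=1.0, rho=0.0)


def test_muscle_two_thirds_constants():
    m = fdtd.MUSCLE_TWO_THIRDS
    assert (m.eps_r, m.sigma, m.rho) == (53.5, 1.34, 1040.0)


def test_exposure_defaults_and_amplitude():
    exp = fdtd.ExposureConfig()
    assert exp.frequency_hz == 1.8e9
    assert exp.power_density_w_m2 == 1.0
    # E0 = sqrt(2 S Z0) for peak amplitude at 1 W/m^2.
    assert exp.e0_v_m == pytest.approx(math.sqrt(2 * fdtd.Z0), rel=1e-12)
    assert exp.e0_v_m == pytest.approx(27.449, abs=0.001)
    assert fdtd.ExposureConfig(polarization="EHK").e_axis == "y"
    assert fdtd.ExposureConfig(polarization="HEK").e_axis == "x"
    with pytest.raises(ValueError):
        fdtd.ExposureConfig(polarization="KEH")


# -- geometry ----------------------------------------------------------------

def test_ellipsoid_volume_and_aabb():
    e = fdtd.Ellipsoid(center_mm=(0, 0, 0), semi_axes_mm=(23.4, 122.4, 23.4))
    assert e.volume_mm3 == pytest.approx(4 / 3 * math.pi * 23.4**2 * 122.4)
    hx, hy, hz = e.aabb_half_extents_mm
    assert (hx, hy, hz) == pytest.approx((23.4, 122.4, 23.4))
    # A 90-degree yaw swaps the in-plane extents.
    r = fdtd.Ellipsoid(center_mm=(0, 0, 0), semi_axes_mm=(23.4, 122.4, 23.4),
                       yaw_deg=90.0)
    hx, hy, hz = r.aabb_half_extents_mm
    assert (hx, hy) == pytest.approx((122.4, 23.4))


def test_ellipsoid_fill_fractions_interior_exterior():
    e = fdtd.Ellipsoid(center_mm=(0, 0, 0), semi_axes_mm=(10.0, 10.0, 10.0))
    xs = np.array([0.0, 50.0])
    f = e.fill_fractions(xs, np.array([0.0]), np.array([0.0]), step_mm=2.0)
    assert f[0, 0, 0] == pytest.approx(1.0)
    assert f[1, 0, 0] == 0.0


def test_build_scene_rejects_overlap():
    a = fdtd.Ellipsoid(center_mm=(0, 0, 0), semi_axes_mm=(10, 10, 10))
    b = fdtd.Ellipsoid(center_mm=(5, 0, 0), semi_axes_mm=(10, 10, 10))
    with pytest.raises(fdtd.OverlapError):
        fdtd.build_scene([a, b], fdtd.MUSCLE_TWO_THIRDS, 2.0)


def test_scene_requires_pml_clearance():
    shape = (40, 40, 40)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[2, 20, 20] = 1  # inside the 7-cell PML margin
    with pytest.raises(ValueError):
        fdtd.Scene(grid_step_mm=2.0, eps_r=np.ones(shape),
                   sigma=np.zeros(shape), rho=np.full(shape, fdtd.RHO_AIR),
                   labels=labels)


def test_scene_rejects_tiny_domain():
    shape = (10, 10, 10)
    with pytest.raises(ValueError):
        fdtd.Scene(grid_step_mm=2.0, eps_r=np.ones(shape),
                   sigma=np.zeros(shape), rho=np.full(shape, fdtd.RHO_AIR),
                   labels=np.zeros(shape, dtype=np.uint8))


def test_snap_to_whole_cells():
    assert fdtd._snap(83.3, 4.0) == pytest.approx(84.0)
    assert fdtd._snap(166.7, 4.0) == pytest.approx(168.0)
    assert fdtd._snap(0.3, 4.0) == pytest.approx(4.0)  # never collapses to 0


# -- subpixel edge materials -------------------------------------------------

def test_subpixel_edge_materials_bounds():
    scene = synthetic.build_phantom_scene(166.7, 0.0, 0.0, grid_step_mm=4.0)
    mats = fdtd.subpixel_edge_materials(scene, 1.8e9)
    assert set(mats) == {"ex", "ey", "ez"}
    for comp, (eps_e, sig_e, owner) in mats.items():
        assert np.all(eps_e >= 1.0)
        assert np.all(sig_e >= 0.0)
        # The smoothed values never exceed the bulk tissue values.
        assert np.all(eps_e <= fdtd.MUSCLE_TWO_THIRDS.eps_r + 1e-9)
        assert set(np.unique(owner)) <= {0, 1, 2}
        # Deep-interior edges carry the bulk material; far-away edges air.
        assert np.isclose(eps_e.max(), fdtd.MUSCLE_TWO_THIRDS.eps_r)
        assert eps_e.flat[0] == pytest.approx(1.0)
        assert sig_e.flat[0] == 0.0


def test_edge_owner_matches_labels():
    scene = synthetic.build_phantom_scene(166.7, 0.0, 0.0, grid_step_mm=4.0)
    mats = fdtd.subpixel_edge_materials(scene, 1.8e9)
    _, _, owner = mats["ey"]
    assert (owner == 1).any() and (owner == 2).any()


# -- representative case geometry --------------------------------------------

def test_case_geometry_merged_block():
    for cid in (1, 13, 25):
        geo = fdtd.case_geometry(cid)
        assert geo["merged"]
        assert geo["d_mm"] == pytest.approx(2 * 23.4)


def test_case_geometry_lower_edges():
    geo = fdtd.case_geometry(26, grid_step_mm=4.0)  # (d=0.5 lambda, 0, 0)
    assert not geo["merged"]
    assert geo["d_mm"] == pytest.approx(84.0)  # 83.35 snapped to whole cells
    assert geo["alpha_deg"] == 0.0 and geo["beta_deg"] == 0.0
    assert not geo["adjusted"]
    geo = fdtd.case_geometry(25 * 1 + 5 * 2 + 3 + 1, grid_step_mm=4.0)
    assert geo["alpha_deg"] == pytest.approx(45.0)
    assert geo["beta_deg"] == pytest.approx(67.5)


def test_case_geometry_pushes_out_infeasible_pose():
    # (d = 0.5 lambda, alpha = 90): phantom 2 sits on phantom 1's spine
    # axis where rigid ellipsoids interpenetrate; the distance must be
    # pushed outward to the closest feasible whole-cell separation.
    cid = 25 * 1 + 5 * 4 + 0 + 1
    geo = fdtd.case_geometry(cid, grid_step_mm=4.0)
    assert geo["adjusted"]
    assert geo["d_mm"] > 84.0
    synthetic.build_phantom_scene(geo["d_mm"], geo["alpha_deg"],
                                  geo["beta_deg"], grid_step_mm=4.0)


def test_case_geometry_rejects_bad_id():
    with pytest.raises(ValueError):
        fdtd.case_geometry(0)


# -- solver validation -------------------------------------------------------

def test_run_fdtd_rejects_bad_courant():
    scene = fdtd.empty_scene((30, 30, 30), 4.0)
    with pytest.raises(ValueError):
        fdtd.run_fdtd(scene, fdtd.ExposureConfig(), courant=0.8)


def test_empty_scene_converges(empty_scene_solution):
    _, sol = empty_scene_solution
    assert sol.converged


# -- PEC standing wave -------------------------------------------------------

def test_pec_standing_wave_null_spacing():
    """Reflection off a PEC sheet forms nulls spaced lambda/2.

    The TF/SF aperture is finite, so diffraction shifts and shallows the
    pattern unless the domain is several wavelengths wide; this uses a
    384 mm x 384 mm cross-section at 6 mm resolution and asserts the
    spacing of interior nulls to within 1.5 cells.
    """
    step = 6.0
    scene = fdtd.empty_scene((64, 64, 60), step, pec_z_index=12)
    sol = fdtd.run_fdtd(scene, fdtd.ExposureConfig(polarization="EHK"))
    e2 = sol.cell_e2()
    prof = e2[e2.shape[0] // 2, e2.shape[1] // 2, :]
    lo, hi = 14, 51  # above the sheet, below the TF/SF top + PML
    mins = [k for k in range(lo, hi - 1)
            if prof[k] < prof[k - 1] and prof[k] <= prof[k + 1]]
    assert len(mins) >= 2
    expected = fdtd.ExposureConfig().wavelength_mm / (2 * step)
    for gap in np.diff(mins):
        assert abs(gap - expected) <= 1.5
    # Constructive antinodes exceed the incident amplitude.
    assert math.sqrt(prof[lo:hi].max()) > fdtd.ExposureConfig().e0_v_m


# -- SAR accounting on a solved pair -----------------------------------------

@pytest.fixture(scope="module")
def contact_run():
    scene = synthetic.build_contact_scene(grid_step_mm=SWEEP_GRID_MM)
    sol = fdtd.run_fdtd(scene, fdtd.ExposureConfig(polarization="EHK"))
    return scene, sol, fdtd.compute_sar(sol, scene)


def test_sar_result_structure(contact_run):
    scene, _, res = contact_run
    assert set(res.wb_avg_sar) == {1, 2}
    assert np.all(res.sar >= 0.0)
    for lbl in (1, 2):
        assert res.wb_avg_sar[lbl] > 0
        assert res.wb_avg_sar[lbl] == pytest.approx(
            res.absorbed_power_w[lbl] / res.phantom_mass_kg[lbl])
        assert res.phantom_mass_kg[lbl] == pytest.approx(
            scene.phantom_mass_kg(lbl))


def test_energy_sanity(contact_run):
    """Total absorbed power cannot exceed the power incident on the domain."""
    scene, sol, res = contact_run
    nx, ny, _ = scene.shape
    area = nx * ny * (scene.grid_step_mm * 1e-3) ** 2
    incident = fdtd.ExposureConfig().power_density_w_m2 * area
    total = sum(res.absorbed_power_w.values())
    assert 0 < total < incident
    assert fdtd.total_absorbed_power(sol, scene) == pytest.approx(total,
                                                                  rel=1e-6)


def test_contact_pair_symmetry(contact_run):
    _, _, res = contact_run
    s1, s2 = res.wb_avg_sar[1], res.wb_avg_sar[2]
    assert abs(s1 - s2) / s1 < 0.01


# -- angle sweeps ------------------------------------------------------------

@pytest.fixture(scope="module")
def alpha_pair():
    exp = fdtd.ExposureConfig(polarization="EHK")
    return fdtd.sweep_alpha([45.0, 225.0], exp, grid_step_mm=SWEEP_GRID_MM)


def test_alpha_point_symmetry(alpha_pair):
    """Swapping the neighbour to the opposite side (alpha + 180) leaves
    the mirror-symmetric pair's absorption unchanged (within 2%)."""
    s = alpha_pair.set_index("alpha_deg")["sar_1"]
    assert abs(s[45.0] - s[225.0]) / s[45.0] < 0.02
    assert (alpha_pair["sar_1"] > 0).all()
    assert (alpha_pair["sar_2"] > 0).all()


@pytest.fixture(scope="module")
def beta_runs():
    ehk = fdtd.ExposureConfig(polarization="EHK")
    hek = fdtd.ExposureConfig(polarization="HEK")
    return {
        "EHK": fdtd.sweep_beta([0.0, 90.0], ehk, grid_step_mm=SWEEP_GRID_MM),
        "HEK": fdtd.sweep_beta([0.0, 90.0], hek, grid_step_mm=SWEEP_GRID_MM),
    }


def test_beta_rat2_max_aligned_with_e(beta_runs):
    """Rat 2 absorbs most when its long axis is parallel to E: beta = 0
    under EHK (E along rat 1's spine), beta = 90 under HEK."""
    ehk = beta_runs["EHK"].set_index("beta_deg")["sar_2"]
    hek = beta_runs["HEK"].set_index("beta_deg")["sar_2"]
    assert ehk[0.0] > ehk[90.0]
    assert hek[90.0] > hek[0.0]


def test_beta_affects_rat1(beta_runs):
    """The neighbour's spin angle changes rat 1's absorption too."""
    ehk = beta_runs["EHK"].set_index("beta_deg")["sar_1"]
    assert ehk[0.0] != pytest.approx(ehk[90.0], rel=1e-4)
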