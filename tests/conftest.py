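"""Shared fixtures.

The expensive FDTD runs are session-scoped so each configuration is
solved once and shared between the property suite and the acceptance
tests.  Everything here is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from ratsar import fdtd, posture, segmentation, synthetic

# Coarse grid used for the two-phantom sweeps: 4 mm keeps a full
# eight-point distance sweep within the test-time budget while resolving
# the wavelength with ~42 cells.
SWEEP_GRID_MM = 4.0
LAMBDA_MM = fdtd.ExposureConfig().wavelength_mm
#: Sampled separations, as multiples of the wavelength (spacing 0.25).
D_OVER_LAMBDA = [0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25]


@pytest.fixture(scope="session")
def ehk_exposure() -> fdtd.ExposureConfig:
    return fdtd.ExposureConfig(polarization="EHK")


@pytest.fixture(scope="session")
def hek_exposure() -> fdtd.ExposureConfig:
    return fdtd.ExposureConfig(polarization="HEK")


@pytest.fixture(scope="session")
def ehk_reference(ehk_exposure) -> float:
    return fdtd.single_rat_reference(ehk_exposure, grid_step_mm=SWEEP_GRID_MM)


@pytest.fixture(scope="session")
def hek_reference(hek_exposure) -> float:
    return fdtd.single_rat_reference(hek_exposure, grid_step_mm=SWEEP_GRID_MM)


@pytest.fixture(scope="session")
def ehk_distance_sweep(ehk_exposure):
    ds = [k * LAMBDA_MM for k in D_OVER_LAMBDA]
    return fdtd.sweep_distance(ds, ehk_exposure, grid_step_mm=SWEEP_GRID_MM)


@pytest.fixture(scope="session")
def hek_distance_sweep(hek_exposure):
    ds = [k * LAMBDA_MM for k in D_OVER_LAMBDA]
    return fdtd.sweep_distance(ds, hek_exposure, grid_step_mm=SWEEP_GRID_MM)


# -- Rayleigh sphere oracle --------------------------------------------------

#: Small-sphere oracle configuration: radius well below lambda/10 inside
#: the dielectric, modest permittivity and loss so the quasi-static
#: uniform-interior-field solution is accurate.
SPHERE_RADIUS_MM = 5.0
SPHERE_MATERIAL = fdtd.Material(eps_r=4.0, sigma=0.05, rho=1000.0)


def rayleigh_sphere_sar(exposure: fdtd.ExposureConfig,
                        material: fdtd.Material = SPHERE_MATERIAL) -> float:
    """Quasi-static WB-avgSAR of a small lossy dielectric sphere.

    The interior field of a sphere small against the wavelength is
    uniform: E_in = 3 E0 / (eps* + 2) with the complex relative
    permittivity eps* = eps_r + sigma/(j omega eps0), so
    SAR = sigma |E_in|^2 / (2 rho).
    """
    omega = 2.0 * np.pi * exposure.frequency_hz
    eps_c = material.eps_r + material.sigma / (1j * omega * fdtd.EPS0)
    e_in = 3.0 * exposure.e0_v_m / abs(eps_c + 2.0)
    return material.sigma * e_in**2 / (2.0 * material.rho)


def solve_sphere(grid_step_mm: float,
                 exposure: fdtd.ExposureConfig) -> float:
    sphere = fdtd.Ellipsoid(center_mm=(0.0, 0.0, 0.0),
                            semi_axes_mm=(SPHERE_RADIUS_MM,) * 3)
    scene = fdtd.build_scene([sphere], SPHERE_MATERIAL, grid_step_mm,
                             margin_cells=10)
    sol = fdtd.run_fdtd(scene, exposure)
    return fdtd.compute_sar(sol, scene).wb_avg_sar[1]


@pytest.fixture(scope="session")
def sphere_sar_by_grid(ehk_exposure) -> dict[float, float]:
    """FDTD sphere WB-avgSAR at the two acceptance grid steps."""
    return {h: solve_sphere(h, ehk_exposure) for h in (1.0, 0.5)}


# -- empty-scene incident field ----------------------------------------------

@pytest.fixture(scope="session")
def empty_scene_solution(ehk_exposure):
    scene = fdtd.empty_scene((40, 40, 40), grid_step_mm=4.0)
    return scene, fdtd.run_fdtd(scene, ehk_exposure)


# -- segmentation parameter-recovery run (matches scripts/acceptance.py) -----

@pytest.fixture(scope="session")
def acceptance_module():
    """scripts/acceptance.py loaded as a module, so the tests exercise
    exactly the code the standalone script runs."""
    import importlib.util
    from pathlib import Path

    path = Path(__file__).resolve().parents[1] / "scripts" / "acceptance.py"
    spec = importlib.util.spec_from_file_location("acceptance_script", path)
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture(scope="session")
def acceptance_results(acceptance_module) -> dict:
    return acceptance_module.run(seed=1)


# -- small tracked synthetic sequence for pipeline tests ---------------------

@pytest.fixture(scope="session")
def tracked_sequence():
    """A short seeded recording with contact episodes, fully tracked."""
    cfg = synthetic.GeneratorConfig(n_frames=40, seed=7, contact_affinity=0.8)
    frames, truth = synthetic.generate_sequence(cfg)
    tracks = segmentation.process_sequence(frames, cfg.pixel_scale_mm)
    return cfg, frames, truth, tracks


@pytest.fixture(scope="session")
def posture_distribution(tracked_sequence):
    _, _, _, tracks = tracked_sequence
    series = posture.postures_from_tracks(tracks)
    return posture.distribution_from_case_ids(series["case_id"]), series
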