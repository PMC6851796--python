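"""X-ray projection and the dose-noise model."""

import numpy as np
import pytest

from fluospect import Geometry
from fluospect.exceptions import InvalidInputError, InvalidParameterError
from fluospect.fluoro import (NoiseModel, add_fluoro_noise,
                              line_integrals_to_intensity, project_xray,
                              simulate_fluoro_acquisition)
from fluospect.phantom import build_phantom
from fluospect.respiration import BreathingPattern, generate_breathing_signal


def test_zero_attenuation_projects_to_zero(small_geometry):
    img = project_xray(np.zeros(small_geometry.grid_dims), 33.0,
                       small_geometry)
    assert not np.any(img)


def test_uniform_slab_line_integral():
    geom = Geometry((20, 20, 10), 10.0, 4)   # 1 cm voxels
    mu = np.zeros(geom.grid_dims)
    mu[:, 5:15, :] = 0.2                     # 10 cm slab normal to the ray
    img = project_xray(mu, 0.0, geom)
    assert img[5, 10] == pytest.approx(2.0, abs=1e-12)


def test_negative_attenuation_rejected(small_geometry):
    mu = np.zeros(small_geometry.grid_dims)
    mu[0, 0, 0] = -1.0
    with pytest.raises(InvalidInputError):
        project_xray(mu, 0.0, small_geometry)


def test_opposed_views_mirror():
    geom = Geometry((24, 24, 12), 8.0, 8)
    ph = build_phantom(150.0, 2.0, geom.grid_dims, 8.0)
    a = project_xray(ph.attenuation_xray, 30.0, geom)
    b = project_xray(ph.attenuation_xray, 210.0, geom)
    np.testing.assert_allclose(b, a[:, ::-1], atol=1e-6)


def test_projection_matches_per_ray_oracle():
    """Brute-force bilinear ray summation on an 8x8x8 grid."""
    rng = np.random.default_rng(5)
    vol = rng.random((8, 8, 8))
    geom = Geometry((8, 8, 8), 10.0, 4)
    angle = 27.0
    img = project_xray(vol, angle, geom)

    th = np.deg2rad(angle)
    c = 3.5
    oracle = np.zeros((8, 8))
    for u in range(8):          # detector column = rotated x
        for yo in range(8):     # sample along the ray
            sx = np.cos(th) * (u - c) - np.sin(th) * (yo - c) + c
            sy = np.sin(th) * (u - c) + np.cos(th) * (yo - c) + c
            x0, y0 = int(np.floor(sx)), int(np.floor(sy))
            fx, fy = sx - x0, sy - y0
            for dx, wx in ((0, 1 - fx), (1, fx)):
                for dy, wy in ((0, 1 - fy), (1, fy)):
                    xi, yi = x0 + dx, y0 + dy
                    if 0 <= xi < 8 and 0 <= yi < 8 and wx * wy:
                        oracle[u, :] += wx * wy * vol[xi, yi, :]
    oracle = oracle.T[::-1, :]   # to detector orientation (row 0 superior)
    np.testing.assert_allclose(img, oracle * 1.0, atol=1e-10)


def test_intensity_examples():
    m = NoiseModel(reference_flux=2000.0, reference_dose_ugy=1.0)
    li = np.zeros((4, 4))
    assert line_integrals_to_intensity(li, 1.0, m)[0, 0] \
        == pytest.approx(2000.0)
    one = line_integrals_to_intensity(np.full((2, 2), 0.3), 1.0, m)
    two = line_integrals_to_intensity(np.full((2, 2), 0.3), 2.0, m)
    np.testing.assert_allclose(two, 2.0 * one)
    assert line_integrals_to_intensity(np.array([[np.log(2.0)]]), 1.0,
                                       m)[0, 0] == pytest.approx(1000.0)
    with pytest.raises(InvalidParameterError):
        line_integrals_to_intensity(li, 0.0, m)


def test_noise_free_model_is_identity():
    m = NoiseModel(sigma0=0.0, c=0.0)
    img = np.full((100, 100), 37.0)
    np.testing.assert_array_equal(add_fluoro_noise(img, m, seed=1), img)


def test_noise_standard_deviation():
    m = NoiseModel(sigma0=2.0, c=0.5)
    img = np.full((400, 256), 400.0)        # sigma = 2 + 0.5*20 = 12
    out = add_fluoro_noise(img, m, seed=2)
    assert out.std() == pytest.approx(12.0, abs=0.2)
    assert out.mean() == pytest.approx(400.0, rel=0.005)


def test_relative_noise_halves_when_dose_quadruples():
    m = NoiseModel(sigma0=0.0, c=1.0)
    lo = add_fluoro_noise(np.full((400, 256), 100.0), m, seed=3)
    hi = add_fluoro_noise(np.full((400, 256), 400.0), m, seed=3)
    ratio = (lo.std() / lo.mean()) / (hi.std() / hi.mean())
    assert ratio == pytest.approx(2.0, rel=0.03)


def test_noise_determinism():
    m = NoiseModel()
    img = np.full((50, 50), 200.0)
    np.testing.assert_array_equal(add_fluoro_noise(img, m, seed=7),
                                  add_fluoro_noise(img, m, seed=7))


def test_noise_parameter_recovery_from_flat_fields():
    """Fitting sigma vs sqrt(mu) over a dose sweep recovers (sigma0, c)."""
    m = NoiseModel(sigma0=2.0, c=1.0)
    mus, sds = [], []
    for i, dose in enumerate((0.05, 0.2, 0.8, 3.2)):
        mu = m.flux_at(dose)
        out = add_fluoro_noise(np.full((400, 256), mu), m, seed=10 + i)
        mus.append(mu)
        sds.append(out.std())
    coef = np.polyfit(np.sqrt(mus), sds, 1)
    assert coef[0] == pytest.approx(m.c, rel=0.05)
    assert coef[1] == pytest.approx(m.sigma0, rel=0.05)


def test_acquisition_frame_schedule(small_geometry):
    ph = build_phantom(150.0, 5.0, small_geometry.grid_dims, 12.0)
    sig = generate_breathing_signal(BreathingPattern(), 60.0, 5.0)
    fset = simulate_fluoro_acquisition(ph, sig, small_geometry, 5.0, 100.0,
                                       NoiseModel(), seed=0)
    assert fset.n_frames == 300
    assert fset.dose_per_frame_ugy == pytest.approx(100.0 / 300)
    assert np.all(np.diff(fset.timestamps_s) == pytest.approx(0.2))
    # step-and-shoot: angles nondecreasing, all scheduled angles visited
    assert np.all(np.diff(fset.angle_indices) >= 0)
    assert len(np.unique(fset.angle_indices)) == small_geometry.n_angles
    with pytest.raises(InvalidParameterError):
        simulate_fluoro_acquisition(ph, sig, small_geometry, 5.0, 0.0,
                                    NoiseModel(), seed=0)


def test_static_signal_gives_identical_frames(small_geometry):
    ph = build_phantom(150.0, 5.0, small_geometry.grid_dims, 12.0)
    sig = generate_breathing_signal(BreathingPattern(), 30.0, 5.0)
    sig.diaphragm_cm[:] = 0.0
    m = NoiseModel(sigma0=0.0, c=0.0)
    fset = simulate_fluoro_acquisition(ph, sig, small_geometry, 5.0, 100.0,
                                       m, seed=0)
    sel = fset.angle_indices == fset.angle_indices[0]
    frames = fset.frames[sel]
    for f in frames[1:]:
        np.testing.assert_array_equal(f, frames[0])
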