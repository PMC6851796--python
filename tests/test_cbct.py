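"""OS-SART CBCT reconstruction and motion-vector-field estimation."""

import numpy as np
import pytest

from fluospect import Geometry
from fluospect.cbct import (MotionVectorField, build_mvf,
                            default_search_boxes, estimate_diaphragm_shift,
                            estimate_sternum_shift, log_transform,
                            perturb_mvf, reconstruct_bin, smooth_mvf)
from fluospect.exceptions import EmptyBinError
from fluospect.fluoro import (NoiseModel, line_integrals_to_intensity,
                              project_xray)
from fluospect.phantom import (build_phantom, ground_truth_displacement,
                               warp_volume)


@pytest.fixture(scope="module")
def geom():
    return Geometry((32, 32, 24), 12.0, 30)


@pytest.fixture(scope="module")
def phantom(geom):
    return build_phantom(150.0, 5.0, geom.grid_dims, geom.voxel_size_mm)


def test_log_transform_examples():
    frame = np.full((4, 4), 1000.0)
    assert not np.any(log_transform(frame, 1000.0))
    assert log_transform(frame / 2, 1000.0)[0, 0] \
        == pytest.approx(np.log(2.0))


def test_log_transform_roundtrip():
    m = NoiseModel()
    li = np.linspace(0.0, 4.0, 16).reshape(4, 4)
    intensity = line_integrals_to_intensity(li, 1.0, m)
    back = log_transform(intensity, m.flux_at(1.0))
    np.testing.assert_allclose(back, li, atol=1e-9)


def test_zero_projections_reconstruct_to_zero(geom):
    sino = {a: np.zeros(geom.det_shape) for a in range(geom.n_angles)}
    vol = reconstruct_bin(sino, geom, n_iterations=3)
    assert not np.any(vol)


def test_empty_bin_raises(geom):
    with pytest.raises(EmptyBinError):
        reconstruct_bin({}, geom)


def test_ossart_selfconsistency_and_residual(geom, phantom):
    """Noise-free projections: residual decreases, nRMSE small."""
    mu = phantom.attenuation_xray
    sino = {a: project_xray(mu, geom.angles_deg[a], geom)
            for a in range(geom.n_angles)}
    hist = []
    vol = reconstruct_bin(sino, geom, n_iterations=20,
                          residual_history=hist)
    assert all(b <= a * (1 + 1e-9) for a, b in zip(hist, hist[1:]))
    nrmse = np.sqrt(np.mean((vol - mu) ** 2)) / (mu.max() - mu.min())
    assert nrmse < 0.08    # tighter bound checked at desk scale


def test_shift_identical_volumes_zero(phantom):
    dia, st = default_search_boxes(phantom)
    ref = phantom.attenuation_xray
    assert estimate_diaphragm_shift(ref, ref, dia, 12.0).shift_mm \
        == pytest.approx(0.0, abs=1e-6)
    assert estimate_sternum_shift(ref, ref, st, 12.0).shift_mm \
        == pytest.approx(0.0, abs=1e-6)


def test_shift_synthetic_integer_rolls(phantom):
    dia, st = default_search_boxes(phantom)
    ref = phantom.attenuation_xray
    rolled = np.roll(ref, -1, axis=2)      # 1 voxel inferior
    est = estimate_diaphragm_shift(ref, rolled, dia, 12.0)
    assert est.shift_mm == pytest.approx(12.0, abs=1.5)
    rolled_y = np.roll(ref, -1, axis=1)    # 1 voxel anterior
    est2 = estimate_sternum_shift(ref, rolled_y, st, 12.0)
    assert est2.shift_mm == pytest.approx(12.0, abs=6.0)


def test_shift_exact_in_the_limit(desk_phantom):
    """Analytically warped volumes: sub-voxel estimation accuracy."""
    dia, st = default_search_boxes(desk_phantom)
    ref = desk_phantom.attenuation_xray
    for d_cm in (0.5, 1.0, 1.7):
        f = ground_truth_displacement(desk_phantom, d_cm, 0.6 * d_cm)
        warped = warp_volume(ref, f)
        de = estimate_diaphragm_shift(ref, warped, dia, 6.0)
        se = estimate_sternum_shift(ref, warped, st, 6.0)
        assert de.reliable and se.reliable
        assert abs(de.shift_mm - 10.0 * d_cm) < 0.3 * 6.0
        assert abs(se.shift_mm - 6.0 * d_cm) < 0.3 * 6.0


def test_build_mvf_values(desk_phantom):
    ph = desk_phantom
    mvf = build_mvf([0.0, 10.0], [0.0, 6.0], ph)
    assert not np.any(mvf.forward_mm[0])
    assert not np.any(mvf.inverse_mm[0])
    liver = ph.masks["liver"]
    idx = tuple(int(round(c.mean())) for c in np.nonzero(liver))
    assert mvf.forward_mm[1][idx + (2,)] == pytest.approx(10.0)
    assert mvf.forward_mm[1][idx + (0,)] == 0.0
    spine_idx = np.nonzero(ph.masks["spine"])
    assert not np.any(mvf.forward_mm[1][spine_idx])
    np.testing.assert_allclose(mvf.inverse_mm[1], -mvf.forward_mm[1])


def test_mvf_forward_inverse_composition(desk_phantom):
    ph = desk_phantom
    mvf = build_mvf([0.0, 8.0, 17.0], [0.0, 4.0, 10.0], ph)
    liver = ph.masks["liver"]
    p = np.array([int(round(c.mean())) for c in np.nonzero(liver)], float)
    for b in range(mvf.n_bins):
        d1 = mvf.forward_mm[b][tuple(p.astype(int))] / 6.0
        p2 = np.clip(np.round(p + d1).astype(int), 0,
                     np.array(ph.grid_dims) - 1)
        d2 = mvf.inverse_mm[b][tuple(p2)] / 6.0
        assert np.linalg.norm(d1 + d2) < 1.0


def _toy_mvf(field_shape=(2, 8, 8, 8, 3)):
    fwd = np.zeros(field_shape)
    return MotionVectorField(forward_mm=fwd, inverse_mm=fwd.copy(),
                             diaphragm_shift_mm=np.zeros(field_shape[0]),
                             sternum_shift_mm=np.zeros(field_shape[0]),
                             voxel_size_mm=6.0)


def test_smooth_mvf_uniform_field_unchanged():
    mvf = _toy_mvf((3, 8, 8, 8, 3))
    mvf.forward_mm[1, ..., 2] = 5.0
    mvf.forward_mm[2, ..., 2] = 5.0
    out = smooth_mvf(mvf)
    # spatially uniform: spatial filter is a no-op; temporal mean mixes bins
    np.testing.assert_allclose(out.forward_mm[1, ..., 2], 10.0 / 3.0)
    assert not np.any(out.forward_mm[0])


def test_smooth_mvf_temporal_center_of_arithmetic_sequence():
    mvf = _toy_mvf((3, 8, 8, 8, 3))
    mvf.forward_mm[1, ..., 2] = 6.0
    mvf.forward_mm[2, ..., 2] = 12.0
    out = smooth_mvf(mvf)
    np.testing.assert_allclose(out.forward_mm[1, ..., 2], 6.0)


def test_smooth_mvf_spatial_spike():
    mvf = _toy_mvf((2, 9, 9, 9, 3))
    mvf.forward_mm[1, 4, 4, 4, 2] = 9.0
    out = smooth_mvf(mvf)   # 2 bins: temporal pass skipped
    assert out.forward_mm[1, 4, 4, 4, 2] == pytest.approx(9.0 / 27.0)


def test_perturb_mvf(desk_phantom):
    mvf = build_mvf([0.0, 10.0, 20.0], [0.0, 6.0, 12.0], desk_phantom)
    same = perturb_mvf(mvf, 0.0, 0.0)
    np.testing.assert_allclose(same.forward_mm, mvf.forward_mm)
    pert = perturb_mvf(mvf, 2.0, 1.0)
    assert pert.diaphragm_shift_mm[2] == pytest.approx(18.0)
    assert pert.diaphragm_shift_mm[1] == pytest.approx(9.0)
    assert pert.sternum_shift_mm[2] == pytest.approx(11.0)
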