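"""Phantom construction and the analytic respiratory deformation."""

import numpy as np
import pytest

from fluospect.exceptions import ShapeError
from fluospect.phantom import (DisplacementField, build_phantom,
                               ground_truth_displacement, phantom_at_amplitude,
                               warp_volume)
from fluospect.respiration import BreathingPattern


def _centroid(mask, axis):
    idx = np.nonzero(mask)
    return idx[axis].mean()


def test_default_grid_and_activity():
    ph = build_phantom()
    assert ph.grid_dims == (128, 128, 100)
    assert ph.voxel_size_mm == 4.7
    assert ph.activity.sum() == pytest.approx(150e6, rel=1e-3)


def test_uptake_ratio_and_masks(desk_phantom):
    ph = desk_phantom
    sphere = ph.masks["sphere"]
    bg = ph.masks["liver"] & ~sphere
    assert ph.activity[sphere].mean() / ph.activity[bg].mean() \
        == pytest.approx(5.0, rel=1e-9)
    assert ph.activity.sum() == pytest.approx(150e6, rel=1e-3)
    # containment relations
    assert np.all(ph.masks["liver"][sphere])
    for organ in ("lungs", "liver", "spine"):
        assert np.all(ph.masks["body"][ph.masks[organ]])
    # activity only in the liver
    assert ph.activity[~ph.masks["liver"]].sum() == 0
    assert np.all(ph.activity >= 0)


def test_unit_uptake_is_uniform():
    ph = build_phantom(150.0, 1.0, (32, 32, 24), 12.0)
    liver_vals = ph.activity[ph.masks["liver"]]
    assert np.allclose(liver_vals, liver_vals[0])


def test_attenuation_ordering(desk_phantom):
    ph = desk_phantom
    lungs, spine = ph.masks["lungs"], ph.masks["spine"]
    soft = ph.masks["body"] & ~lungs & ~spine & ~ph.masks["sternum"]
    for att in (ph.attenuation_140kev, ph.attenuation_xray):
        assert att[lungs].mean() < att[soft].mean() < att[spine].mean()
        assert att[lungs].mean() == pytest.approx(0.25 * att[soft].mean(),
                                                  rel=0.01)


def test_zero_amplitude_field_is_zero(desk_phantom):
    f = ground_truth_displacement(desk_phantom, 0.0, 0.0)
    assert not np.any(f.vectors_mm)


def test_field_values(desk_phantom):
    ph = desk_phantom
    f = ground_truth_displacement(ph, 2.0, 1.2)
    liver = ph.masks["liver"]
    ci = tuple(int(round(_centroid(liver, a))) for a in range(3))
    assert f.vectors_mm[ci + (2,)] == pytest.approx(20.0)
    # spine fixed
    assert not np.any(f.vectors_mm[ph.masks["spine"]])
    # anterior body-surface voxel carries the full AP shift
    iy_front = np.nonzero(ph.masks["body"].any(axis=(0, 2)))[0][0]
    assert f.vectors_mm[ci[0], iy_front, ci[2], 1] \
        == pytest.approx(12.0, abs=0.5)


def test_field_linearity(desk_phantom):
    f1 = ground_truth_displacement(desk_phantom, 0.8, 0.48).vectors_mm
    f2 = ground_truth_displacement(desk_phantom, 1.6, 0.96).vectors_mm
    np.testing.assert_allclose(f2, 2.0 * f1, atol=1e-9)


def test_warp_identity(desk_phantom):
    ph = desk_phantom
    f = ground_truth_displacement(ph, 0.0, 0.0)
    np.testing.assert_array_equal(warp_volume(ph.activity, f), ph.activity)


def test_warp_integer_impulse_shift():
    vol = np.zeros((16, 16, 16))
    vol[8, 8, 8] = 1.0
    vec = np.zeros((16, 16, 16, 3))
    vec[..., 2] = 2 * 6.0          # read 2 voxels superior -> move inferior
    f = DisplacementField(vec, 6.0)
    out = warp_volume(vol, f, interpolation="nearest")
    assert out[8, 8, 6] == 1.0
    assert out.sum() == 1.0


def test_warp_roundtrip_uniform_translation():
    rng = np.random.default_rng(0)
    vol = rng.random((16, 16, 16))
    vec = np.zeros((16, 16, 16, 3))
    vec[..., 0] = 3 * 6.0
    fwd = DisplacementField(vec, 6.0)
    inv = DisplacementField(-vec, 6.0)
    out = warp_volume(warp_volume(vol, fwd), inv)
    interior = out[4:12, :, :]      # border voxels read zeros, exclude them
    np.testing.assert_allclose(interior, vol[4:12, :, :], atol=1e-9)


def test_warp_shape_mismatch():
    f = DisplacementField(np.zeros((8, 8, 8, 3)), 6.0)
    with pytest.raises(ShapeError):
        warp_volume(np.zeros((9, 8, 8)), f)


def test_pose_at_zero_amplitude(desk_phantom):
    act, a140, ax = phantom_at_amplitude(desk_phantom, 0.0,
                                         BreathingPattern())
    np.testing.assert_array_equal(act, desk_phantom.activity)
    np.testing.assert_array_equal(a140, desk_phantom.attenuation_140kev)


def test_pose_moves_liver_and_conserves_activity(desk_phantom):
    ph = desk_phantom
    pat = BreathingPattern()
    act, _, _ = phantom_at_amplitude(ph, 2.0, pat)
    # activity centroid moves ~20 mm inferior (z index decreases)
    z0 = (ph.activity * np.arange(48)[None, None, :]).sum() / ph.activity.sum()
    z1 = (act * np.arange(48)[None, None, :]).sum() / act.sum()
    assert (z1 - z0) * ph.voxel_size_mm == pytest.approx(-20.0, abs=2.0)
    assert act.sum() == pytest.approx(ph.activity.sum(), rel=0.02)


def test_warped_sphere_stays_in_warped_liver(desk_phantom):
    ph = desk_phantom
    f = ground_truth_displacement(ph, 2.0, 1.2)
    ws = warp_volume(ph.masks["sphere"].astype(float), f, "nearest") > 0.5
    wl = warp_volume(ph.masks["liver"].astype(float), f, "nearest") > 0.5
    assert np.all(wl[ws])


def test_small_grid_invariants():
    ph = build_phantom(150.0, 3.0, (48, 48, 36), 8.0)
    assert np.all(ph.masks["liver"][ph.masks["sphere"]])
    assert ph.activity.sum() == pytest.approx(150e6, rel=1e-3)
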