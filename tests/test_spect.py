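"""MLEM and motion-compensated MLEM reconstruction."""

import numpy as np
import pytest

from fluospect import Geometry
from fluospect.cbct import MotionVectorField
from fluospect.exceptions import InsufficientGateError
from fluospect.nuclear import SystemModel, simulate_nuclear_acquisition
from fluospect.phantom import build_phantom
from fluospect.respiration import BreathingPattern, generate_breathing_signal
from fluospect.spect import (MatrixOperator, SpectOperator, mlem_core,
                             reconstruct_gated, reconstruct_mvf,
                             reconstruct_uncompensated)


def _em_oracle(A, b, n_iter, x0):
    """Hand-rolled EM on an explicit matrix."""
    s = A.T @ np.ones(A.shape[0])
    x = x0.copy()
    for _ in range(n_iter):
        x = x / s * (A.T @ (b / (A @ x)))
    return x


@pytest.fixture(scope="module")
def toy_system():
    rng = np.random.default_rng(8)
    A = rng.random((6, 4)) + 0.1
    x_true = np.array([1.0, 2.0, 0.5, 3.0])
    return A, x_true


def test_mlem_matches_explicit_em_oracle(toy_system):
    A, x_true = toy_system
    b = A @ x_true
    res = mlem_core(b, MatrixOperator(A), n_iter=10,
                    init=np.ones(4), store_snapshots=True)
    x = np.ones(4)
    for it in range(10):
        x = _em_oracle(A, b, 1, x)
        np.testing.assert_allclose(res.snapshots[it], x, rtol=1e-12)


def test_mlem_truth_is_fixed_point(toy_system):
    A, x_true = toy_system
    b = A @ x_true
    res = mlem_core(b, MatrixOperator(A), n_iter=5, init=x_true,
                    store_snapshots=True)
    for snap in res.snapshots:
        np.testing.assert_allclose(snap, x_true, rtol=1e-10)


def test_mlem_count_conservation_uniform_sensitivity():
    rng = np.random.default_rng(9)
    A = rng.random((8, 5)) + 0.05
    A /= A.sum(axis=0, keepdims=True)        # uniform column sums
    b = rng.poisson(40.0, size=8).astype(float)
    op = MatrixOperator(A)
    res = mlem_core(b, op, n_iter=15, store_snapshots=True)
    for snap in res.snapshots:
        assert (A @ snap).sum() == pytest.approx(b.sum(), rel=1e-6)


def test_mlem_loglikelihood_nondecreasing(toy_system):
    A, x_true = toy_system
    rng = np.random.default_rng(10)
    b = rng.poisson(50.0 * (A @ x_true)).astype(float)
    res = mlem_core(b, MatrixOperator(A), n_iter=25)
    ll = res.log_likelihood
    assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[:-1]))


def test_mlem_zero_data_zero_result(toy_system):
    A, _ = toy_system
    res = mlem_core(np.zeros(6), MatrixOperator(A), n_iter=3)
    np.testing.assert_allclose(res.volume, 0.0, atol=1e-15)


def test_mlem_nonnegative_snapshots(toy_system):
    A, x_true = toy_system
    rng = np.random.default_rng(11)
    b = rng.poisson(20.0 * (A @ x_true)).astype(float)
    res = mlem_core(b, MatrixOperator(A), n_iter=10, store_snapshots=True)
    for snap in res.snapshots:
        assert np.all(snap >= 0)


@pytest.fixture(scope="module")
def small_acquisition():
    geom = Geometry((32, 32, 24), 12.0, 20)
    ph = build_phantom(150.0, 5.0, geom.grid_dims, 12.0)
    model = SystemModel(geometry=geom)
    sig = generate_breathing_signal(BreathingPattern(), 100.0, 5.0)
    sig.diaphragm_cm[:] = 0.0        # static
    nset = simulate_nuclear_acquisition(ph, sig, geom, 100.0, model, seed=3)
    return geom, ph, model, nset


def test_uncompensated_equals_mlem_on_sums(small_acquisition):
    geom, ph, model, nset = small_acquisition
    res = reconstruct_uncompensated(nset, model, ph.attenuation_140kev,
                                    n_iter=3)
    from fluospect.spect import mlem
    proj, dur = nset.counts_per_angle()
    ref = mlem(proj, model, ph.attenuation_140kev,
               np.arange(geom.n_angles), dur, n_iter=3)
    np.testing.assert_array_equal(res.volume, ref.volume)
    assert proj.sum() == nset.total_counts


def test_gated_all_accepted_equals_uncompensated(small_acquisition):
    geom, ph, model, nset = small_acquisition
    allon = np.ones(nset.n_subframes, bool)
    a = reconstruct_gated(nset, allon, model, ph.attenuation_140kev, n_iter=3)
    b = reconstruct_uncompensated(nset, model, ph.attenuation_140kev,
                                  n_iter=3)
    np.testing.assert_array_equal(a.volume, b.volume)


def test_gated_uses_only_accepted_counts(small_acquisition):
    geom, ph, model, nset = small_acquisition
    gate = nset.timestamps_s < 60.0
    proj, dur = nset.counts_per_angle(weights=gate)
    assert proj.sum() == nset.subframes[gate].sum()
    assert dur.sum() == pytest.approx(gate.sum() * 0.2)


def test_gated_insufficient_angles_raises(small_acquisition):
    geom, ph, model, nset = small_acquisition
    gate = nset.timestamps_s < 10.0      # only the first two angles
    with pytest.raises(InsufficientGateError):
        reconstruct_gated(nset, gate, model, ph.attenuation_140kev, n_iter=2)


def test_mvf_identity_single_bin_reduces_to_mlem(small_acquisition):
    geom, ph, model, nset = small_acquisition
    proj, dur = nset.counts_per_angle()
    mvf = MotionVectorField(
        forward_mm=np.zeros((1,) + geom.grid_dims + (3,)),
        inverse_mm=np.zeros((1,) + geom.grid_dims + (3,)),
        diaphragm_shift_mm=np.zeros(1), sternum_shift_mm=np.zeros(1),
        voxel_size_mm=12.0)
    res = reconstruct_mvf({1: (proj, dur)}, mvf, model,
                          ph.attenuation_140kev, n_iter=5,
                          store_snapshots=True)
    ref = reconstruct_uncompensated(nset, model, ph.attenuation_140kev,
                                    n_iter=5, store_snapshots=True)
    for a, b in zip(res.snapshots, ref.snapshots):
        np.testing.assert_allclose(a, b, rtol=1e-6)


def test_mvf_matches_explicit_motion_em_oracle():
    """Four-voxel, two-bin toy with exact one-voxel shifts."""
    from motion_toy import run_toy
    snaps, oracle = run_toy(n_iter=5)
    for s, o in zip(snaps, oracle):
        np.testing.assert_allclose(s, o, atol=1e-9)


def test_spect_operator_adjoint(small_acquisition):
    geom, ph, model, _ = small_acquisition
    rng = np.random.default_rng(12)
    op = SpectOperator(model, ph.attenuation_140kev, np.arange(5),
                       np.full(5, 2.0))
    x = rng.random(geom.grid_dims)
    y = rng.random((5,) + geom.det_shape)
    assert (op.forward(x) * y).sum() \
        == pytest.approx((x * op.backward(y)).sum(), rel=1e-10)
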