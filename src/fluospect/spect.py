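"""MLEM SPECT reconstruction: plain, gated, and motion-compensated.

Classic MLEM (no subsets) with the attenuated, depth-dependent-PSF projector
and per-angle acquisition times:

    x <- x / s * A^T ( b / max(A x, eps) ),    s = A^T 1

Four modes are provided: uncompensated (all counts, breath-hold attenuation),
gated (only low-amplitude counts, rescaled times), motion-vector-field
compensated, and a static reference.  The motion-compensated update follows
the bin-wise scheme: per iteration and bin, the current motion-free estimate
is warped to the bin pose, forward-projected with the bin-warped attenuation,
the measured/estimated ratio is backprojected, the error image is warped
back with the inverse field, and the error images are averaged over bins
weighted by bin acquisition time; the sensitivity is the matching
time-weighted average of warped-back per-bin sensitivities, so the update
reduces exactly to plain MLEM for identity fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _projops
from ._projops import Geometry
from .cbct import MotionVectorField
from .exceptions import ConfigurationError, InsufficientGateError
from .nuclear import NuclearSet, SystemModel
from .phantom import DisplacementField, warp_volume

__all__ = ["ReconResult", "ProjectorOperator", "SpectOperator",
           "MatrixOperator", "mlem", "mlem_core",
           "reconstruct_uncompensated", "reconstruct_gated",
           "reconstruct_mvf", "reconstruct_reference", "bin_nuclear_counts"]

EPS_FRACTION = 1e-12


@dataclass
class ReconResult:
    """MLEM output: calibrated volume (Bq/voxel) plus per-iteration traces."""

    volume: np.ndarray
    mode: str
    n_iterations: int
    log_likelihood: np.ndarray = None
    snapshots: list | None = None
    seed: int | None = None

    def snapshot(self, it: int) -> np.ndarray:
        if self.snapshots is None:
            raise ValueError("snapshots were not stored")
        return self.snapshots[it]


class ProjectorOperator:
    """Linear forward/backprojection pair; subclasses must be exact adjoints."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class MatrixOperator(ProjectorOperator):
    """Explicit-matrix operator for small systems and oracle checks."""

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=float)

    def forward(self, x):
        return self.matrix @ np.ravel(x)

    def backward(self, y):
        return self.matrix.T @ np.ravel(y)


class SpectOperator(ProjectorOperator):
    """Attenuated PSF projector over a set of angles with exposure times.

    ``x`` is a volume (Bq); ``forward`` returns a (n_angles, rows, cols)
    stack of expected counts (time-scaled).  Rotated attenuation survival
    factors are precomputed per angle.
    """

    def __init__(self, model: SystemModel, attenuation: np.ndarray,
                 angle_indices: np.ndarray, durations_s: np.ndarray):
        self.model = model
        self.geom = model.geometry
        self.angle_indices = np.asarray(angle_indices, dtype=int)
        self.durations = np.asarray(durations_s, dtype=float)
        self.sigmas = model.psf_sigmas()
        vs = self.geom.voxel_size_cm
        self._factors = {}
        for a in np.unique(self.angle_indices):
            mu_rot = _projops.rotate_volume(attenuation,
                                            self.geom.angles_deg[a])
            self._factors[int(a)] = _projops.attenuation_factors(mu_rot, vs)

    def forward(self, x):
        out = np.empty((len(self.angle_indices),) + self.geom.det_shape)
        for i, a in enumerate(self.angle_indices):
            if self.durations[i] == 0:
                out[i] = 0.0
                continue
            out[i] = _projops.nuclear_forward(
                x, self._factors[int(a)], self.geom.angles_deg[a],
                self.sigmas, self.model.scale) * self.durations[i]
        return out

    def backward(self, y):
        vol = np.zeros(self.geom.grid_dims)
        for i, a in enumerate(self.angle_indices):
            if self.durations[i] == 0:
                continue
            vol += _projops.nuclear_backward(
                y[i], self._factors[int(a)], self.geom.angles_deg[a],
                self.sigmas, self.model.scale) * self.durations[i]
        return vol


def _poisson_loglik(b, yhat):
    pos = yhat > 0
    ll = -float(yhat.sum())
    bb = b[pos]
    ll += float((bb[bb > 0] * np.log(yhat[pos][bb > 0])).sum())
    return ll


def mlem_core(projections: np.ndarray, op: ProjectorOperator,
              n_iter: int = 25, init: np.ndarray | None = None,
              callback=None, store_snapshots: bool = False,
              track_loglik: bool = True) -> ReconResult:
    """Classic MLEM on an abstract projector pair.

    Voxels with zero sensitivity stay zero; the measured/estimated ratio is
    guarded with eps = 1e-12 of the mean expectation.  The Poisson
    log-likelihood is recorded per iteration when ``track_loglik``.
    """
    b = np.asarray(projections, dtype=float)
    sens = op.backward(np.ones_like(b))
    live = sens > 0
    x = np.ones(sens.shape) if init is None else np.asarray(init, float).copy()
    x[~live] = 0.0
    logliks = []
    snaps = [] if store_snapshots else None
    for it in range(n_iter):
        yhat = op.forward(x)
        eps = EPS_FRACTION * max(float(np.mean(yhat)), np.finfo(float).tiny)
        ratio = b / np.maximum(yhat, eps)
        upd = op.backward(ratio)
        x = np.where(live, x * upd / np.where(live, sens, 1.0), 0.0)
        if track_loglik:
            logliks.append(_poisson_loglik(b, op.forward(x)))
        if store_snapshots:
            snaps.append(x.copy())
        if callback is not None:
            callback(it, x)
    return ReconResult(volume=x, mode="mlem", n_iterations=n_iter,
                       log_likelihood=np.asarray(logliks) if track_loglik
                       else None,
                       snapshots=snaps)


def mlem(projections: np.ndarray, model: SystemModel, attenuation: np.ndarray,
         angle_indices: np.ndarray, durations_s: np.ndarray, n_iter: int = 25,
         init: np.ndarray | None = None, **kw) -> ReconResult:
    """MLEM with the SPECT system model (thin wrapper over mlem_core)."""
    op = SpectOperator(model, attenuation, angle_indices, durations_s)
    return mlem_core(projections, op, n_iter=n_iter, init=init, **kw)


def reconstruct_uncompensated(nuclear: NuclearSet, model: SystemModel,
                              attenuation_ref: np.ndarray, n_iter: int = 25,
                              **kw) -> ReconResult:
    """All counts summed per angle, breath-hold attenuation, plain MLEM."""
    proj, dur = nuclear.counts_per_angle()
    used = dur > 0
    res = mlem(proj[used], model, attenuation_ref,
               np.arange(nuclear.geometry.n_angles)[used], dur[used],
               n_iter=n_iter, **kw)
    res.mode = "none"
    return res


def reconstruct_gated(nuclear: NuclearSet, gated: np.ndarray,
                      model: SystemModel, attenuation_ref: np.ndarray,
                      n_iter: int = 25, **kw) -> ReconResult:
    """MLEM on the accepted (low-amplitude) subframes only.

    Per-angle exposure times are rescaled to the accepted durations.  Raises
    when fewer than half of the angles have any accepted subframe.
    """
    proj, dur = nuclear.counts_per_angle(weights=np.asarray(gated, bool))
    n_ang = nuclear.geometry.n_angles
    if np.count_nonzero(dur > 0) < n_ang / 2:
        raise InsufficientGateError(
            "fewer than half of the angles have accepted frames")
    used = dur > 0
    res = mlem(proj[used], model, attenuation_ref,
               np.arange(n_ang)[used], dur[used], n_iter=n_iter, **kw)
    res.mode = "gated"
    return res


def reconstruct_reference(nuclear_static: NuclearSet, model: SystemModel,
                          attenuation_ref: np.ndarray, n_iter: int = 25,
                          **kw) -> ReconResult:
    """Plain MLEM of a no-motion acquisition (upper-bound reference)."""
    res = reconstruct_uncompensated(nuclear_static, model, attenuation_ref,
                                    n_iter=n_iter, **kw)
    res.mode = "reference"
    return res


def bin_nuclear_counts(nuclear: NuclearSet, bin_index: np.ndarray,
                       bins: list[int]):
    """Per-bin (projections, durations) stacks for the listed bins."""
    out = {}
    for b in bins:
        out[b] = nuclear.counts_per_angle(weights=bin_index == b)
    return out


def reconstruct_mvf(per_bin: dict, mvf: MotionVectorField,
                    model: SystemModel, attenuation_ref: np.ndarray,
                    n_iter: int = 25, init: np.ndarray | None = None,
                    bin_weighting: str = "time", callback=None,
                    store_snapshots: bool = False) -> ReconResult:
    """Motion-compensated MLEM using per-bin projections and the MVF.

    ``per_bin`` maps bin label -> (projections, durations) per angle, in the
    same ascending order as the MVF bins.  ``bin_weighting`` averages the
    per-bin error images by acquisition time (default) or plainly.
    """
    bins = sorted(per_bin)
    if len(bins) != mvf.n_bins:
        raise ConfigurationError("MVF bin count does not match projections")
    geom = model.geometry
    vsz = mvf.voxel_size_mm

    ops, fwd_fields, inv_fields, tau = [], [], [], []
    for k, b in enumerate(bins):
        proj, dur = per_bin[b]
        used = dur > 0
        fwd = DisplacementField(mvf.forward_mm[k], vsz)
        inv = DisplacementField(mvf.inverse_mm[k], vsz)
        att_b = warp_volume(attenuation_ref, fwd)
        ops.append((SpectOperator(model, att_b,
                                  np.arange(geom.n_angles)[used], dur[used]),
                    proj[used]))
        fwd_fields.append(fwd)
        inv_fields.append(inv)
        tau.append(dur.sum())
    tau = np.asarray(tau)
    w = tau if bin_weighting == "time" else np.ones_like(tau)
    w = w / w.sum()

    # time-weighted average of warped-back per-bin sensitivities
    sens = np.zeros(geom.grid_dims)
    for k, (op, proj) in enumerate(ops):
        s_b = op.backward(np.ones_like(proj))
        sens += w[k] * warp_volume(s_b, inv_fields[k])
    live = sens > 0

    x = np.ones(geom.grid_dims) if init is None else np.asarray(init).copy()
    x[~live] = 0.0
    snaps = [] if store_snapshots else None
    for it in range(n_iter):
        err = np.zeros(geom.grid_dims)
        for k, (op, proj) in enumerate(ops):
            xb = warp_volume(x, fwd_fields[k])
            yhat = op.forward(xb)
            eps = EPS_FRACTION * max(float(np.mean(yhat)),
                                     np.finfo(float).tiny)
            e_b = op.backward(proj / np.maximum(yhat, eps))
            err += w[k] * warp_volume(e_b, inv_fields[k])
        x = np.where(live, x * err / np.where(live, sens, 1.0), 0.0)
        np.maximum(x, 0.0, out=x)
        if store_snapshots:
            snaps.append(x.copy())
        if callback is not None:
            callback(it, x)
    return ReconResult(volume=x, mode="mvf", n_iterations=n_iter,
                       snapshots=snaps)
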