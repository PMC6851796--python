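"""Shared four-voxel / two-bin motion-EM toy and its explicit-matrix oracle.

The grid is 2 x 2 x 1 with two projection angles (0 and 90 degrees), no PSF
and no attenuation; bin 2 is the reference content shifted exactly one voxel
along y.  Every operator (projection, warp, inverse warp) then has an exact
matrix representation, so the motion-compensated EM update can be replayed
independently with dense linear algebra.
"""

import numpy as np

from fluospect import Geometry
from fluospect.cbct import MotionVectorField
from fluospect.nuclear import SystemModel
from fluospect.spect import reconstruct_mvf

A0 = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], float)    # angle 0
A90 = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], float)   # angle 90
W = np.array([[0, 1, 0, 0], [0, 0, 0, 0],
              [0, 0, 0, 1], [0, 0, 0, 0]], float)      # +1 voxel along y
WINV = np.array([[0, 0, 0, 0], [1, 0, 0, 0],
                 [0, 0, 0, 0], [0, 0, 1, 0]], float)


def run_toy(n_iter=5):
    """Returns (implementation snapshots, oracle iterates), both length n."""
    geom = Geometry((2, 2, 1), 10.0, 4)
    model = SystemModel(geometry=geom, psf_fwhm0_mm=0.0,
                        psf_slope_mm_per_cm=0.0, sensitivity_cps_per_bq=1.0,
                        flat_panel_transmission=1.0)
    att = np.zeros(geom.grid_dims)
    x_true = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])

    fwd = np.zeros((2,) + geom.grid_dims + (3,))
    fwd[1, ..., 1] = 10.0
    mvf = MotionVectorField(forward_mm=fwd, inverse_mm=-fwd,
                            diaphragm_shift_mm=np.zeros(2),
                            sternum_shift_mm=np.zeros(2),
                            voxel_size_mm=10.0)

    t = np.array([2.0, 3.0, 0.0, 0.0])
    xf = x_true.ravel()
    per_bin, mats = {}, {}
    for k, (Wb, Wbi) in enumerate([(np.eye(4), np.eye(4)), (W, WINV)]):
        proj = np.zeros((4, 1, 2))
        for a, Aa in ((0, A0), (1, A90)):
            proj[a, 0, :] = t[a] * (Aa @ (Wb @ xf))
        per_bin[k + 1] = (proj, t.copy())
        mats[k] = (Wb, Wbi)

    res = reconstruct_mvf(per_bin, mvf, model, att, n_iter=n_iter,
                          store_snapshots=True)

    Astack = np.vstack([t[0] * A0, t[1] * A90])
    bvec = {k: np.concatenate([per_bin[k + 1][0][0, 0, :],
                               per_bin[k + 1][0][1, 0, :]])
            for k in range(2)}
    w = np.array([0.5, 0.5])
    sens = sum(w[k] * (mats[k][1] @ (Astack.T @ np.ones(4)))
               for k in range(2))
    x = np.ones(4)
    oracle = []
    for _ in range(n_iter):
        err = np.zeros(4)
        for k in range(2):
            Wb, Wbi = mats[k]
            yhat = Astack @ (Wb @ x)
            ratio = np.divide(bvec[k], yhat, out=np.zeros_like(yhat),
                              where=yhat > 0)
            err += w[k] * (Wbi @ (Astack.T @ ratio))
        x = np.where(sens > 0, x * err / np.where(sens > 0, sens, 1.0), 0.0)
        oracle.append(x.copy())
    return [s.ravel() for s in res.snapshots], oracle
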