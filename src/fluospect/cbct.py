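"""Per-bin CBCT reconstruction (OS-SART) and motion-vector-field estimation.

Log-transformed fluoroscopic frames are grouped by amplitude bin and
reconstructed with the ordered-subset simultaneous algebraic reconstruction
technique.  Because the low-dose reconstructions cannot support free-form
registration of the liver itself, the per-bin motion is summarized by two
scalars measured on the reconstructions -- the superior-inferior shift of
the lung-liver boundary (diaphragm) and the anterior-posterior shift of the
sternum -- and extrapolated over the volume with the anatomical rules also
used by the phantom's motion model: full SI shift below the lungs tapering
to zero at the lung apex, AP ramp from zero at the (fixed) spine to the
sternum shift at the anterior surface.  Fields are spatially mean-filtered
over 3 voxels and temporally over 3 bins; bin 1 is the reference
(stationary) bin with identically zero fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi

from . import _projops
from ._projops import Geometry
from .exceptions import (EmptyBinError, InvalidParameterError, ShapeError)
from .fluoro import FluoroSet, NoiseModel
from .motion import ExtractedSignal
from .phantom import VoxelPhantom, respiratory_field

__all__ = ["BinnedFluoro", "MotionVectorField", "log_transform", "bin_fluoro",
           "reconstruct_bin", "estimate_diaphragm_shift",
           "estimate_sternum_shift", "build_mvf", "smooth_mvf", "perturb_mvf",
           "estimate_mvf"]


def log_transform(frame: np.ndarray, flux0: float,
                  floor: float = 1.0) -> np.ndarray:
    """Transmission preprocessing: -ln(max(frame, floor)/flux0)."""
    if flux0 <= 0:
        raise InvalidParameterError("flux0 must be > 0")
    return -np.log(np.maximum(np.asarray(frame, float), floor) / flux0)


@dataclass
class BinnedFluoro:
    """Per-bin, per-angle averaged log-transformed projections.

    ``sinograms[b]`` maps angle index -> mean log frame; ``coverage[b]`` is
    the fraction of scheduled angles with at least one frame in bin b.
    """

    sinograms: dict[int, dict[int, np.ndarray]]
    coverage: dict[int, float]
    geometry: Geometry

    @property
    def bins(self) -> list[int]:
        return sorted(self.sinograms)


def bin_fluoro(fluoro: FluoroSet, extracted: ExtractedSignal) -> BinnedFluoro:
    """Group frames by bin, log-transform, and average per gantry angle."""
    flux0 = fluoro.noise_model.flux_at(fluoro.dose_per_frame_ugy)
    logs = log_transform(fluoro.frames, flux0)
    sinos: dict[int, dict[int, np.ndarray]] = {}
    for b in np.unique(extracted.bin_index):
        sel_b = extracted.bin_index == b
        per_angle = {}
        for a in np.unique(fluoro.angle_indices[sel_b]):
            sel = sel_b & (fluoro.angle_indices == a)
            per_angle[int(a)] = logs[sel].mean(axis=0)
        sinos[int(b)] = per_angle
    coverage = {b: len(v) / fluoro.geometry.n_angles
                for b, v in sinos.items()}
    return BinnedFluoro(sinograms=sinos, coverage=coverage,
                        geometry=fluoro.geometry)


def reconstruct_bin(bin_sinogram: dict[int, np.ndarray], geometry: Geometry,
                    n_iterations: int = 50, n_subsets: int = 6,
                    relaxation: float = 1.0,
                    residual_history: list | None = None) -> np.ndarray:
    """OS-SART reconstruction of one bin's log projections.

    Angles are interleaved over the subsets.  Each subset applies the
    SART-weighted additive update
    ``x += lam * V_s^-1 A_s^T W_s^-1 (b_s - A_s x)`` with row (ray-length)
    and column (backprojection) normalization, followed by a nonnegativity
    clamp.  Pass ``residual_history`` to record ||Ax - b||_2 after every
    full iteration.
    """
    angles = sorted(bin_sinogram)
    if not angles:
        raise EmptyBinError("bin contains no frames")
    vs = geometry.voxel_size_cm
    dims = geometry.grid_dims
    n_subsets = max(1, min(n_subsets, len(angles)))
    subsets = [angles[s::n_subsets] for s in range(n_subsets)]

    ones_vol = np.ones(dims)
    row_norm = {a: np.maximum(
        _projops.xray_forward(ones_vol, geometry.angles_deg[a], vs,
                              check=False), 1e-8) for a in angles}
    col_norm = {}
    for s, sub in enumerate(subsets):
        cn = np.zeros(dims)
        for a in sub:
            cn += _projops.xray_backward(np.ones(geometry.det_shape),
                                         geometry.angles_deg[a], vs, dims)
        col_norm[s] = np.maximum(cn, 1e-8)

    x = np.zeros(dims)
    for _ in range(n_iterations):
        for s, sub in enumerate(subsets):
            upd = np.zeros(dims)
            for a in sub:
                est = _projops.xray_forward(x, geometry.angles_deg[a], vs,
                                            check=False)
                upd += _projops.xray_backward(
                    (bin_sinogram[a] - est) / row_norm[a],
                    geometry.angles_deg[a], vs, dims)
            x = np.maximum(x + relaxation * upd / col_norm[s], 0.0)
        if residual_history is not None:
            res = 0.0
            for a in angles:
                d = _projops.xray_forward(x, geometry.angles_deg[a], vs,
                                          check=False) - bin_sinogram[a]
                res += float(np.sum(d * d))
            residual_history.append(np.sqrt(res))
    return x


def _profile_shift(profile_ref_ext: np.ndarray, profile_bin: np.ndarray,
                   max_shift_vox: int):
    """Sub-voxel template-matching lag between 1D intensity profiles.

    ``profile_ref_ext`` extends the bin window by ``max_shift_vox`` samples
    on each side, so every candidate lag is scored on a full-length overlap
    (short-overlap normalized correlation is spuriously high on flat
    anatomy).  Positive lag means the bin content moved toward *lower*
    indices.  Returns (lag, at_boundary).
    """
    n = len(profile_bin)
    b = profile_bin - profile_bin.mean()
    nb = np.linalg.norm(b)
    lags = np.arange(-max_shift_vox, max_shift_vox + 1)
    scores = np.empty(len(lags))
    for i, k in enumerate(lags):
        # bin[z] = ref[z + k]  <=>  template matches ref window offset by +k
        seg = profile_ref_ext[max_shift_vox + k: max_shift_vox + k + n]
        a = seg - seg.mean()
        denom = np.linalg.norm(a) * nb
        scores[i] = (a @ b) / denom if denom > 0 else -1.0
    j = int(np.argmax(scores))
    at_boundary = j in (0, len(lags) - 1)
    lag = float(lags[j])
    if 0 < j < len(lags) - 1:
        # refine on a fine fractional-lag grid with interpolated reference
        # (a parabola through ZNCC samples is biased on asymmetric peaks)
        xs = np.arange(len(profile_ref_ext), dtype=float)
        base = np.arange(n, dtype=float) + max_shift_vox
        best = (scores[j], lag)
        for k in np.arange(lag - 1.0, lag + 1.0 + 1e-9, 0.05):
            seg = np.interp(base + k, xs, profile_ref_ext)
            a = seg - seg.mean()
            denom = np.linalg.norm(a) * nb
            s = (a @ b) / denom if denom > 0 else -1.0
            if s > best[0]:
                best = (s, float(k))
        lag = best[1]
    return lag, at_boundary


@dataclass
class ShiftEstimate:
    shift_mm: float
    reliable: bool = True


def estimate_diaphragm_shift(recon_ref: np.ndarray, recon_bin: np.ndarray,
                             search_box: tuple[slice, slice, slice],
                             voxel_size_mm: float,
                             max_shift_vox: int = 8) -> ShiftEstimate:
    """SI shift (mm) of the lung-liver boundary between two reconstructions.

    The mean-intensity SI profile inside the search box is cross-correlated;
    positive = inferior displacement in the bin volume.  A correlation peak
    at the search boundary is flagged unreliable.
    """
    if recon_ref.shape != recon_bin.shape:
        raise ShapeError("volumes must share a grid")
    sx, sy, sz = search_box
    nz = recon_ref.shape[2]
    m = min(max_shift_vox, sz.start, nz - sz.stop)
    ext = slice(sz.start - m, sz.stop + m)
    p_ref = recon_ref[sx, sy, ext].mean(axis=(0, 1))
    p_bin = recon_bin[sx, sy, sz].mean(axis=(0, 1))
    # z index increases superior; content moving inferior = toward lower z
    lag, at_boundary = _profile_shift(p_ref, p_bin, m)
    return ShiftEstimate(shift_mm=lag * voxel_size_mm,
                         reliable=not at_boundary)


def estimate_sternum_shift(recon_ref: np.ndarray, recon_bin: np.ndarray,
                           search_box: tuple[slice, slice, slice],
                           voxel_size_mm: float,
                           max_shift_vox: int = 8) -> ShiftEstimate:
    """AP shift (mm) of the sternum; positive = anterior displacement."""
    if recon_ref.shape != recon_bin.shape:
        raise ShapeError("volumes must share a grid")
    sx, sy, sz = search_box
    ny = recon_ref.shape[1]
    m = min(max_shift_vox, sy.start, ny - sy.stop)
    ext = slice(sy.start - m, sy.stop + m)
    p_ref = recon_ref[sx, ext, sz].mean(axis=(0, 2))
    p_bin = recon_bin[sx, sy, sz].mean(axis=(0, 2))
    # y index increases posterior; anterior motion = toward lower y
    lag, at_boundary = _profile_shift(p_ref, p_bin, m)
    return ShiftEstimate(shift_mm=lag * voxel_size_mm,
                         reliable=not at_boundary)


@dataclass
class MotionVectorField:
    """Per-bin forward (bin1 -> bin b) and inverse pull-back fields (mm)."""

    forward_mm: np.ndarray     # (B, nx, ny, nz, 3)
    inverse_mm: np.ndarray
    diaphragm_shift_mm: np.ndarray   # (B,)
    sternum_shift_mm: np.ndarray
    voxel_size_mm: float
    bin_labels: tuple[int, ...] | None = None  # original bin numbers

    @property
    def n_bins(self) -> int:
        return self.forward_mm.shape[0]


def build_mvf(diaphragm_shifts_mm, sternum_shifts_mm,
              phantom: VoxelPhantom) -> MotionVectorField:
    """Extrapolate per-bin scalar shifts to full displacement fields.

    Bin 1 (index 0) is the reference; its shifts are forced to zero.  The
    inverse fields negate the shifts (valid for this parametric family).
    """
    d = np.asarray(diaphragm_shifts_mm, dtype=float).copy()
    s = np.asarray(sternum_shifts_mm, dtype=float).copy()
    d[0] = 0.0
    s[0] = 0.0
    dims = phantom.grid_dims
    fwd = np.zeros((len(d),) + dims + (3,))
    inv = np.zeros_like(fwd)
    for b in range(len(d)):
        args = (dims, phantom.voxel_size_mm, phantom.masks["body"],
                phantom.masks["spine"], phantom.lung_z_range,
                phantom.spine_y_mm, phantom.anterior_y_mm)
        fwd[b] = respiratory_field(*args, d[b], s[b])
        inv[b] = respiratory_field(*args, -d[b], -s[b])
    return MotionVectorField(forward_mm=fwd, inverse_mm=inv,
                             diaphragm_shift_mm=d, sternum_shift_mm=s,
                             voxel_size_mm=phantom.voxel_size_mm)


def smooth_mvf(mvf: MotionVectorField) -> MotionVectorField:
    """3-voxel spatial box mean, then 3-bin temporal mean (truncated ends).

    The temporal pass is skipped for fewer than 3 bins; bin-1 fields are
    re-zeroed afterwards so the reference stays exact.
    """
    def _smooth(stack):
        out = np.empty_like(stack)
        for b in range(stack.shape[0]):
            for c in range(3):
                out[b, ..., c] = ndi.uniform_filter(
                    stack[b, ..., c], size=3, mode="nearest")
        if stack.shape[0] >= 3:
            tmp = out.copy()
            for b in range(stack.shape[0]):
                lo, hi = max(0, b - 1), min(stack.shape[0], b + 2)
                out[b] = tmp[lo:hi].mean(axis=0)
        out[0] = 0.0
        return out

    return replace(mvf, forward_mm=_smooth(mvf.forward_mm),
                   inverse_mm=_smooth(mvf.inverse_mm))


def perturb_mvf(mvf: MotionVectorField, si_deficit_mm: float = 2.0,
                ap_deficit_mm: float = 1.0) -> MotionVectorField:
    """Emulate a motion vector field from a previously acquired 4D scan.

    The maximum-amplitude bin loses exactly the given deficits; all bins are
    scaled proportionally (a prior scan underestimating the in-scan motion).
    """
    if si_deficit_mm < 0 or ap_deficit_mm < 0:
        raise InvalidParameterError("deficits must be nonnegative")

    def _factor(shifts, deficit):
        m = np.max(np.abs(shifts))
        return 1.0 if m == 0 else max(m - deficit, 0.0) / m

    f_si = _factor(mvf.diaphragm_shift_mm, si_deficit_mm)
    f_ap = _factor(mvf.sternum_shift_mm, ap_deficit_mm)
    fwd = mvf.forward_mm.copy()
    inv = mvf.inverse_mm.copy()
    for arr in (fwd, inv):
        arr[..., 2] *= f_si
        arr[..., 1] *= f_ap
    return replace(mvf, forward_mm=fwd, inverse_mm=inv,
                   diaphragm_shift_mm=mvf.diaphragm_shift_mm * f_si,
                   sternum_shift_mm=mvf.sternum_shift_mm * f_ap)


def default_search_boxes(phantom: VoxelPhantom):
    """Diaphragm and sternum search boxes from the phantom masks.

    The diaphragm box covers the liver's (x, y) footprint around the
    lung-liver boundary; the sternum box covers the sternum's (x, z)
    footprint across the anterior chest wall.
    """
    liver = phantom.masks["liver"]
    sternum = phantom.masks["sternum"]
    nx, ny, nz = phantom.grid_dims
    ix, iy, iz = np.nonzero(liver)
    zb = phantom.lung_z_range[0]
    margin = max(3, int(round(30.0 / phantom.voxel_size_mm)))
    # keep the window below the lung taper so everything in it moves rigidly
    dia_box = (slice(ix.min(), ix.max() + 1),
               slice(iy.min(), iy.max() + 1),
               slice(max(zb - 3 * margin, 0), min(zb + 2, nz)))
    jx, jy, jz = np.nonzero(sternum)
    st_box = (slice(jx.min(), jx.max() + 1),
              slice(max(jy.min() - margin, 0), min(jy.max() + margin, ny)),
              slice(jz.min(), jz.max() + 1))
    return dia_box, st_box


def estimate_mvf(binned: BinnedFluoro, phantom: VoxelPhantom,
                 n_iterations: int = 50, n_subsets: int = 6,
                 smooth: bool = True):
    """Reconstruct every bin, measure shifts vs bin 1, extrapolate fields.

    Empty bins were already dropped by the binning step; bins are renumbered
    in ascending order with the lowest-amplitude bin as the reference.
    Returns (mvf, per-bin reconstructions, shift estimates).
    """
    geometry = binned.geometry
    recons = {b: reconstruct_bin(binned.sinograms[b], geometry,
                                 n_iterations, n_subsets)
              for b in binned.bins}
    bins = binned.bins
    ref = recons[bins[0]]
    dia_box, st_box = default_search_boxes(phantom)
    d_mm, s_mm, estimates = [], [], {}
    for b in bins:
        de = estimate_diaphragm_shift(ref, recons[b], dia_box,
                                      phantom.voxel_size_mm)
        se = estimate_sternum_shift(ref, recons[b], st_box,
                                    phantom.voxel_size_mm)
        d_mm.append(de.shift_mm)
        s_mm.append(se.shift_mm)
        estimates[b] = (de, se)
    mvf = build_mvf(d_mm, s_mm, phantom)
    mvf = replace(mvf, bin_labels=tuple(bins))
    if smooth:
        mvf = smooth_mvf(mvf)
    return mvf, recons, estimates
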