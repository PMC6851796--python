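"""Parallel-beam projection operators shared by the x-ray and gamma chains.

The dual-layer detector is modelled with a parallel-beam geometry: rays run
along the +y axis of a frame rotated by the gantry angle about the z
(superior-inferior) axis.  The in-plane resampling onto that rotated frame is
realised as a sparse matrix with bilinear weights, so the adjoint of every
projection operator is available exactly (matrix transpose) -- a requirement
for MLEM/SART correctness.

Conventions
-----------
* Volumes are indexed ``vol[ix, iy, iz]`` with x = left-right,
  y = anterior(-)/posterior(+), z = inferior(0) -> superior.
* Detector images are ``img[row, col]`` with row 0 = superior (standard
  radiograph orientation) and columns along the rotated x axis.
* The detector plane sits on the +y side of the rotated frame; depth is the
  distance from a voxel plane to that detector plane.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp

from .exceptions import InvalidInputError

__all__ = ["Geometry", "rotate_volume", "rotate_volume_adjoint",
           "xray_forward", "xray_backward", "attenuation_factors",
           "nuclear_forward", "nuclear_backward", "psf_sigma_vox"]


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry: voxel grid, detector grid and gantry schedule.

    The detector is matched to the voxel grid: ``n_det_cols = nx`` columns of
    ``voxel_size_mm`` pitch along the rotated x axis and ``n_det_rows = nz``
    rows along z.  ``angles_deg`` is the step-and-shoot schedule over 360
    degrees.
    """

    grid_dims: tuple[int, int, int]
    voxel_size_mm: float
    n_angles: int = 120

    angles_deg: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "angles_deg",
            np.linspace(0.0, 360.0, self.n_angles, endpoint=False))

    @property
    def nx(self) -> int:
        return self.grid_dims[0]

    @property
    def ny(self) -> int:
        return self.grid_dims[1]

    @property
    def nz(self) -> int:
        return self.grid_dims[2]

    @property
    def det_shape(self) -> tuple[int, int]:
        return (self.nz, self.nx)

    @property
    def voxel_size_cm(self) -> float:
        return self.voxel_size_mm / 10.0

    def angle_index_at(self, t: float | np.ndarray, scan_time: float):
        """Step-and-shoot gantry: angle index = floor(t / scan_time * n)."""
        idx = np.floor(np.asarray(t, dtype=float) / scan_time * self.n_angles)
        return np.clip(idx.astype(int), 0, self.n_angles - 1)


# ---------------------------------------------------------------------------
# sparse in-plane rotation
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=512)
def _rotation_csr(nx: int, ny: int, angle_mdeg: int) -> sp.csr_matrix:
    """Sparse (nx*ny, nx*ny) bilinear resampler for an in-plane rotation.

    Output sample at rotated-frame point p is read from the input at
    ``c + R(theta) (p - c)`` where c is the grid center; out-of-grid samples
    read as zero.  ``angle_mdeg`` is the angle in millidegrees (hashable key).
    """
    theta = np.deg2rad(angle_mdeg / 1000.0)
    cth, sth = np.cos(theta), np.sin(theta)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ox, oy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ox = ox.ravel() - cx
    oy = oy.ravel() - cy
    sx = cth * ox - sth * oy + cx
    sy = sth * ox + cth * oy + cy

    x0 = np.floor(sx).astype(np.int64)
    y0 = np.floor(sy).astype(np.int64)
    fx = sx - x0
    fy = sy - y0

    rows, cols, vals = [], [], []
    out_idx = np.arange(nx * ny, dtype=np.int64)
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xi = x0 + dx
            yi = y0 + dy
            w = wx * wy
            ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny) & (w != 0.0)
            rows.append(out_idx[ok])
            cols.append((xi * ny + yi)[ok])
            vals.append(w[ok])
    mat = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny), dtype=np.float64)
    return mat.tocsr()


def _rot_pair(nx, ny, angle_deg):
    key = int(round(angle_deg * 1000.0)) % 360000
    mat = _rotation_csr(nx, ny, key)
    return mat


def rotate_volume(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Resample ``vol`` onto the frame rotated by ``angle_deg`` about z."""
    nx, ny, nz = vol.shape
    mat = _rot_pair(nx, ny, angle_deg)
    out = mat @ vol.reshape(nx * ny, nz)
    return out.reshape(nx, ny, nz)


def rotate_volume_adjoint(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Exact transpose of :func:`rotate_volume` (not its inverse)."""
    nx, ny, nz = vol.shape
    mat = _rot_pair(nx, ny, angle_deg)
    out = mat.T @ vol.reshape(nx * ny, nz)
    return out.reshape(nx, ny, nz)


def _to_det(img_xz: np.ndarray) -> np.ndarray:
    """(nx, nz) rotated-frame plane -> detector image (rows=z top=superior)."""
    return img_xz.T[::-1, :]


def _from_det(img: np.ndarray) -> np.ndarray:
    return img[::-1, :].T


# ---------------------------------------------------------------------------
# x-ray line integrals
# ---------------------------------------------------------------------------

def xray_forward(mu: np.ndarray, angle_deg: float, voxel_size_cm: float,
                 check: bool = True) -> np.ndarray:
    """Line integrals of an attenuation volume (1/cm) -> dimensionless image.

    Samples are taken on the rotated voxel grid (bilinear in-plane) and summed
    along +y with step ``voxel_size_cm``.
    """
    if check and np.any(mu < 0):
        raise InvalidInputError("attenuation must be nonnegative")
    rot = rotate_volume(mu, angle_deg)
    return _to_det(rot.sum(axis=1) * voxel_size_cm)


def xray_backward(img: np.ndarray, angle_deg: float, voxel_size_cm: float,
                  grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Exact adjoint of :func:`xray_forward`."""
    nx, ny, nz = grid_dims
    plane = _from_det(np.asarray(img, dtype=float)) * voxel_size_cm
    rot = np.broadcast_to(plane[:, None, :], (nx, ny, nz)).copy()
    return rotate_volume_adjoint(rot, angle_deg)


# ---------------------------------------------------------------------------
# gamma-camera projector: attenuation + depth-dependent PSF
# ---------------------------------------------------------------------------

def attenuation_factors(mu_rot: np.ndarray, voxel_size_cm: float) -> np.ndarray:
    """Per-voxel survival factor exp(-integral of mu to the detector).

    The detector is on the +y side; the path covers half of the voxel's own
    plane plus every plane between it and the detector.
    """
    rev = mu_rot[:, ::-1, :]
    cum = np.cumsum(rev, axis=1) - 0.5 * rev
    return np.exp(-voxel_size_cm * cum[:, ::-1, :])


def psf_sigma_vox(geom: Geometry, fwhm0_mm: float, slope_mm_per_cm: float,
                  sigma_quant_vox: float = 0.1) -> np.ndarray:
    """Gaussian sigma (voxel units) per y-plane, quantized for plane grouping.

    fwhm(depth) = fwhm0 + slope * depth; depth measured from the voxel plane
    to the detector plane half a voxel beyond the last y index.
    """
    ny = geom.ny
    depth_cm = (ny - 0.5 - np.arange(ny)) * geom.voxel_size_cm
    fwhm_mm = fwhm0_mm + slope_mm_per_cm * depth_cm
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / geom.voxel_size_mm
    if sigma_quant_vox > 0:
        sigma = np.round(sigma / sigma_quant_vox) * sigma_quant_vox
    return sigma


def nuclear_forward(activity: np.ndarray, mu_rot_factors: np.ndarray,
                    angle_deg: float, sigmas: np.ndarray,
                    scale: float) -> np.ndarray:
    """Expected counts/s image of an activity volume (Bq).

    ``mu_rot_factors`` are precomputed attenuation survival factors on the
    *rotated* grid for this angle; ``scale`` folds sensitivity and flat-panel
    transmission (counts per Bq*s).  Planes sharing a (quantized) PSF sigma
    are summed before blurring -- the blur is linear, so this is exact.
    Zero-padded symmetric kernels keep the per-plane blur self-adjoint.
    """
    rot = rotate_volume(activity, angle_deg)
    rot *= mu_rot_factors
    acc = np.zeros((rot.shape[0], rot.shape[2]))
    for s in np.unique(sigmas):
        plane = rot[:, sigmas == s, :].sum(axis=1)
        if s > 0:
            plane = ndi.gaussian_filter(plane, sigma=s, mode="constant")
        acc += plane
    return _to_det(acc) * scale


def nuclear_backward(img: np.ndarray, mu_rot_factors: np.ndarray,
                     angle_deg: float, sigmas: np.ndarray,
                     scale: float) -> np.ndarray:
    """Exact adjoint of :func:`nuclear_forward`."""
    nx, ny, nz = mu_rot_factors.shape
    plane = _from_det(np.asarray(img, dtype=float)) * scale
    rot = np.empty((nx, ny, nz))
    for s in np.unique(sigmas):
        b = ndi.gaussian_filter(plane, sigma=s, mode="constant") \
            if s > 0 else plane
        rot[:, sigmas == s, :] = b[:, None, :]
    rot *= mu_rot_factors
    return rotate_volume_adjoint(rot, angle_deg)
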