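"""Voxelized torso phantom with an analytic respiratory deformation model.

The phantom is built from geometric primitives -- elliptic-cylinder body,
ellipsoidal lungs and liver, cylindrical spine, an anterior sternum bar and a
30 mm spherical lesion inside the liver -- so that the ground-truth motion is
analytic.  Activity (99mTc) lives only in the liver, split so the lesion's
mean voxel activity is ``uptake_ratio`` times the liver background's.
Attenuation is provided at 140 keV (gamma) and at a single effective x-ray
energy (60 keV equivalent).

The respiratory deformation mirrors the anatomical extrapolation rule used
downstream for motion-vector-field estimation: a uniform superior-inferior
shift below the lungs tapering linearly to zero at the lung apex, and an
anterior-posterior expansion growing linearly from zero at the spine to the
full AP shift at the anterior body surface.  The spine is fixed.  Fields use
the pull-back convention ``warped(p) = ref(p + d(p))`` with displacements in
mm.

Axes: ``vol[ix, iy, iz]``; x = left-right, y anterior(low index)->posterior,
z inferior(0)->superior.  World coordinates (mm) at voxel centers, origin at
the grid center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .exceptions import GeometryError, InvalidParameterError, ShapeError
from .respiration import BreathingPattern, ap_from_diaphragm

__all__ = ["VoxelPhantom", "DisplacementField", "AttenuationCoefficients",
           "build_phantom", "ground_truth_displacement", "warp_volume",
           "phantom_at_amplitude"]


@dataclass(frozen=True)
class AttenuationCoefficients:
    """Linear attenuation (1/cm).  Lungs ~0.25x water; bone exceeds water."""

    water_140kev: float = 0.154
    lung_140kev: float = 0.0385
    bone_140kev: float = 0.25
    water_xray: float = 0.206   # 60 keV effective
    lung_xray: float = 0.0515
    bone_xray: float = 0.55


@dataclass
class VoxelPhantom:
    """Paired activity/attenuation fields with organ masks on one grid."""

    activity: np.ndarray            # Bq per voxel
    attenuation_140kev: np.ndarray  # 1/cm
    attenuation_xray: np.ndarray    # 1/cm
    masks: dict[str, np.ndarray]    # body, lungs, liver, sphere, spine, sternum
    voxel_size_mm: float
    lung_z_range: tuple[int, int]   # (bottom, top) z indices of the lungs
    spine_y_mm: float               # world y of the spine axis
    anterior_y_mm: float            # world y of the anterior body surface

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.activity.shape

    def world_axes(self):
        """World coordinates (mm) of voxel centers along each axis."""
        return tuple((np.arange(n) - (n - 1) / 2.0) * self.voxel_size_mm
                     for n in self.grid_dims)


@dataclass
class DisplacementField:
    """Pull-back displacement field (mm), one 3-vector per voxel."""

    vectors_mm: np.ndarray          # (nx, ny, nz, 3)
    voxel_size_mm: float
    diaphragm_shift_cm: float = 0.0

    @property
    def grid_dims(self):
        return self.vectors_mm.shape[:3]


def _ellipsoid(xx, yy, zz, center, semi):
    return (((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2) <= 1.0


def build_phantom(total_activity_mbq: float = 150.0,
                  uptake_ratio: float = 5.0,
                  grid_dims: tuple[int, int, int] = (128, 128, 100),
                  voxel_size_mm: float = 4.7,
                  seed: int = 0,
                  attenuation: AttenuationCoefficients | None = None,
                  ) -> VoxelPhantom:
    """Build the torso phantom.

    ``uptake_ratio`` r means mean voxel activity in the sphere equals r times
    the mean in the liver background (written 1:r liver:sphere).  Organ
    proportions scale with the field of view so desk-scale grids keep the
    same anatomy.
    """
    if uptake_ratio < 1:
        raise InvalidParameterError("uptake ratio must be >= 1")
    att = attenuation or AttenuationCoefficients()
    nx, ny, nz = grid_dims
    ax = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size_mm
    ay = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size_mm
    az = (np.arange(nz) - (nz - 1) / 2.0) * voxel_size_mm
    xx, yy, zz = np.meshgrid(ax, ay, az, indexing="ij")
    fov = np.array([nx, ny, nz]) * voxel_size_mm

    # body: elliptic cylinder over the full z extent
    body_sx, body_sy = 0.45 * fov[0], 0.32 * fov[1]
    body = ((xx / body_sx) ** 2 + (yy / body_sy) ** 2) <= 1.0

    # lungs: two ellipsoids in the upper thorax
    lung_cz = 0.28 * fov[2]
    lung_sz = 0.21 * fov[2]
    lungs = (_ellipsoid(xx, yy, zz, (+0.16 * fov[0], -0.02 * fov[1], lung_cz),
                        (0.145 * fov[0], 0.20 * fov[1], lung_sz))
             | _ellipsoid(xx, yy, zz, (-0.16 * fov[0], -0.02 * fov[1], lung_cz),
                          (0.145 * fov[0], 0.20 * fov[1], lung_sz)))
    lungs &= body
    z_lung_bot = lung_cz - lung_sz
    z_lung_top = lung_cz + lung_sz

    # liver: ellipsoid capped at the lung bottom (diaphragm boundary)
    liver_c = (0.14 * fov[0], -0.04 * fov[1], z_lung_bot - 0.22 * fov[2])
    liver_s = (0.24 * fov[0], 0.20 * fov[1], 0.22 * fov[2])
    liver = _ellipsoid(xx, yy, zz, liver_c, liver_s) & body & ~lungs
    liver &= zz <= z_lung_bot + 0.5 * voxel_size_mm

    # spine: posterior cylinder, full z
    spine_y = 0.24 * fov[1]
    spine_r = 0.045 * fov[0]
    spine = ((xx ** 2 + (yy - spine_y) ** 2) <= spine_r ** 2) & body

    # sternum: anterior bar over the thorax z range
    sternum = (np.abs(xx) < 0.06 * fov[0]) \
        & (yy < -0.265 * fov[1]) & body \
        & (zz > z_lung_bot) & (zz < z_lung_top)

    # 30 mm lesion inside the liver
    sphere_c = (liver_c[0] + 0.35 * liver_s[0],
                liver_c[1] - 0.2 * liver_s[1],
                liver_c[2] - 0.2 * liver_s[2])
    sphere = _ellipsoid(xx, yy, zz, sphere_c, (15.0, 15.0, 15.0))
    if not np.all(liver[sphere]):
        raise GeometryError("30 mm sphere does not fit inside the liver")
    liver_bg = liver & ~sphere
    spine &= ~liver  # keep masks disjoint where they could touch
    lungs &= ~spine

    # attenuation
    att140 = np.zeros(grid_dims)
    attx = np.zeros(grid_dims)
    att140[body] = att.water_140kev
    attx[body] = att.water_xray
    att140[lungs] = att.lung_140kev
    attx[lungs] = att.lung_xray
    for bone in (spine, sternum):
        att140[bone] = att.bone_140kev
        attx[bone] = att.bone_xray

    # activity: sphere mean = r * background mean; total fixed
    total_bq = total_activity_mbq * 1e6
    n_s = int(sphere.sum())
    n_b = int(liver_bg.sum())
    a_bg = total_bq / (n_b + uptake_ratio * n_s)
    activity = np.zeros(grid_dims)
    activity[liver_bg] = a_bg
    activity[sphere] = uptake_ratio * a_bg

    masks = {"body": body, "lungs": lungs, "liver": liver,
             "sphere": sphere, "spine": spine, "sternum": sternum}
    return VoxelPhantom(
        activity=activity, attenuation_140kev=att140, attenuation_xray=attx,
        masks=masks, voxel_size_mm=voxel_size_mm,
        lung_z_range=(int(round((z_lung_bot - az[0]) / voxel_size_mm)),
                      int(round((z_lung_top - az[0]) / voxel_size_mm))),
        spine_y_mm=spine_y, anterior_y_mm=-body_sy)


def respiratory_field(grid_dims, voxel_size_mm, body, spine,
                      lung_z_range, spine_y_mm, anterior_y_mm,
                      diaphragm_shift_mm: float, ap_shift_mm: float,
                      rigid_mask: np.ndarray | None = None) -> np.ndarray:
    """Anatomy-extrapolated pull-back field (mm) for given scalar shifts.

    SI component: full shift below the lungs, linear taper to zero at the
    lung apex.  AP component: zero at (and posterior of) the spine, linear to
    ``ap_shift_mm`` at the anterior surface, continued at full strength into
    the air in front of it so the surface itself rises on inhalation (a field
    truncated at the body contour cannot expand the body under pull-back
    warping).  Spine voxels are fixed.  ``rigid_mask`` (the liver in the
    ground-truth motion model) translates as a block with the AP value at
    its centroid, so the compressive divergence of the ramp does not deform
    it -- the liver is treated as rigid.  Shared between the phantom ground
    truth and MVF construction, and linear in (diaphragm_shift, ap_shift) by
    construction.
    """
    nx, ny, nz = grid_dims
    field = np.zeros((nx, ny, nz, 3))
    zb, zt = lung_z_range
    wz = np.ones(nz)
    iz = np.arange(nz)
    span = max(zt - zb, 1)
    wz[iz > zb] = np.clip(1.0 - (iz[iz > zb] - zb) / span, 0.0, 1.0)
    ay = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size_mm
    wy = np.clip((spine_y_mm - ay) / (spine_y_mm - anterior_y_mm), 0.0, 1.0)
    field[..., 2] = diaphragm_shift_mm * wz[None, None, :]
    field[..., 1] = ap_shift_mm * wy[None, :, None]
    if rigid_mask is not None and np.any(rigid_mask):
        iy_c = np.nonzero(rigid_mask)[1].mean()
        wy_c = float(np.clip((spine_y_mm - (iy_c - (ny - 1) / 2.0)
                              * voxel_size_mm)
                             / (spine_y_mm - anterior_y_mm), 0.0, 1.0))
        # dilate so the field discontinuity sits in inactive tissue, not on
        # the organ surface (a boundary jump double-counts surface voxels)
        shell = ndi.binary_dilation(rigid_mask, iterations=3)
        field[shell, 1] = ap_shift_mm * wy_c
    field[spine] = 0.0
    return field


def ground_truth_displacement(phantom: VoxelPhantom, diaphragm_shift_cm: float,
                              ap_shift_cm: float) -> DisplacementField:
    """Ground-truth pull-back field for a breathing state (shifts in cm)."""
    vec = respiratory_field(
        phantom.grid_dims, phantom.voxel_size_mm, phantom.masks["body"],
        phantom.masks["spine"], phantom.lung_z_range, phantom.spine_y_mm,
        phantom.anterior_y_mm, 10.0 * diaphragm_shift_cm, 10.0 * ap_shift_cm,
        rigid_mask=phantom.masks["liver"])
    return DisplacementField(vectors_mm=vec,
                             voxel_size_mm=phantom.voxel_size_mm,
                             diaphragm_shift_cm=diaphragm_shift_cm)


def warp_volume(volume: np.ndarray, disp: DisplacementField,
                interpolation: str = "linear") -> np.ndarray:
    """Pull-back resampling ``out(p) = in(p + d(p))``; outside reads as 0."""
    if volume.shape != disp.grid_dims:
        raise ShapeError(f"volume {volume.shape} vs field {disp.grid_dims}")
    order = {"linear": 1, "nearest": 0}[interpolation]
    if not np.any(disp.vectors_mm):
        return volume.astype(float, copy=True)
    nx, ny, nz = volume.shape
    grid = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                       indexing="ij")
    coords = [g + disp.vectors_mm[..., i] / disp.voxel_size_mm
              for i, g in enumerate(grid)]
    return ndi.map_coordinates(volume.astype(float), coords, order=order,
                               mode="constant", cval=0.0)


def phantom_at_amplitude(phantom: VoxelPhantom, diaphragm_displacement_cm: float,
                         pattern: BreathingPattern):
    """Pose the phantom at an instantaneous diaphragm displacement.

    Returns (activity, attenuation_140keV, attenuation_xray) warped by the
    ground-truth field with the pattern's coupled AP expansion.
    """
    ap = float(ap_from_diaphragm(diaphragm_displacement_cm, pattern))
    disp = ground_truth_displacement(phantom, diaphragm_displacement_cm, ap)
    return (warp_volume(phantom.activity, disp),
            warp_volume(phantom.attenuation_140kev, disp),
            warp_volume(phantom.attenuation_xray, disp))
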