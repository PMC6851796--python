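"""Fluoroscopic projection simulation with a dose-dependent noise model.

X-ray transport is an analytic parallel-beam line integral of the posed
attenuation map (scatter and beam hardening out of scope).  Detector noise
follows the compound model fitted on clinical flat-panel data,

    sigma(mu) = sigma0 + c * sqrt(mu)

with an electrical floor ``sigma0`` and a Poisson-like term scaling with the
square root of the pixel expectation ``mu``; the expectation itself scales
linearly with the per-frame dose.  The default parameters are configuration
(the scanner-calibration constants are not public) and were chosen so that a
1-1000 uGy total-dose sweep spans boundary-invisible to organs-visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np

from . import _projops
from ._projops import Geometry
from .exceptions import InvalidParameterError
from .phantom import VoxelPhantom, phantom_at_amplitude
from .respiration import MotionSignal

__all__ = ["NoiseModel", "FluoroSet", "project_xray",
           "line_integrals_to_intensity", "add_fluoro_noise",
           "simulate_fluoro_acquisition", "PoseCache"]


@dataclass(frozen=True)
class NoiseModel:
    """Dose-noise model of the flat panel.

    ``reference_flux`` is the mean unattenuated detector signal at
    ``reference_dose_ugy`` per frame; sigma(mu) = sigma0 + c*sqrt(mu).
    """

    sigma0: float = 2.0
    c: float = 1.0
    reference_dose_ugy: float = 1.0
    reference_flux: float = 2000.0

    def __post_init__(self):
        if self.sigma0 < 0 or self.c < 0 or self.reference_flux <= 0:
            raise InvalidParameterError("invalid noise-model parameters")

    def sigma(self, mu):
        return self.sigma0 + self.c * np.sqrt(np.maximum(mu, 0.0))

    def flux_at(self, dose_per_frame_ugy: float) -> float:
        """Unattenuated pixel expectation: linear in dose."""
        return self.reference_flux * dose_per_frame_ugy / self.reference_dose_ugy


@dataclass
class FluoroSet:
    """Time- and angle-stamped fluoroscopic frame stack (detector units)."""

    frames: np.ndarray            # (n_frames, rows, cols)
    timestamps_s: np.ndarray
    angle_indices: np.ndarray
    angles_deg: np.ndarray        # per frame
    dose_per_frame_ugy: float
    geometry: Geometry
    noise_model: NoiseModel
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(self.timestamps_s[1] - self.timestamps_s[0])

    def sidecar(self) -> dict:
        return {"timestamps_s": self.timestamps_s.tolist(),
                "angles_deg": self.angles_deg.tolist(),
                "angle_indices": self.angle_indices.tolist(),
                "dose_per_frame_ugy": self.dose_per_frame_ugy,
                "noise_model": asdict(self.noise_model),
                "seed": self.seed}


def project_xray(attenuation_xray: np.ndarray, angle_deg: float,
                 geometry: Geometry) -> np.ndarray:
    """Parallel-beam line integrals (dimensionless) at a gantry angle."""
    return _projops.xray_forward(attenuation_xray, angle_deg,
                                 geometry.voxel_size_cm)


def line_integrals_to_intensity(line_integrals: np.ndarray,
                                dose_per_frame_ugy: float,
                                model: NoiseModel) -> np.ndarray:
    """Noise-free detector expectation: flux(dose) * exp(-line integral)."""
    if dose_per_frame_ugy <= 0:
        raise InvalidParameterError("dose per frame must be > 0")
    return model.flux_at(dose_per_frame_ugy) * np.exp(-line_integrals)


def add_fluoro_noise(expectation: np.ndarray, model: NoiseModel,
                     seed=None) -> np.ndarray:
    """Gaussian noise with sd sigma0 + c*sqrt(mu), truncated at zero."""
    if np.any(expectation < 0):
        raise InvalidParameterError("expectation must be nonnegative")
    rng = np.random.default_rng(seed)
    sig = model.sigma(expectation)
    if not np.any(sig > 0):
        return expectation.astype(float, copy=True)
    out = expectation + sig * rng.standard_normal(expectation.shape)
    return np.maximum(out, 0.0)


class PoseCache:
    """Posed phantom volumes cached on a quantized diaphragm amplitude.

    The instantaneous diaphragm displacement is quantized (default 0.5 mm,
    far below the voxel size) so acquisition loops reuse warped volumes and
    projections across subframes at the same breathing state.
    """

    def __init__(self, phantom: VoxelPhantom, pattern,
                 quant_cm: float = 0.05):
        self.phantom = phantom
        self.pattern = pattern
        self.quant_cm = quant_cm
        self._poses: dict[int, tuple] = {}
        self._proj: dict = {}

    def level(self, displacement_cm: float) -> int:
        return int(round(displacement_cm / self.quant_cm))

    def pose(self, level: int):
        """(activity, att140, attx) at a quantized amplitude level."""
        if level not in self._poses:
            self._poses[level] = phantom_at_amplitude(
                self.phantom, level * self.quant_cm, self.pattern)
        return self._poses[level]

    def projection(self, kind: str, level: int, angle_idx: int, fn):
        """Memoized per-(kind, pose, angle) projection; fn computes it."""
        key = (kind, level, angle_idx)
        if key not in self._proj:
            self._proj[key] = fn(*self.pose(level))
        return self._proj[key]


def simulate_fluoro_acquisition(phantom: VoxelPhantom, signal: MotionSignal,
                                geometry: Geometry, sampling_rate_hz: float,
                                total_dose_ugy: float, model: NoiseModel,
                                seed=None, pose_cache: PoseCache | None = None,
                                ) -> FluoroSet:
    """Simulate the full fluoroscopic stack of a step-and-shoot scan.

    Frames are sampled at 1/rate intervals over the signal duration; each
    frame poses the phantom at the instantaneous diaphragm displacement and
    uses the gantry angle scheduled at its timestamp.  The total dose is
    split evenly over the frames.
    """
    if total_dose_ugy <= 0:
        raise InvalidParameterError("total dose must be > 0")
    scan_time = signal.duration_s
    n = int(round(scan_time * sampling_rate_hz))
    times = np.arange(n) / sampling_rate_hz
    dose_per_frame = total_dose_ugy / n
    angle_idx = geometry.angle_index_at(times, scan_time)
    disp = signal.value_at(times)
    cache = pose_cache or PoseCache(phantom, signal.pattern)
    rng = np.random.default_rng(seed)

    frames = np.empty((n,) + geometry.det_shape)
    for i in range(n):
        lvl = cache.level(disp[i])

        def _proj(_act, _a140, attx):
            return project_xray(attx, geometry.angles_deg[angle_idx[i]],
                                geometry)

        li = cache.projection("xray_li", lvl, int(angle_idx[i]), _proj)
        mu = line_integrals_to_intensity(li, dose_per_frame, model)
        frames[i] = add_fluoro_noise(mu, model, rng)
    return FluoroSet(frames=frames, timestamps_s=times,
                     angle_indices=angle_idx,
                     angles_deg=geometry.angles_deg[angle_idx],
                     dose_per_frame_ugy=dose_per_frame, geometry=geometry,
                     noise_model=model,
                     seed=seed if isinstance(seed, int) else None)
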