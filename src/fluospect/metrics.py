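"""Evaluation metrics: activity recovery, relative noise, CNR, aggregation.

All metrics are evaluated in the reference (end-exhale, bin-1) pose.  The
lesion VOI is the phantom's sphere mask; the background VOI is the liver mask
minus the sphere dilated by one voxel.  Activity recovery is the recovered
sphere activity over the true inserted sphere activity; relative noise is the
background standard deviation over its mean; CNR is
(sphere mean - background mean) / background standard deviation, with the
Rose criterion CNR >= 4 marking the sphere detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .exceptions import AggregationError, InvalidMaskError, UndefinedMetricError
from .phantom import VoxelPhantom

__all__ = ["MetricsReport", "activity_recovery", "relative_noise", "cnr",
           "max_cnr", "aggregate_realizations", "background_mask",
           "MetricsTracker", "ROSE_CNR"]

ROSE_CNR = 4.0


def background_mask(phantom: VoxelPhantom, dilate_voxels: int = 1
                    ) -> np.ndarray:
    """Liver minus the sphere dilated by ``dilate_voxels``."""
    sphere = ndi.binary_dilation(phantom.masks["sphere"],
                                 iterations=dilate_voxels)
    return phantom.masks["liver"] & ~sphere


def activity_recovery(recon: np.ndarray, sphere_mask: np.ndarray,
                      true_sphere_activity_bq: float) -> float:
    """Recovered / true activity inside the (reference-pose) sphere VOI."""
    if not np.any(sphere_mask):
        raise InvalidMaskError("empty sphere mask")
    if true_sphere_activity_bq <= 0:
        raise InvalidMaskError("true sphere activity must be > 0")
    return float(recon[sphere_mask].sum() / true_sphere_activity_bq)


def relative_noise(recon: np.ndarray, bg_mask: np.ndarray) -> float:
    """Sample standard deviation / mean over the background VOI."""
    if not np.any(bg_mask):
        raise InvalidMaskError("empty background mask")
    vals = recon[bg_mask]
    m = vals.mean()
    if m <= 0:
        raise UndefinedMetricError("background mean is non-positive")
    return float(vals.std(ddof=1) / m)


def cnr(recon: np.ndarray, sphere_mask: np.ndarray,
        bg_mask: np.ndarray) -> float:
    """(sphere mean - background mean) / background sample std."""
    if not np.any(sphere_mask) or not np.any(bg_mask):
        raise InvalidMaskError("empty VOI mask")
    bg = recon[bg_mask]
    sd = bg.std(ddof=1)
    if sd == 0:
        raise UndefinedMetricError("zero background standard deviation")
    return float((recon[sphere_mask].mean() - bg.mean()) / sd)


def max_cnr(cnr_per_iteration: np.ndarray) -> tuple[float, int]:
    """Maximum CNR over iterations and its first 1-based argmax."""
    arr = np.asarray(cnr_per_iteration, dtype=float)
    if arr.size == 0:
        raise InvalidMaskError("need at least one iteration")
    i = int(np.argmax(arr))
    return float(arr[i]), i + 1


@dataclass
class MetricsReport:
    """Per-iteration metric curves for one reconstruction (or aggregate)."""

    activity_recovery: np.ndarray
    relative_noise: np.ndarray
    cnr: np.ndarray
    descriptor: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)   # per-metric std when aggregated
    n_realizations: int = 1

    @property
    def max_cnr(self) -> tuple[float, int]:
        return max_cnr(self.cnr)

    def row(self) -> dict:
        v, it = self.max_cnr
        out = dict(self.descriptor)
        out.update({
            "max_cnr": v, "max_cnr_iteration": it,
            "recovery_final": float(self.activity_recovery[-1]),
            "noise_final": float(self.relative_noise[-1]),
            "detectable": bool(v >= ROSE_CNR)})
        if self.std:
            out["max_cnr_std"] = self.std.get("max_cnr", 0.0)
        return out


class MetricsTracker:
    """Iteration callback computing the metric curves during MLEM."""

    def __init__(self, phantom: VoxelPhantom, descriptor: dict | None = None):
        self.sphere = phantom.masks["sphere"]
        self.bg = background_mask(phantom)
        self.true_sphere_bq = float(phantom.activity[self.sphere].sum())
        self.descriptor = descriptor or {}
        self._rec, self._noise, self._cnr = [], [], []

    def __call__(self, it: int, x: np.ndarray) -> None:
        self._rec.append(activity_recovery(x, self.sphere,
                                           self.true_sphere_bq))
        self._noise.append(relative_noise(x, self.bg))
        self._cnr.append(cnr(x, self.sphere, self.bg))

    def report(self) -> MetricsReport:
        return MetricsReport(activity_recovery=np.asarray(self._rec),
                             relative_noise=np.asarray(self._noise),
                             cnr=np.asarray(self._cnr),
                             descriptor=dict(self.descriptor))


def aggregate_realizations(reports: list[MetricsReport]) -> MetricsReport:
    """Mean and sample std over noise realizations of identical experiments.

    Descriptors must agree except for the ``seed`` entry; the aggregate's
    ``std`` dict carries the per-metric, per-iteration standard deviations
    and the max-CNR spread (the "22.3 +/- 0.7" presentation).
    """
    if len(reports) < 2:
        raise AggregationError("need at least two reports")

    def _key(rep):
        return {k: v for k, v in rep.descriptor.items()
                if k not in ("seed", "realization")}

    ref = _key(reports[0])
    for rep in reports[1:]:
        if _key(rep) != ref:
            raise AggregationError("experiment descriptors differ")
    rec = np.stack([r.activity_recovery for r in reports])
    noi = np.stack([r.relative_noise for r in reports])
    cn = np.stack([r.cnr for r in reports])
    maxes = np.array([r.max_cnr[0] for r in reports])
    return MetricsReport(
        activity_recovery=rec.mean(axis=0),
        relative_noise=noi.mean(axis=0),
        cnr=cn.mean(axis=0),
        descriptor=ref,
        std={"activity_recovery": rec.std(axis=0, ddof=1),
             "relative_noise": noi.std(axis=0, ddof=1),
             "cnr": cn.std(axis=0, ddof=1),
             "max_cnr": float(maxes.std(ddof=1)),
             "max_cnr_mean": float(maxes.mean())},
        n_realizations=len(reports))
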