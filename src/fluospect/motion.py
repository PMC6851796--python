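"""Respiratory signal extraction from fluoroscopic frames, and binning.

The diaphragm surrogate is the row center-of-mass of a horizontal-band
("vertical strip") of the frame centered on the lung-liver boundary: as the
bright lung region extends inferiorly on inhalation the center-of-mass row
increases.  The slowly varying background from gantry rotation is removed
(centered moving average by default, per-gantry-angle mean as an alternative
for step-and-shoot schedules), peaks in the detrended signal define the
per-cycle maximum-motion envelope, per-cycle minima define the floor (needed
for baseline-shift patterns), and the normalized signal in [0, 1] is split
into equal-width amplitude bins.  Bin 1 is the low-amplitude (end-exhale)
reference bin; gating accepts frames below a normalized threshold.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal

from .exceptions import (DegenerateSignalError, ExtractionFailureError,
                         InvalidParameterError, UndefinedComError)
from .fluoro import FluoroSet
from .nuclear import NuclearSet

__all__ = ["StripSpec", "BinningScheme", "ExtractedSignal",
           "auto_strip", "center_of_mass_signal", "remove_background",
           "detect_peaks", "normalize_signal", "assign_bins", "gating_mask",
           "propagate_bins_to_nuclear", "extract_motion"]


@dataclass(frozen=True)
class StripSpec:
    """Detector band used for center-of-mass tracking.

    ``height_rows`` rows centered on ``center_row`` (the lung-liver boundary),
    restricted to ``col_range`` columns.
    """

    center_row: int
    height_rows: int = 50
    col_range: tuple[int, int] | None = None   # [lo, hi); None = central half

    def rows(self, n_rows: int) -> slice:
        lo = max(self.center_row - self.height_rows // 2, 0)
        hi = min(lo + self.height_rows, n_rows)
        return slice(lo, hi)

    def cols(self, n_cols: int) -> slice:
        if self.col_range is None:
            return slice(n_cols // 4, n_cols - n_cols // 4)
        return slice(*self.col_range)


@dataclass(frozen=True)
class BinningScheme:
    """Equal-width amplitude bins on [0, 1]; half-open, top bin closed."""

    n_bins: int = 5

    def __post_init__(self):
        if self.n_bins < 1:
            raise InvalidParameterError("need at least one bin")

    @property
    def boundaries(self) -> np.ndarray:
        return np.arange(1, self.n_bins) / self.n_bins


@dataclass
class ExtractedSignal:
    """Per-frame surrogate signal through every extraction stage."""

    timestamps_s: np.ndarray
    angle_indices: np.ndarray
    raw_com: np.ndarray
    background: np.ndarray
    detrended: np.ndarray
    peak_indices: np.ndarray
    normalized: np.ndarray
    bin_index: np.ndarray           # 1-based
    gated: np.ndarray               # bool, True = accepted
    strip: StripSpec
    scheme: BinningScheme
    gating_threshold: float

    def to_csv(self, path, params: dict | None = None) -> None:
        path = Path(path)
        buf = io.StringIO()
        buf.write("frame,time_s,raw_com,background,detrended,"
                  "normalized,bin,gated\n")
        for i in range(len(self.raw_com)):
            buf.write(f"{i},{float(self.timestamps_s[i])!r},"
                      f"{float(self.raw_com[i])!r},"
                      f"{float(self.background[i])!r},"
                      f"{float(self.detrended[i])!r},"
                      f"{float(self.normalized[i])!r},{self.bin_index[i]},"
                      f"{int(self.gated[i])}\n")
        path.write_text(buf.getvalue())
        meta = {"strip": {"center_row": self.strip.center_row,
                          "height_rows": self.strip.height_rows,
                          "col_range": self.strip.col_range},
                "n_bins": self.scheme.n_bins,
                "gating_threshold": self.gating_threshold}
        meta.update(params or {})
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def auto_strip(frames: np.ndarray, height_rows: int | None = None) -> StripSpec:
    """Place the strip on the respiratory motion band.

    The strip is centered on the row whose summed intensity varies most over
    time -- the band of lung tissue modulated by the moving lung-liver
    boundary.  With a single frame the fallback is the row of maximum
    vertical intensity gradient.  The default height is 50 rows, shrunk on
    small detectors to ~40% of the rows so the strip stays a band.
    """
    n_rows, n_cols = frames.shape[1:]
    cols = slice(n_cols // 4, n_cols - n_cols // 4)
    if height_rows is None:
        height_rows = min(50, max(8, int(round(0.4 * n_rows))))
    if frames.shape[0] > 1:
        profile = frames[:, :, cols].sum(axis=2).std(axis=0)
        center = int(np.argmax(profile))
    else:
        grad = np.abs(np.diff(frames[0].mean(axis=1)))
        center = int(np.argmax(grad))
    return StripSpec(center_row=center, height_rows=height_rows)


def center_of_mass_signal(frames, strip: StripSpec) -> np.ndarray:
    """Row center-of-mass of the strip, one value per frame (row units)."""
    stack = frames.frames if isinstance(frames, FluoroSet) else frames
    n_rows, n_cols = stack.shape[1:]
    rs = strip.rows(n_rows)
    if rs.start >= rs.stop:
        raise InvalidParameterError("strip outside frame bounds")
    w = stack[:, rs, strip.cols(n_cols)].sum(axis=2)
    tot = w.sum(axis=1)
    if np.any(tot <= 0):
        raise UndefinedComError("all-zero strip in at least one frame")
    rows = np.arange(rs.start, rs.stop)
    return (w * rows).sum(axis=1) / tot


def remove_background(raw_com: np.ndarray, window_s: float,
                      sample_rate_hz: float, mode: str = "moving_average",
                      angle_indices: np.ndarray | None = None):
    """Estimate and subtract the gantry-rotation background.

    ``moving_average``: centered moving average with a truncated window at
    the edges.  ``per_angle``: mean of the frames sharing each gantry angle
    (exact for step-and-shoot schedules when the dwell covers a full cycle).
    Returns (background, detrended).
    """
    raw_com = np.asarray(raw_com, dtype=float)
    n = len(raw_com)
    if mode == "per_angle":
        if angle_indices is None:
            raise InvalidParameterError("per_angle mode needs angle indices")
        bg = np.empty(n)
        for a in np.unique(angle_indices):
            sel = angle_indices == a
            bg[sel] = raw_com[sel].mean()
    else:
        win = int(round(window_s * sample_rate_hz))
        if win > n:
            raise InvalidParameterError("window longer than signal")
        half = win // 2
        csum = np.concatenate([[0.0], np.cumsum(raw_com)])
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n)
        bg = (csum[hi] - csum[lo]) / (hi - lo)
    return bg, raw_com - bg


def detect_peaks(detrended: np.ndarray, min_separation_s: float,
                 sample_rate_hz: float,
                 prominence_fraction: float = 0.3) -> np.ndarray:
    """Respiratory peaks: prominent local maxima at least one near-cycle apart.

    Prominence threshold is a fraction of the robust signal amplitude
    (4 x median absolute value).
    """
    if min_separation_s <= 0:
        raise InvalidParameterError("min separation must be > 0")
    amp = 4.0 * np.median(np.abs(detrended))
    peaks, _ = scipy.signal.find_peaks(
        detrended, distance=max(int(round(min_separation_s * sample_rate_hz)), 1),
        prominence=prominence_fraction * amp if amp > 0 else None)
    if len(peaks) == 0 or amp == 0:
        raise ExtractionFailureError("no respiratory peaks found")
    return peaks


def _lower_envelope_indices(detrended: np.ndarray,
                            peaks: np.ndarray) -> np.ndarray:
    """Per-cycle minima: argmin between consecutive peaks and at the ends."""
    idx = []
    segments = [(0, peaks[0])] + \
        [(peaks[i], peaks[i + 1]) for i in range(len(peaks) - 1)] + \
        [(peaks[-1], len(detrended))]
    for lo, hi in segments:
        if hi - lo > 1:
            idx.append(lo + int(np.argmin(detrended[lo:hi])))
    return np.unique(idx)


def normalize_signal(detrended: np.ndarray,
                     peak_indices: np.ndarray) -> np.ndarray:
    """Scale between the per-cycle minima floor and the peak envelope.

    Both envelopes are piecewise-linear through their support points with
    constant extrapolation outside; output clipped to [0, 1].
    """
    if len(peak_indices) < 2:
        raise ExtractionFailureError("need at least two peaks to normalize")
    x = np.arange(len(detrended))
    upper = np.interp(x, peak_indices, detrended[peak_indices])
    mins = _lower_envelope_indices(detrended, peak_indices)
    lower = np.interp(x, mins, detrended[mins])
    span = upper - lower
    if np.any(span <= 0):
        raise DegenerateSignalError("upper envelope does not exceed floor")
    return np.clip((detrended - lower) / span, 0.0, 1.0)


def assign_bins(normalized: np.ndarray, scheme: BinningScheme) -> np.ndarray:
    """1-based equal-width bin index; intervals [lo, hi), top bin closed."""
    b = np.floor(np.asarray(normalized) * scheme.n_bins).astype(int) + 1
    return np.clip(b, 1, scheme.n_bins)


def gating_mask(normalized: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Accept frames at or below the normalized amplitude threshold."""
    if not 0.0 < threshold < 1.0:
        raise InvalidParameterError("threshold must be in (0, 1)")
    return np.asarray(normalized) <= threshold


def propagate_bins_to_nuclear(extracted: ExtractedSignal,
                              nuclear: NuclearSet):
    """Label each nuclear subframe with its fluoro frame's bin and gate flag.

    A subframe inherits the label of the nearest *preceding* fluoroscopic
    frame; subframes before the first frame take the first frame's label.
    Returns (bin_index, gated) per subframe.
    """
    pos = np.searchsorted(extracted.timestamps_s, nuclear.timestamps_s,
                          side="right") - 1
    pos = np.clip(pos, 0, len(extracted.timestamps_s) - 1)
    return extracted.bin_index[pos], extracted.gated[pos]


def extract_motion(fluoro: FluoroSet, strip: StripSpec | None = None,
                   scheme: BinningScheme = BinningScheme(5),
                   background_window_s: float = 10.0,
                   background_mode: str = "moving_average",
                   min_separation_s: float | None = None,
                   nominal_period_s: float = 5.0,
                   gating_threshold: float = 0.2) -> ExtractedSignal:
    """Full extraction pipeline: strip COM -> detrend -> peaks -> bins."""
    strip = strip or auto_strip(fluoro.frames)
    raw = center_of_mass_signal(fluoro, strip)
    bg, det = remove_background(raw, background_window_s,
                                fluoro.sampling_rate_hz, background_mode,
                                fluoro.angle_indices)
    sep = min_separation_s if min_separation_s is not None \
        else 0.6 * nominal_period_s
    peaks = detect_peaks(det, sep, fluoro.sampling_rate_hz)
    norm = normalize_signal(det, peaks)
    bins = assign_bins(norm, scheme)
    gate = gating_mask(norm, gating_threshold)
    return ExtractedSignal(timestamps_s=fluoro.timestamps_s,
                           angle_indices=fluoro.angle_indices,
                           raw_com=raw, background=bg, detrended=det,
                           peak_indices=peaks, normalized=norm,
                           bin_index=bins, gated=gate, strip=strip,
                           scheme=scheme, gating_threshold=gating_threshold)
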