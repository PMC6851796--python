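"""Parametric respiratory signals: diaphragm displacement versus time.

Six breathing patterns are modelled, one stable and five irregular: a phase
(period) change halfway through the scan, an amplitude change, a baseline
shift, and two randomized patterns with per-cycle draws of amplitude, period
and baseline.  Each cycle is a raised cosine

    a(phi) = amplitude * (1 - cos 2 pi phi) / 2,   phi in [0, 1)

starting and ending at end-exhale, so phase is continuous across parameter
switches (which take effect at the first cycle boundary at or after the
switch instant).  Diaphragm displacement (cm, superior->inferior excursion)
couples to anterior-posterior chest expansion through a fixed ratio
(1.2 cm AP per 2.0 cm diaphragm for the default pattern), preserved when the
amplitude is scaled.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["BreathingPattern", "MotionSignal", "waveform_value",
           "generate_breathing_signal", "ap_from_diaphragm",
           "PATTERN_KINDS"]

PATTERN_KINDS = ("stable", "phase_change", "amplitude_change",
                 "baseline_shift", "small_variations", "large_variations")


@dataclass(frozen=True)
class BreathingPattern:
    """Parameters of one respiratory pattern.

    Defaults reproduce stable breathing: 5 s cycle, 2.0 cm maximum diaphragm
    excursion, 1.2 cm AP expansion, zero baseline.  ``switch_time_fraction``
    places the parameter switch of the *_change / *_shift kinds as a fraction
    of scan duration.  The random kinds draw per-cycle values uniformly from
    the closed ranges: ``small_variations`` draws the cycle *peak* in
    ``amplitude_range`` (cm) and the baseline in ``baseline_range``;
    ``large_variations`` draws the oscillation amplitude, period and baseline.
    """

    kind: str = "stable"
    period_s: float = 5.0
    diaphragm_amplitude_cm: float = 2.0
    ap_expansion_cm: float = 1.2
    baseline_cm: float = 0.0
    switch_time_fraction: float = 0.5
    # switched-to values for the *_change kinds
    period2_s: float = 3.0
    amplitude2_cm: float = 3.0
    ap_expansion2_cm: float = 1.8
    baseline_shift_cm: float = 1.0
    # per-cycle draw ranges for the random kinds
    amplitude_range_cm: tuple[float, float] = (2.0, 2.5)
    baseline_range_cm: tuple[float, float] = (0.0, 0.5)
    period_range_s: tuple[float, float] = (3.0, 7.0)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in PATTERN_KINDS:
            raise InvalidParameterError(f"unknown pattern kind {self.kind!r}")
        if self.period_s <= 0 or self.diaphragm_amplitude_cm <= 0 \
                or self.ap_expansion_cm <= 0:
            raise InvalidParameterError(
                "period, diaphragm amplitude and AP expansion must be > 0")
        if not 0.0 <= self.switch_time_fraction <= 1.0:
            raise InvalidParameterError("switch_time_fraction must be in [0,1]")
        for rng_ in (self.amplitude_range_cm, self.baseline_range_cm,
                     self.period_range_s):
            if len(rng_) != 2 or rng_[1] < rng_[0]:
                raise InvalidParameterError(f"empty range {rng_!r}")

    @property
    def ap_ratio(self) -> float:
        """AP expansion per unit diaphragm displacement (scaled AP)."""
        return self.ap_expansion_cm / self.diaphragm_amplitude_cm


def waveform_value(phase_fraction, amplitude_cm):
    """Raised-cosine intra-cycle waveform, 0 at end-exhale, peak at phi=0.5."""
    amplitude_cm = np.asarray(amplitude_cm, dtype=float)
    if np.any(amplitude_cm < 0):
        raise InvalidParameterError("amplitude must be nonnegative")
    phi = np.asarray(phase_fraction, dtype=float)
    val = amplitude_cm * (1.0 - np.cos(2.0 * np.pi * phi)) / 2.0
    return val if val.shape else float(val)


def ap_from_diaphragm(diaphragm_displacement_cm, pattern: BreathingPattern):
    """Map diaphragm displacement to AP expansion via the pattern's ratio."""
    return np.asarray(diaphragm_displacement_cm, dtype=float) * pattern.ap_ratio


@dataclass
class MotionSignal:
    """Diaphragm displacement over time, with per-sample ground truth.

    ``true_normalized_amplitude`` is the within-cycle normalized amplitude
    (1 - cos 2 pi phi)/2 in [0, 1] -- the quantity amplitude binning targets.
    ``cycle_index`` labels the breathing cycle of every sample.
    """

    times_s: np.ndarray
    diaphragm_cm: np.ndarray
    true_normalized_amplitude: np.ndarray
    cycle_index: np.ndarray
    pattern: BreathingPattern

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(self.times_s[1] - self.times_s[0])

    @property
    def duration_s(self) -> float:
        return float(len(self.times_s)) / self.sample_rate_hz

    def value_at(self, t) -> np.ndarray:
        """Displacement at arbitrary times (linear interpolation)."""
        return np.interp(t, self.times_s, self.diaphragm_cm)

    def to_csv(self, path, header: dict | None = None) -> None:
        """Two-column CSV (time_s, diaphragm_cm) + JSON header sidecar."""
        path = Path(path)
        buf = io.StringIO()
        buf.write("time_s,diaphragm_cm\n")
        for t, d in zip(self.times_s, self.diaphragm_cm):
            buf.write(f"{float(t)!r},{float(d)!r}\n")
        path.write_text(buf.getvalue())
        meta = asdict(self.pattern)
        meta.update(header or {})
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _cycle_params(pattern: BreathingPattern, duration_s: float):
    """Yield (period, amplitude, baseline) per cycle until duration covered."""
    rng = np.random.default_rng(pattern.seed)
    t_switch = pattern.switch_time_fraction * duration_s
    cycles = []
    t = 0.0
    while t < duration_s:
        switched = t >= t_switch
        k = pattern.kind
        if k == "stable":
            p, a, b = pattern.period_s, pattern.diaphragm_amplitude_cm, \
                pattern.baseline_cm
        elif k == "phase_change":
            p = pattern.period2_s if switched else pattern.period_s
            a, b = pattern.diaphragm_amplitude_cm, pattern.baseline_cm
        elif k == "amplitude_change":
            p = pattern.period_s
            a = pattern.amplitude2_cm if switched \
                else pattern.diaphragm_amplitude_cm
            b = pattern.baseline_cm
        elif k == "baseline_shift":
            p, a = pattern.period_s, pattern.diaphragm_amplitude_cm
            b = pattern.baseline_cm + (pattern.baseline_shift_cm
                                       if switched else 0.0)
        elif k == "small_variations":
            p = pattern.period_s
            peak = rng.uniform(*pattern.amplitude_range_cm)
            b = rng.uniform(*pattern.baseline_range_cm)
            a = peak - b
        else:  # large_variations
            a = rng.uniform(*pattern.amplitude_range_cm)
            p = rng.uniform(*pattern.period_range_s)
            b = rng.uniform(*pattern.baseline_range_cm)
        cycles.append((t, p, a, b))
        t += p
    return cycles


def generate_breathing_signal(pattern: BreathingPattern, duration_s: float,
                              sample_rate_hz: float) -> MotionSignal:
    """Sample the pattern at a uniform rate over ``duration_s``.

    Deterministic given (pattern, duration, rate): random kinds use the
    pattern's stored seed.
    """
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise InvalidParameterError("duration and sample rate must be > 0")
    # random ranges for the two variation kinds: override defaults per kind
    if pattern.kind == "large_variations" and \
            pattern.amplitude_range_cm == (2.0, 2.5):
        pattern = BreathingPattern(
            **{**asdict(pattern),
               "amplitude_range_cm": (0.5, 2.0),
               "baseline_range_cm": (0.0, 1.0)})
    n = int(round(duration_s * sample_rate_hz))
    times = np.arange(n) / sample_rate_hz
    cycles = _cycle_params(pattern, duration_s)
    starts = np.array([c[0] for c in cycles])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, None)
    disp = np.empty(n)
    norm = np.empty(n)
    for i, (t0, p, a, b) in enumerate(cycles):
        sel = idx == i
        if not np.any(sel):
            continue
        phi = (times[sel] - t0) / p
        w = (1.0 - np.cos(2.0 * np.pi * phi)) / 2.0
        disp[sel] = b + a * w
        norm[sel] = w
    return MotionSignal(times_s=times, diaphragm_cm=disp,
                        true_normalized_amplitude=norm,
                        cycle_index=idx.astype(int), pattern=pattern)
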