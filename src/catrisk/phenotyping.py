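"""Cycle detection and six-parameter calcium-transient phenotyping.

The six per-well parameters:

* ``p80`` — mean peak width at 80% recovery (s)
* ``r82`` — mean per-cycle ratio of the 80%- to 20%-recovery widths
* ``cl``  — mean inter-peak interval (s)
* ``amp`` — mean peak height above the per-cycle baseline
* ``pn``  — number of detected cycles
* ``csd`` — sample standard deviation of inter-peak intervals (s)

Peaks are found on a moving-average-smoothed copy of the signal; widths
are measured on the raw signal by linear interpolation of level
crossings. Undefined parameters (e.g. on a ceased well) carry NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .registry import Trace

__all__ = [
    "DetectionConfig",
    "Cycle",
    "PhenotypeVector",
    "ChangeVector",
    "WidthResult",
    "PhenotypeError",
    "detect_cycles",
    "width_at_recovery",
    "phenotype",
    "percent_change",
    "PARAMETER_NAMES",
]

#: Canonical parameter order used by every table and radial axis.
PARAMETER_NAMES = ("p80", "r82", "cl", "amp", "pn", "csd")


class PhenotypeError(ValueError):
    """Raised when a phenotype operation's precondition is violated."""


@dataclass(frozen=True)
class DetectionConfig:
    """Peak-detection settings.

    ``prominence_frac`` scales with the smoothed signal's range, so
    detection is invariant to affine rescaling of the fluorescence;
    ``noise_mult`` adds a floor of that many high-frequency-noise sigmas
    so a flat (ceased) well yields zero cycles instead of noise peaks.
    """

    smoothing_window_s: float = 0.1
    prominence_frac: float = 0.3
    min_spacing_s: float = 0.25
    noise_mult: float = 6.0


@dataclass(frozen=True)
class WidthResult:
    """A measured recovery width plus whether it was truncated at a boundary."""

    width: float
    truncated: bool


@dataclass(frozen=True)
class Cycle:
    """One detected CaT cycle and its per-cycle measurements."""

    peak_index: int
    peak_time: float
    peak_value: float
    baseline_value: float
    start_index: int
    end_index: int
    width80: float
    width20: float
    width_truncated: bool
    cycle_length: float | None


def _smooth(values: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    n = max(int(round(window_s * fs)), 1)
    return uniform_filter1d(values.astype(float), size=n, mode="nearest")


def _crossings(
    values: np.ndarray,
    times: np.ndarray,
    peak: int,
    start: int,
    end: int,
    level: float,
) -> tuple[float | None, float | None]:
    """Locate the last upward crossing of ``level`` before ``peak`` and the
    first downward crossing after it, by linear interpolation. ``None``
    marks a missing crossing within the search window."""
    left_t: float | None = None
    for j in range(peak - 1, start - 1, -1):
        if values[j] <= level < values[j + 1] or (
            values[j] < level <= values[j + 1]
        ):
            frac = (level - values[j]) / (values[j + 1] - values[j])
            left_t = times[j] + frac * (times[j + 1] - times[j])
            break
    right_t: float | None = None
    for j in range(peak, end):
        if values[j] >= level > values[j + 1] or (
            values[j] > level >= values[j + 1]
        ):
            frac = (values[j] - level) / (values[j] - values[j + 1])
            right_t = times[j] + frac * (times[j + 1] - times[j])
            break
    return left_t, right_t


def width_at_recovery(
    trace: Trace, cycle: Cycle, recovery_frac: float
) -> WidthResult:
    """Width of one cycle's pulse at a fractional recovery level.

    The level is ``baseline + (1 - recovery_frac) * (peak - baseline)``;
    crossings are interpolated linearly between bracketing raw samples.
    If the decay never crosses the level before the next-cycle boundary,
    the width is truncated at that boundary and flagged.
    """
    if not 0.0 < recovery_frac < 1.0:
        raise PhenotypeError("recovery_frac must lie in (0, 1)")
    level = cycle.baseline_value + (1.0 - recovery_frac) * (
        cycle.peak_value - cycle.baseline_value
    )
    left_t, right_t = _crossings(
        trace.values, trace.times, cycle.peak_index,
        cycle.start_index, cycle.end_index, level,
    )
    truncated = False
    if left_t is None:
        left_t = float(trace.times[cycle.start_index])
        truncated = True
    if right_t is None:
        right_t = float(trace.times[cycle.end_index])
        truncated = True
    return WidthResult(width=float(right_t - left_t), truncated=truncated)


def detect_cycles(trace: Trace, cfg: DetectionConfig | None = None) -> list[Cycle]:
    """Detect CaT cycles in a trace.

    Peaks are found on the smoothed signal with prominence at least
    ``prominence_frac`` of its range (floored by the noise estimate) and
    spacing at least ``min_spacing_s``. The per-cycle baseline is the
    raw-signal minimum in the gap preceding the peak (first cycle: the
    minimum before its peak). A leading partial pulse whose rising edge
    is cut off by the record start is discarded. Returns an empty list
    for flat traces; never raises on degenerate input.
    """
    cfg = cfg or DetectionConfig()
    raw = trace.values
    fs = trace.sampling_rate
    smoothed = _smooth(raw, fs, cfg.smoothing_window_s)
    value_range = float(np.ptp(smoothed))
    if value_range <= 0:
        return []
    resid = raw - smoothed
    noise_sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    prominence = max(
        cfg.prominence_frac * value_range, cfg.noise_mult * noise_sigma
    )
    distance = max(int(round(cfg.min_spacing_s * fs)), 1)
    peaks, _ = find_peaks(smoothed, prominence=prominence, distance=distance)
    if peaks.size == 0:
        return []

    cycles: list[Cycle] = []
    n = len(raw)
    for k, p in enumerate(peaks):
        start = int(peaks[k - 1]) if k > 0 else 0
        end = int(peaks[k + 1]) if k + 1 < len(peaks) else n - 1
        gap = raw[start:p] if p > start else raw[p : p + 1]
        baseline = float(np.min(gap))
        peak_value = float(raw[p])
        if peak_value <= baseline:
            continue
        cycle_length = (
            float(trace.times[peaks[k + 1]] - trace.times[p])
            if k + 1 < len(peaks)
            else None
        )
        stub = Cycle(
            peak_index=int(p),
            peak_time=float(trace.times[p]),
            peak_value=peak_value,
            baseline_value=baseline,
            start_index=start,
            end_index=end,
            width80=math.nan,
            width20=math.nan,
            width_truncated=False,
            cycle_length=cycle_length,
        )
        w80 = width_at_recovery(trace, stub, 0.8)
        w20 = width_at_recovery(trace, stub, 0.2)
        truncated = w80.truncated or w20.truncated
        if k == 0 and truncated and p < distance:
            # leading partial pulse cut off by the record start
            continue
        cycles.append(
            Cycle(
                peak_index=int(p),
                peak_time=float(trace.times[p]),
                peak_value=peak_value,
                baseline_value=baseline,
                start_index=start,
                end_index=end,
                width80=w80.width,
                width20=w20.width,
                width_truncated=truncated,
                cycle_length=cycle_length,
            )
        )
    return cycles


@dataclass(frozen=True)
class PhenotypeVector:
    """The six per-well parameters; NaN marks "undefined"."""

    p80: float
    r82: float
    cl: float
    amp: float
    pn: int
    csd: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p80, self.r82, self.cl, self.amp, float(self.pn), self.csd]
        )


_SENTINEL = PhenotypeVector(
    p80=math.nan, r82=math.nan, cl=math.nan, amp=math.nan, pn=0, csd=math.nan
)


def phenotype(trace: Trace, cfg: DetectionConfig | None = None) -> PhenotypeVector:
    """Compute the six-parameter phenotype of one trace.

    Cycles with truncated widths are excluded from the ``p80``/``r82``
    means but still counted in ``pn``. ``csd`` is the sample (n-1)
    standard deviation of inter-peak intervals, defined as 0 when fewer
    than 3 peaks are present.
    """
    cycles = detect_cycles(trace, cfg)
    pn = len(cycles)
    if pn == 0:
        return _SENTINEL
    valid = [c for c in cycles if not c.width_truncated and c.width20 > 0]
    if valid:
        p80 = float(np.mean([c.width80 for c in valid]))
        r82 = float(np.mean([c.width80 / c.width20 for c in valid]))
    else:
        p80 = math.nan
        r82 = math.nan
    amp = float(np.mean([c.peak_value - c.baseline_value for c in cycles]))
    intervals = np.array(
        [c.cycle_length for c in cycles if c.cycle_length is not None]
    )
    cl = float(np.mean(intervals)) if intervals.size else math.nan
    csd = float(np.std(intervals, ddof=1)) if pn >= 3 else 0.0
    return PhenotypeVector(p80=p80, r82=r82, cl=cl, amp=amp, pn=pn, csd=csd)


@dataclass(frozen=True)
class ChangeVector:
    """Percent change from pre- to post-dose, per parameter.

    On a ceased well (``post.pn == 0``) the continuous parameters carry
    NaN and ``ceased`` is set; the ``pn`` change is still defined.
    """

    p80: float
    r82: float
    cl: float
    amp: float
    pn: float
    csd: float
    ceased: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.p80, self.r82, self.cl, self.amp, self.pn, self.csd])


def _pct(post: float, pre: float) -> float:
    if post == pre:
        return 0.0
    if not np.isfinite(post) or not np.isfinite(pre) or pre == 0:
        return math.nan
    return 100.0 * (post - pre) / pre


def percent_change(post: PhenotypeVector, pre: PhenotypeVector) -> ChangeVector:
    """Percent change ``100*(post - pre)/pre`` for each parameter.

    Raises :class:`PhenotypeError` when the baseline itself has no
    detected cycles (uninterpretable well).
    """
    if pre.pn == 0:
        raise PhenotypeError("pre-dose trace has no cycles; well uninterpretable")
    ceased = post.pn == 0
    pn_change = _pct(float(post.pn), float(pre.pn))
    if ceased:
        return ChangeVector(
            p80=math.nan, r82=math.nan, cl=math.nan, amp=math.nan,
            pn=pn_change, csd=math.nan, ceased=True,
        )
    return ChangeVector(
        p80=_pct(post.p80, pre.p80),
        r82=_pct(post.r82, pre.r82),
        cl=_pct(post.cl, pre.cl),
        amp=_pct(post.amp, pre.amp),
        pn=pn_change,
        csd=_pct(post.csd, pre.csd),
        ceased=False,
    )
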