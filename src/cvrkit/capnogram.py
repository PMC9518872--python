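"""End-tidal CO2 (EtCO2) extraction from raw capnograms.

A capnogram oscillates once per breath between the inspired CO2 level
(trough) and the end-expiratory level (peak). The EtCO2 curve is the upper
envelope of those oscillations and approximates arterial CO2, which is the
physiological driver of the BOLD response during a gas challenge.

The extraction chain: smooth (100 ms window) and resample the recording to
10 Hz; detect breath peaks with two independent algorithms (a scale-space
local-maximum persistence score, and a smooth-cross segmentation against a
10 s moving average); median-filter each peak-value sequence over 5 breaths
to suppress partial breaths; interpolate each to a uniform 1 Hz series; and
take the pointwise maximum of the two series as the EtCO2 curve. Summary
statistics (mean, bottom-25% baseline) feed the CVR formula downstream, and
an unusually low baseline (< 25 mmHg) raises a "CO2 switching" warning,
the pattern where exhaled CO2 transiently drops below the inhaled level so
the envelope's meaning inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .exceptions import CapnogramError
from .io_formats import Co2Trace

__all__ = [
    "PeakSet",
    "EtCo2Curve",
    "preprocess_trace",
    "scale_space_peaks",
    "smooth_cross_peaks",
    "regularize_peaks",
    "combine_envelopes",
    "extract_etco2",
    "check_co2_switching",
]

RESAMPLE_HZ = 10.0          # working rate for peak detection
SMOOTH_WINDOW_S = 0.1       # pre-smoothing moving-average window
SCALE_SPACE_ITERS = 30      # number of progressive smoothing scales
SCALE_SPACE_THRESHOLD = 15  # minimum persistence score (out of 30)
SMOOTH_CROSS_WINDOW_S = 10.0
MEDIAN_WINDOW = 5           # breaths, for partial-breath suppression
SWITCHING_BASELINE_MMHG = 25.0


@dataclass
class PeakSet:
    """Breath-peak times (s) and values (mmHg) from one detector."""

    times: np.ndarray
    values: np.ndarray
    source: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise CapnogramError("peak times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise CapnogramError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class EtCo2Curve:
    """1 Hz EtCO2 envelope with the summary statistics used by the CVR model.

    ``baseline_etco2`` is the average of the lowest 25% of curve values
    (ceil(0.25*N) smallest), a robust stand-in for the room-air level that a
    single deep breath cannot drag down the way a minimum would.
    """

    t: np.ndarray
    v: np.ndarray
    mean_etco2: float = field(init=False)
    baseline_etco2: float = field(init=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size or self.t.size < 2:
            raise CapnogramError("EtCO2 curve needs >= 2 samples with matching grids")
        if not np.allclose(np.diff(self.t), 1.0):
            raise CapnogramError("EtCO2 curve must be sampled at uniform 1 s spacing")
        self.mean_etco2 = float(np.mean(self.v))
        k = int(np.ceil(0.25 * self.v.size))
        self.baseline_etco2 = float(np.mean(np.sort(self.v)[:k]))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def _local_maxima(v: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus report their earliest sample.

    A sample n is a peak when v[n] = max(v[n-1], v[n], v[n+1]) with strictly
    lower neighbours on both sides of its (possibly flat) plateau. The first
    and last samples are never peaks.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    if n < 3:
        return np.array([], dtype=int)
    # run-length encode equal-value plateaus
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))  # inclusive
    keep = []
    for s, e in zip(starts, ends):
        if s == 0 or e == n - 1:
            continue
        if v[s - 1] < v[s] and v[e + 1] < v[s]:
            keep.append(s)
    return np.asarray(keep, dtype=int)


def preprocess_trace(trace: Co2Trace) -> Co2Trace:
    """Smooth with a 100 ms moving average and resample to a uniform 10 Hz grid.

    The grid spans the recording, shifted so it starts at t = 0.
    """
    if trace.duration < 10.0:
        raise CapnogramError(f"trace too short ({trace.duration:.1f} s < 10 s)")
    k = max(1, int(round(SMOOTH_WINDOW_S * trace.fs_native)))
    smoothed = uniform_filter1d(trace.p, size=k, mode="nearest")
    t0 = trace.t[0]
    n_out = int(np.floor(trace.duration * RESAMPLE_HZ)) + 1
    t_grid = np.arange(n_out) / RESAMPLE_HZ
    p_grid = np.interp(t_grid, trace.t - t0, smoothed)
    return Co2Trace(t=t_grid, p=p_grid, fs_native=RESAMPLE_HZ)


def _require_10hz(trace: Co2Trace) -> None:
    if not np.isclose(trace.fs_native, RESAMPLE_HZ) or not np.allclose(
        np.diff(trace.t), 1.0 / RESAMPLE_HZ
    ):
        raise CapnogramError("peak detection requires a uniform 10 Hz trace "
                             "(run preprocess_trace first)")


def scale_space_peaks(
    trace: Co2Trace,
    n_iters: int = SCALE_SPACE_ITERS,
    threshold: int = SCALE_SPACE_THRESHOLD,
) -> PeakSet:
    """Scale-space peak detection by local-maximum persistence.

    Local maxima of the trace are candidates. The trace is then smoothed at
    30 progressively wider scales (centered moving average of width 2k+1 at
    iteration k); after each smoothing pass the maxima are re-detected and
    each one credits the nearest candidate within k+2 samples, accumulating
    a per-candidate persistence score. Candidates scoring at least
    ``threshold`` survive; times and values are read from the original
    (unsmoothed) trace. Breath peaks persist across scales while noise
    spikes die after the first few, which is what the score separates.
    """
    _require_10hz(trace)
    v = trace.p
    candidates = _local_maxima(v)
    if candidates.size == 0:
        return PeakSet(times=np.array([]), values=np.array([]), source="scale_space")
    score = np.zeros(candidates.size, dtype=int)
    for k in range(1, n_iters + 1):
        vs = uniform_filter1d(v, size=2 * k + 1, mode="nearest")
        for m in _local_maxima(vs):
            j = int(np.searchsorted(candidates, m))
            best, dist = -1, k + 3
            for jj in (j - 1, j):
                if 0 <= jj < candidates.size:
                    d = abs(int(candidates[jj]) - m)
                    if d < dist:  # strict: ties keep the earlier candidate
                        best, dist = jj, d
            if best >= 0 and dist <= k + 2:
                score[best] += 1
    keep = candidates[score >= threshold]
    return PeakSet(times=trace.t[keep], values=v[keep], source="scale_space")


def smooth_cross_peaks(trace: Co2Trace, window_s: float = SMOOTH_CROSS_WINDOW_S) -> PeakSet:
    """Smooth-cross peak detection.

    A 10 s moving average of the trace crosses the raw trace roughly twice
    per breath; each maximal run where the raw trace exceeds its moving
    average is one breath segment, and the segment's maximum is its peak.
    """
    _require_10hz(trace)
    if trace.duration <= window_s:
        raise CapnogramError(f"smooth-cross needs a trace longer than {window_s:.0f} s")
    v = trace.p
    size = int(round(window_s * RESAMPLE_HZ)) | 1  # odd, centered
    ma = uniform_filter1d(v, size=size, mode="nearest")
    above = v > ma
    # boundaries of runs of True
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [above.size]))
    idx = []
    for s, e in zip(starts, ends):
        idx.append(s + int(np.argmax(v[s:e])))
    idx = np.asarray(sorted(idx), dtype=int)
    return PeakSet(times=trace.t[idx], values=v[idx], source="smooth_cross")


def _median_filter_clipped(values: np.ndarray, window: int = MEDIAN_WINDOW) -> np.ndarray:
    """Running median with symmetrically shrunken windows at the ends.

    The window radius at position i is min(window//2, i, n-1-i), so the
    window stays centered; a centered median leaves monotone stretches
    untouched while still replacing isolated outliers.
    """
    values = np.asarray(values, dtype=float)
    half = window // 2
    n = values.size
    out = np.empty_like(values)
    for i in range(n):
        r = min(half, i, n - 1 - i)
        out[i] = np.median(values[i - r:i + r + 1])
    return out


def regularize_peaks(peaks: PeakSet, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Median-filter peak values (window 5) and interpolate to a 1 Hz grid.

    The filter replaces outlying values (partial breaths) but keeps the
    breath-time grid; interpolation is linear between breaths, held constant
    before the first and after the last peak. Returns ``(t_grid, values)``
    on integer seconds [0, t_end].
    """
    if len(peaks) == 0:
        raise CapnogramError(f"no peaks to regularize ({peaks.source})")
    filtered = _median_filter_clipped(peaks.values)
    t_grid = np.arange(int(np.floor(t_end)) + 1, dtype=float)
    v_grid = np.interp(t_grid, peaks.times, filtered)
    return t_grid, v_grid


def combine_envelopes(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> EtCo2Curve:
    """Pointwise maximum of two 1 Hz envelope series on identical grids.

    Each detector underestimates the envelope in different places; taking
    the higher value recovers the true upper envelope of the trace.
    """
    ta, va = a
    tb, vb = b
    if ta.size != tb.size or not np.allclose(ta, tb):
        raise CapnogramError("cannot combine envelopes on different time grids")
    return EtCo2Curve(t=ta, v=np.maximum(va, vb))


def check_co2_switching(curve: EtCo2Curve) -> tuple[bool, str]:
    """Warn when the baseline EtCO2 suggests possible CO2 switching.

    Fires iff baseline < 25 mmHg (strict). Detection only — the curve is
    never auto-corrected; a human must inspect the raw trace.
    """
    if curve.baseline_etco2 < SWITCHING_BASELINE_MMHG:
        return True, (
            f"baseline EtCO2 {curve.baseline_etco2:.1f} mmHg is below "
            f"{SWITCHING_BASELINE_MMHG:.0f} mmHg: possible CO2 switching; "
            "inspect the raw CO2 trace"
        )
    return False, ""


MIN_PEAKS = 3


def extract_etco2(
    trace: Co2Trace,
    scale_space_threshold: int = SCALE_SPACE_THRESHOLD,
) -> tuple[EtCo2Curve, dict]:
    """Full EtCO2 extraction chain; returns the curve and a QC record.

    QC fields: per-detector peak counts, the fraction of grid points where
    the two 1 Hz series disagree by more than 2 mmHg, which detectors were
    usable, and the CO2-switching flag. If only one detector yields at
    least 3 peaks the curve falls back to that detector alone; if neither
    does the capnogram is unusable.
    """
    if trace.duration < 30.0:
        raise CapnogramError(f"capnogram too short ({trace.duration:.1f} s < 30 s)")
    pre = preprocess_trace(trace)
    t_end = pre.t[-1]
    ss = scale_space_peaks(pre, threshold=scale_space_threshold)
    sc = smooth_cross_peaks(pre)
    qc: dict = {
        "n_peaks_scale_space": len(ss),
        "n_peaks_smooth_cross": len(sc),
    }
    usable = [p for p in (ss, sc) if len(p) >= MIN_PEAKS]
    if not usable:
        raise CapnogramError(
            "unusable capnogram: fewer than 3 peaks from both detectors "
            f"(scale-space {len(ss)}, smooth-cross {len(sc)})"
        )
    series = [regularize_peaks(p, t_end) for p in usable]
    if len(series) == 2:
        curve = combine_envelopes(series[0], series[1])
        disagree = np.mean(np.abs(series[0][1] - series[1][1]) > 2.0)
        qc["disagreement_fraction"] = float(disagree)
        qc["detectors_used"] = ["scale_space", "smooth_cross"]
    else:
        curve = EtCo2Curve(t=series[0][0], v=series[0][1])
        qc["disagreement_fraction"] = float("nan")
        qc["detectors_used"] = [usable[0].source]
    flag, message = check_co2_switching(curve)
    qc["co2_switching_flag"] = bool(flag)
    qc["co2_switching_message"] = message
    qc["mean_etco2_mmHg"] = curve.mean_etco2
    qc["baseline_etco2_mmHg"] = curve.baseline_etco2
    return curve, qc
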