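"""ECG-to-RR preprocessing for short-term HRV analysis.

Pipeline: Pan-Tompkins QRS detection -> RR intervals -> local-median artifact
correction -> nonoverlapping 1-minute segments over the first six hours ->
cubic-spline resampling of each minute's tachogram onto a uniform 2 Hz grid
(120 samples), the unit both the entropy and spectral stages consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "ECGRecord",
    "RRSeries",
    "MinuteSlice",
    "RRSegment",
    "DetectionError",
    "detect_r_peaks",
    "rr_from_peaks",
    "correct_rr_local_median",
    "segment_minutes",
    "resample_2hz",
    "rr_to_segments",
]

SEGMENT_SAMPLES = 120  # 1 minute at 2 Hz
RESAMPLE_HZ = 2.0


class DetectionError(RuntimeError):
    """QRS detection failed (flat, too short, or otherwise unusable signal)."""


@dataclass(frozen=True)
class ECGRecord:
    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class RRSeries:
    """Beat times (s, strictly increasing) and successive intervals (s).

    ``corrected[k]`` flags interval k as replaced by the artifact filter.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    corrected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        if iv.size != bt.size - 1:
            raise ValueError("intervals must have length len(beat_times) - 1")
        if np.any(iv <= 0):
            raise ValueError("all RR intervals must be positive")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        if self.corrected is None:
            object.__setattr__(self, "corrected", np.zeros(iv.size, dtype=bool))


@dataclass(frozen=True)
class MinuteSlice:
    """One minute's (interval end time, interval value) pairs, pre-resampling."""

    minute: int
    times: np.ndarray
    intervals: np.ndarray
    valid: bool


@dataclass(frozen=True)
class RRSegment:
    """A valid 1-min segment resampled to 2 Hz: exactly 120 samples."""

    minute: int
    samples: np.ndarray
    n_beats: int
    valid: bool


def detect_r_peaks(ecg: ECGRecord) -> np.ndarray:
    """Pan-Tompkins QRS detection returning R-peak sample indices.

    Stages: 5-15 Hz band-pass, derivative, squaring, 150 ms moving-window
    integration, then adaptive dual signal/noise thresholds with a 1.66*RR
    search-back for missed beats.  A 200 ms refractory period is enforced and
    each detection is refined to the local band-passed maximum.
    """
    x = np.asarray(ecg.samples, dtype=float)
    fs = ecg.fs
    if fs < 100:
        raise DetectionError(f"sampling rate {fs} Hz too low; need >= 100 Hz")
    if x.size / fs < 10:
        raise DetectionError("record shorter than 10 s")
    if np.ptp(x) == 0:
        raise DetectionError("flat signal: no QRS energy")

    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    peaks, _ = signal.find_peaks(mwi, distance=refractory)
    if peaks.size == 0:
        raise DetectionError("no candidate peaks in integrated signal")

    # adaptive thresholding over integrated-signal peaks
    spki = float(np.mean(mwi[peaks[: min(10, peaks.size)]]))
    npki = float(np.mean(mwi)) * 0.5
    qrs: list[int] = []
    rr_history: list[float] = []
    threshold = lambda: npki + 0.25 * (spki - npki)

    for idx, pk in enumerate(peaks):
        level = mwi[pk]
        if level > threshold():
            qrs.append(int(pk))
            spki = 0.125 * level + 0.875 * spki
            if len(qrs) >= 2:
                rr_history.append(qrs[-1] - qrs[-2])
                rr_history = rr_history[-8:]
        else:
            npki = 0.125 * level + 0.875 * npki
            # search-back: if the gap since the last QRS exceeds 1.66x the
            # running RR average, accept the candidate at half threshold
            if qrs and rr_history:
                rr_avg = float(np.mean(rr_history))
                if (pk - qrs[-1]) > 1.66 * rr_avg and level > 0.5 * threshold():
                    qrs.append(int(pk))
                    spki = 0.25 * level + 0.75 * spki
                    rr_history.append(qrs[-1] - qrs[-2])
                    rr_history = rr_history[-8:]

    if len(qrs) < 2:
        raise DetectionError("fewer than 2 QRS complexes detected")

    # refine each detection to the band-passed local maximum (R peak proper)
    half = int(round(0.100 * fs))
    refined = []
    for pk in qrs:
        lo, hi = max(pk - half, 0), min(pk + half + 1, bp.size)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    # re-enforce refractory after refinement
    keep = [int(refined[0])]
    for p in refined[1:]:
        if p - keep[-1] >= refractory:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def rr_from_peaks(indices, fs: float) -> RRSeries:
    """Beat times and RR intervals (s) from R-peak sample indices."""
    idx = np.asarray(indices)
    if idx.size < 2:
        raise ValueError("need at least 2 peaks to form an RR interval")
    if np.any(np.diff(idx) <= 0):
        raise ValueError("peak indices must be strictly increasing")
    beat_times = idx / fs
    return RRSeries(beat_times=beat_times, intervals=np.diff(beat_times))


def correct_rr_local_median(
    rr: RRSeries, window: int = 5, tolerance: float = 0.2
) -> RRSeries:
    """Local-median artifact correction of RR intervals.

    Any interval deviating from the median of its centered ``window``-beat
    neighborhood by more than ``tolerance`` * median is replaced by that
    median and flagged; beat times are rebuilt by cumulative sum from the
    first beat.  No-op on series shorter than the window.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    iv = rr.intervals.copy()
    if iv.size < window:
        return RRSeries(rr.beat_times.copy(), iv, np.zeros(iv.size, dtype=bool))
    med = signal.medfilt(iv, kernel_size=window)
    half = window // 2
    # medfilt zero-pads the edges; recompute edge medians on the true neighborhoods
    for k in range(half):
        med[k] = np.median(iv[: k + half + 1])
        med[-(k + 1)] = np.median(iv[-(k + half + 1) :])
    flags = np.abs(iv - med) > tolerance * med
    iv[flags] = med[flags]
    beat_times = rr.beat_times[0] + np.concatenate([[0.0], np.cumsum(iv)])
    return RRSeries(beat_times=beat_times, intervals=iv, corrected=flags)


def segment_minutes(
    rr: RRSeries, hours: float = 6.0, min_beats: int = 30
) -> list[MinuteSlice]:
    """Split an RR series into nonoverlapping 1-min tachogram slices.

    Interval k is stamped with its end-beat time; minute ``k`` owns stamps in
    the half-open window [60k, 60(k+1)).  Slices with fewer than
    ``min_beats`` intervals are marked invalid (likely detector failure —
    physiologic minutes carry 60-100 beats).  Records shorter than the
    requested span yield fewer slices with a logged warning.
    """
    n_minutes = int(round(hours * 60))
    t = rr.beat_times[1:]  # end time of each interval
    iv = rr.intervals
    last = t[-1] if t.size else 0.0
    avail = int(np.ceil(last / 60.0))
    if avail < n_minutes:
        logger.warning(
            "record covers %.1f min < requested %d min; yielding %d segments",
            last / 60.0,
            n_minutes,
            min(avail, n_minutes),
        )
        n_minutes = min(avail, n_minutes)
    out = []
    for k in range(n_minutes):
        sel = (t >= 60.0 * k) & (t < 60.0 * (k + 1))
        out.append(
            MinuteSlice(
                minute=k,
                times=t[sel],
                intervals=iv[sel],
                valid=int(sel.sum()) >= min_beats,
            )
        )
    return out


def resample_2hz(sl: MinuteSlice) -> RRSegment:
    """Cubic-spline resample of a minute's tachogram onto the 2 Hz grid.

    The spline interpolates interval value vs. interval end time and is
    evaluated at 60k + {0, 0.5, ..., 59.5} s; outside the first/last beat the
    edge value is held constant.  Invalid slices propagate as invalid
    segments with no samples.
    """
    if not sl.valid:
        return RRSegment(minute=sl.minute, samples=np.empty(0), n_beats=sl.times.size, valid=False)
    grid = 60.0 * sl.minute + np.arange(SEGMENT_SAMPLES) / RESAMPLE_HZ
    t, v = sl.times, sl.intervals
    # spline needs strictly increasing abscissae; duplicates cannot occur for
    # positive intervals, but guard against numerically equal stamps
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, v = t[keep], v[keep]
    cs = CubicSpline(t, v, extrapolate=False)
    y = cs(grid)
    y[grid <= t[0]] = v[0]
    y[grid >= t[-1]] = v[-1]
    return RRSegment(minute=sl.minute, samples=y, n_beats=sl.times.size, valid=True)


def rr_to_segments(
    rr: RRSeries, hours: float = 6.0, min_beats: int = 30
) -> list[RRSegment]:
    """Convenience: segment an RR series and resample every minute."""
    return [resample_2hz(sl) for sl in segment_minutes(rr, hours=hours, min_beats=min_beats)]
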