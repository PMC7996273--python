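"""Frequency-domain HRV indices from 1-min segments via Burg AR spectra.

Sixty-second tachogram segments (120 samples at 2 Hz) are too short for
stable nonparametric spectra, so the power spectral density is estimated
parametrically: an order-6 autoregressive model fitted by Burg's
reflection-coefficient recursion, with the PSD evaluated from the AR
transfer function on a dense grid over [0, 1] Hz (the Nyquist band).

LF is the 0.04-0.15 Hz band power, HF the 0.15-0.4 Hz band power, and LF/HF
their ratio — the classic sympathovagal-balance proxy.  Band powers carry
the squared units of the input (s^2 for RR in seconds); the ratio is
unitless, so the PSD normalization cancels where it matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from statsmodels.regression.linear_model import burg as _burg_fit

from .preprocess import RRSegment

__all__ = [
    "SpectralEstimate",
    "FrequencyIndices",
    "burg_psd",
    "band_power",
    "frequency_indices",
    "LF_BAND",
    "HF_BAND",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class SpectralEstimate:
    frequencies: np.ndarray
    psd: np.ndarray


@dataclass(frozen=True)
class FrequencyIndices:
    lf: float
    hf: float

    @property
    def lf_hf(self) -> float:
        """LF/HF ratio; NaN when HF power is zero."""
        return self.lf / self.hf if self.hf > 0 else float("nan")


def _segment_values(segment) -> np.ndarray:
    if isinstance(segment, RRSegment):
        if not segment.valid:
            raise ValueError("cannot estimate a spectrum from an invalid segment")
        return np.asarray(segment.samples, dtype=float)
    return np.asarray(segment, dtype=float)


def burg_psd(
    segment, order: int = 6, n_freq: int = 1024, fs: float = 2.0, detrend: str = "mean"
) -> SpectralEstimate:
    """AR-Burg power spectral density of a uniform segment.

    The mean (or a linear trend with ``detrend='linear'``) is removed before
    fitting; the AR(order) coefficients come from Burg's recursion and the
    PSD is sigma^2 / (fs * |A(f)|^2) on a uniform ``n_freq``-point grid over
    [0, fs/2].
    """
    x = _segment_values(segment)
    if order >= x.size:
        raise ValueError(f"AR order {order} must be < segment length {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance segment: spectrum degenerate")
    if detrend == "linear":
        x = signal.detrend(x, type="linear")
    else:
        x = x - x.mean()
    ar, sigma2 = _burg_fit(x, order=order)
    # AR model x_t = sum_k ar[k] x_{t-k} + e_t  ->  A(z) = 1 - sum ar[k] z^-k
    a = np.concatenate([[1.0], -ar])
    freqs, h = signal.freqz(1.0, a, worN=n_freq, fs=fs)
    psd = float(sigma2) * np.abs(h) ** 2 / fs
    return SpectralEstimate(frequencies=freqs, psd=psd)


def band_power(est: SpectralEstimate, f_lo: float, f_hi: float) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi]."""
    if not 0 <= f_lo < f_hi:
        raise ValueError(f"need 0 <= f_lo < f_hi, got [{f_lo}, {f_hi}]")
    if f_hi > est.frequencies[-1] + 1e-12:
        raise ValueError(f"band edge {f_hi} Hz outside spectral grid")
    f, p = est.frequencies, est.psd
    sel = (f >= f_lo) & (f <= f_hi)
    # include the exact band edges by interpolation so narrow bands are exact
    fi = np.concatenate([[f_lo], f[sel], [f_hi]])
    pi = np.concatenate([[np.interp(f_lo, f, p)], p[sel], [np.interp(f_hi, f, p)]])
    fi, uniq = np.unique(fi, return_index=True)
    return float(np.trapezoid(pi[uniq], fi))


def frequency_indices(
    segment, order: int = 6, n_freq: int = 1024, fs: float = 2.0
) -> FrequencyIndices:
    """LF and HF band powers (and their ratio) of one 1-min segment."""
    est = burg_psd(segment, order=order, n_freq=n_freq, fs=fs)
    return FrequencyIndices(
        lf=band_power(est, *LF_BAND),
        hf=band_power(est, *HF_BAND),
    )
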