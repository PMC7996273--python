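"""End-to-end per-minute feature extraction.

Given an RR series (from Pan-Tompkins detection or read from CSV), produce
one row per minute with both entropies and the frequency-domain indices, the
table the screening layer aggregates per recording.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .entropy import npsampen, sampen
from .preprocess import (
    ECGRecord,
    RRSeries,
    correct_rr_local_median,
    detect_r_peaks,
    resample_2hz,
    rr_from_peaks,
    segment_minutes,
)
from .spectral import frequency_indices

__all__ = ["ecg_to_rr", "minute_features", "aggregate_features"]

FEATURE_COLS = ["sampen", "npsampen", "lf", "hf", "lf_hf"]


def ecg_to_rr(ecg: ECGRecord, window: int = 5, tolerance: float = 0.2) -> RRSeries:
    """Detect R peaks and return the artifact-corrected RR series."""
    peaks = detect_r_peaks(ecg)
    return correct_rr_local_median(rr_from_peaks(peaks, ecg.fs), window=window, tolerance=tolerance)


def minute_features(
    rr: RRSeries,
    record_id: str = "",
    hours: float = 6.0,
    m: int = 2,
    r: float = 0.2,
    min_beats: int = 30,
    entropy_on_raw: bool = False,
    compute_sampen: bool = True,
    compute_spectral: bool = True,
) -> pd.DataFrame:
    """Per-minute feature table: SampEn, NPSampEn, LF, HF, LF/HF.

    By default the entropies are computed on the same 120-sample 2 Hz
    resampled segment the spectral indices use; ``entropy_on_raw=True``
    switches them to the minute's raw beat intervals instead.  Invalid
    minutes (too few beats) get NaN features and ``valid=False``.
    """
    rows = []
    for sl in segment_minutes(rr, hours=hours, min_beats=min_beats):
        row = {"record_id": record_id, "minute": sl.minute, "valid": sl.valid}
        row.update({c: np.nan for c in FEATURE_COLS})
        if sl.valid:
            seg = resample_2hz(sl)
            ex = sl.intervals if entropy_on_raw else seg.samples
            if np.ptp(ex) > 0:
                row["npsampen"] = npsampen(ex, m=m).value
                if compute_sampen:
                    row["sampen"] = sampen(ex, m=m, r=r).value
            else:
                row["npsampen"] = 0.0
                row["sampen"] = 0.0
            if compute_spectral:
                try:
                    fi = frequency_indices(seg)
                    row["lf"], row["hf"], row["lf_hf"] = fi.lf, fi.hf, fi.lf_hf
                except ValueError:
                    row["valid"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_features(per_minute: pd.DataFrame) -> pd.DataFrame:
    """One row per recording: mean of each feature over its valid minutes."""
    from .screening import aggregate_recording

    out = []
    for rid, grp in per_minute.groupby("record_id", sort=False):
        agg = aggregate_recording(grp, feature_cols=FEATURE_COLS)
        agg["record_id"] = rid
        out.append(agg)
    return pd.DataFrame(out).reset_index(drop=True)
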