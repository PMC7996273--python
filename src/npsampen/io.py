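"""Plain-text readers and writers for ECG samples, RR series, AHI labels
and per-minute feature tables.

All floats are written with repr-level precision ("%.17g") so files
round-trip bit-exactly through numpy.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ECGRecord, RRSeries

__all__ = [
    "read_ecg_csv",
    "read_rr_csv",
    "write_rr_csv",
    "read_ahi_csv",
    "write_ahi_csv",
    "read_features_csv",
    "write_features_csv",
    "read_wfdb_record",
]

_FLOAT_FMT = "%.17g"


def read_ecg_csv(path, fs: float, record_id: str | None = None) -> ECGRecord:
    """Plain sampled-signal CSV: one sample per line, sampling rate supplied."""
    samples = np.loadtxt(path, dtype=float, ndmin=1)
    return ECGRecord(samples=samples, fs=fs, record_id=record_id or Path(path).stem)


def write_rr_csv(rr: RRSeries, path) -> None:
    """RR CSV with header ``time_s,interval_s,flag``; one row per interval.

    ``time_s`` is the interval's end-beat time.  The first beat time is
    recoverable as ``time_s[0] - interval_s[0]``.
    """
    df = pd.DataFrame(
        {
            "time_s": rr.beat_times[1:],
            "interval_s": rr.intervals,
            "flag": rr.corrected.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_rr_csv(path) -> RRSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    t_end = df["time_s"].to_numpy(dtype=float)
    iv = df["interval_s"].to_numpy(dtype=float)
    beat_times = np.concatenate([[t_end[0] - iv[0]], t_end])
    flags = df["flag"].to_numpy(dtype=bool) if "flag" in df else None
    return RRSeries(beat_times=beat_times, intervals=iv, corrected=flags)


def write_ahi_csv(labels: dict[str, float], path) -> None:
    pd.DataFrame(
        {"record_id": list(labels), "ahi": list(labels.values())}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_ahi_csv(path) -> dict[str, float]:
    df = pd.read_csv(path, float_precision="round_trip")
    return dict(zip(df["record_id"].astype(str), df["ahi"].astype(float)))


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_wfdb_record(record_path, channel: int = 0) -> ECGRecord:
    """Load a PhysioNet waveform-database record (requires the ``wfdb`` extra)."""
    try:
        import wfdb  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading waveform-database records requires the optional 'wfdb' "
            "package (pip install npsampen[wfdb]); plain CSV input needs no extras"
        ) from exc
    rec = wfdb.rdrecord(str(record_path))
    return ECGRecord(
        samples=np.asarray(rec.p_signal[:, channel], dtype=float),
        fs=float(rec.fs),
        record_id=rec.record_name,
    )
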