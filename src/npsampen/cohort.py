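"""Seeded synthetic ECG and RR cohorts for end-to-end testing.

Real overnight recordings cannot ship with the package, so this module
generates RR dynamics with the contrast the screening layer relies on:

* normal sleep — a respiratory sinus-arrhythmia oscillation (~0.25 Hz in
  beat time), a weaker low-frequency component, and comparatively strong
  broadband beat-to-beat noise (complex, high-entropy tachogram);
* obstructive sleep apnea — a slow cyclic bradycardia-tachycardia swing
  (period 40-60 s) whose amplitude and prevalence grow with severity, with
  damped respiratory modulation and reduced broadband noise (regular,
  low-entropy, sympathetically shifted tachogram).

This is a sum-of-sinusoids test fixture, not a physiological model; it
reproduces the direction of the real-data effects (entropy falls and LF/HF
rises with severity), which is what the pipeline tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ECGRecord, RRSeries
from .screening import GroupLabel, assign_group

__all__ = ["GroupParams", "CohortSpec", "CohortRecord", "synth_ecg", "synth_rr", "generate_cohort"]


@dataclass(frozen=True)
class GroupParams:
    """Per-severity-group RR dynamics parameters (all amplitudes in seconds)."""

    resp_amp: float
    lf_amp: float
    noise_sd: float
    cycle_amp: float
    ahi_range: tuple[float, float]


# Frozen default study conditions: amplitudes chosen so the synthetic contrast
# mirrors the real-data direction (entropy N > MOSA > SOSA, LF/HF increasing)
# with physiologically plausible magnitudes (RR noise a few tens of ms,
# respiratory modulation ~2-4% of mean RR, apnea swings up to ~0.1 s).  The
# fraction of time the apnea cycle is active is tied to the recording's AHI
# (more events per hour -> more of the night spent cycling), which gives the
# mild-moderate group the within-group spread real cohorts show.
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "N": GroupParams(resp_amp=0.040, lf_amp=0.020, noise_sd=0.045,
                     cycle_amp=0.040, ahi_range=(0.5, 4.5)),
    "MOSA": GroupParams(resp_amp=0.025, lf_amp=0.025, noise_sd=0.020,
                        cycle_amp=0.085, ahi_range=(6.0, 28.0)),
    "SOSA": GroupParams(resp_amp=0.015, lf_amp=0.030, noise_sd=0.015,
                        cycle_amp=0.100, ahi_range=(32.0, 80.0)),
}


@dataclass(frozen=True)
class CohortSpec:
    n_normal: int = 20
    n_mosa: int = 14
    n_sosa: int = 26
    duration_h: float = 6.0
    mean_rr: float = 0.9
    subject_rr_sd: float = 0.06
    resp_freq: float = 0.25
    lf_freq: float = 0.10
    cycle_period_range: tuple[float, float] = (40.0, 60.0)
    epoch_s: float = 120.0
    # apnea-cycle prevalence = min(ahi * prevalence_per_ahi, prevalence_max)
    prevalence_per_ahi: float = 0.03
    prevalence_max: float = 0.95
    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    seed: int = 0

    def __post_init__(self):
        if min(self.n_normal, self.n_mosa, self.n_sosa) < 0:
            raise ValueError("group sizes must be >= 0")


@dataclass(frozen=True)
class CohortRecord:
    record_id: str
    rr: RRSeries
    label: GroupLabel


def synth_ecg(
    beat_times, fs: float = 100.0, noise_sd: float = 0.02, seed: int | None = None
) -> tuple[ECGRecord, np.ndarray]:
    """Synthetic single-lead ECG: a fixed QRS template at given beat times.

    Adds slow baseline wander and white noise; returns the record together
    with the ground-truth beat times so detector tests can score recovery.
    """
    bt = np.asarray(beat_times, dtype=float)
    if bt.size == 0:
        raise ValueError("beat_times must be non-empty")
    if bt.size > 1 and np.any(np.diff(bt) < 0.2):
        raise ValueError("beats closer than 200 ms: refractory violation")
    rng = np.random.default_rng(seed)
    n = int(np.ceil((bt[-1] + 0.5) * fs))
    x = np.zeros(n)

    # biphasic QRS template ~100 ms wide, R amplitude 1
    tt = np.arange(-0.05, 0.05 + 1e-12, 1.0 / fs)
    template = (
        np.exp(-(tt**2) / (2 * 0.008**2))
        - 0.25 * np.exp(-((tt + 0.025) ** 2) / (2 * 0.012**2))
        - 0.30 * np.exp(-((tt - 0.030) ** 2) / (2 * 0.014**2))
    )
    half = template.size // 2
    for t in bt:
        c = int(round(t * fs))
        lo, hi = c - half, c - half + template.size
        sl_lo, sl_hi = max(lo, 0), min(hi, n)
        x[sl_lo:sl_hi] += template[sl_lo - lo : template.size - (hi - sl_hi)]

    ts = np.arange(n) / fs
    x += 0.08 * np.sin(2 * np.pi * 0.3 * ts + rng.uniform(0, 2 * np.pi))
    x += rng.normal(0.0, noise_sd, size=n)
    return ECGRecord(samples=x, fs=fs, record_id="synth"), bt


def synth_rr(
    group: str,
    duration_s: float,
    spec: CohortSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RRSeries, float]:
    """One synthetic RR series for a severity group, plus its drawn AHI.

    Beats are generated iteratively: the interval ending at time t is the
    subject's mean RR plus respiratory and low-frequency sinusoids, an
    epoch-gated apnea cycle, and white noise.  Deterministic given the
    generator state.
    """
    spec = spec or CohortSpec()
    rng = rng or np.random.default_rng(spec.seed)
    gp: GroupParams = spec.groups[group]

    base = rng.normal(spec.mean_rr, spec.subject_rr_sd)
    period = rng.uniform(*spec.cycle_period_range)
    phi_r, phi_l, phi_c = rng.uniform(0, 2 * np.pi, size=3)
    ahi = float(rng.uniform(*gp.ahi_range))
    prevalence = min(ahi * spec.prevalence_per_ahi, spec.prevalence_max)
    n_epochs = int(np.ceil(duration_s / spec.epoch_s))
    active = rng.random(n_epochs) < prevalence

    two_pi = 2 * np.pi
    times = [0.0]
    t = 0.0
    # draw noise in blocks to avoid per-beat Generator calls
    noise = rng.normal(0.0, gp.noise_sd, size=max(int(duration_s / base * 1.5), 64))
    k = 0
    while t < duration_s:
        cyc = gp.cycle_amp * np.sin(two_pi * t / period + phi_c) if active[
            min(int(t // spec.epoch_s), n_epochs - 1)
        ] else 0.0
        if k >= noise.size:
            noise = np.concatenate([noise, rng.normal(0.0, gp.noise_sd, size=noise.size)])
        rr = (
            base
            + gp.resp_amp * np.sin(two_pi * spec.resp_freq * t + phi_r)
            + gp.lf_amp * np.sin(two_pi * spec.lf_freq * t + phi_l)
            + cyc
            + noise[k]
        )
        rr = max(rr, 0.3)  # physiological floor
        t += rr
        times.append(t)
        k += 1
    bt = np.asarray(times)
    return RRSeries(beat_times=bt, intervals=np.diff(bt)), ahi


def generate_cohort(spec: CohortSpec | None = None) -> list[CohortRecord]:
    """Deterministic cohort of labelled RR recordings (one RNG stream per spec)."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    duration_s = spec.duration_h * 3600.0
    records = []
    plan = [("N", spec.n_normal), ("MOSA", spec.n_mosa), ("SOSA", spec.n_sosa)]
    i = 0
    for group, count in plan:
        for _ in range(count):
            rr, ahi = synth_rr(group, duration_s, spec=spec, rng=rng)
            label = assign_group(ahi)
            assert label.group == group  # AHI draws respect group boundaries
            records.append(CohortRecord(record_id=f"x{i:03d}", rr=rr, label=label))
            i += 1
    return records
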