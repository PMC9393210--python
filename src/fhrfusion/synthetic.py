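"""Synthetic two-class 2 Hz FHR records with known ground truth.

Each record is assembled additively: a slowly drifting baseline near the
normal 110-160 bpm range, band-limited Gaussian variability with configured
power in the LF / MF / HF fetal heart-rate-variability bands, smooth
raised-cosine accelerations and decelerations drawn from Poisson event
counts, and zero-reading signal-loss gaps.  Every injected component is
logged, so downstream detectors and spectral estimators can be checked
against the construction.

The default class contrast makes the pathological class (label 1) a
reduced-variability, reduced-reactivity version of the healthy class:
variability band powers halved, acceleration rate quartered, deceleration
rate tripled — separable but overlapping, so a classifier is exercised
nontrivially.  Metadata (gestational week, maternal age) is drawn from the
same distribution for both classes to avoid metadata leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .preprocessing import FS_HZ, SAMPLES_PER_MINUTE, RawCTGRecord

__all__ = [
    "ClassParams",
    "SyntheticConfig",
    "InjectedEvent",
    "GroundTruth",
    "LabeledDataset",
    "generate_record",
    "generate_dataset",
]


@dataclass
class ClassParams:
    """Generator parameters for one class; rates are per 20 minutes."""

    baseline_mean_bpm: float = 140.0
    baseline_sd_bpm: float = 8.0  # across records
    drift_amp_bpm: float = 2.0
    drift_period_min: float = 12.0
    lf_power: float = 9.0  # bpm^2, 0.03-0.15 Hz
    mf_power: float = 2.0  # bpm^2, 0.15-0.5 Hz
    hf_power: float = 0.8  # bpm^2, 0.5-1.0 Hz
    accel_rate: float = 3.0
    accel_amp_mean_bpm: float = 18.0
    accel_amp_sd_bpm: float = 3.0
    accel_dur_mean_s: float = 40.0
    accel_dur_sd_s: float = 10.0
    decel_rate: float = 0.3
    decel_amp_mean_bpm: float = 30.0
    decel_amp_sd_bpm: float = 5.0
    decel_dur_mean_s: float = 90.0
    decel_dur_sd_s: float = 15.0
    gap_rate: float = 2.0
    gap_dur_mean_s: float = 6.0
    gap_dur_sd_s: float = 3.0


def _default_pathological() -> ClassParams:
    h = ClassParams()
    return replace(
        h,
        lf_power=h.lf_power * 0.5,
        mf_power=h.mf_power * 0.5,
        hf_power=h.hf_power * 0.5,
        accel_rate=h.accel_rate * 0.25,
        decel_rate=h.decel_rate * 3.0,
    )


@dataclass
class SyntheticConfig:
    """Two-class generator configuration."""

    healthy: ClassParams = field(default_factory=ClassParams)
    pathological: ClassParams = field(default_factory=_default_pathological)
    duration_min: float = 20.0
    gestational_week_range: tuple[float, float] = (32.0, 40.0)
    maternal_age_mean: float = 31.0
    maternal_age_sd: float = 5.0
    maternal_age_range: tuple[float, float] = (18.0, 45.0)

    @classmethod
    def zero_contrast(cls, **kwargs) -> "SyntheticConfig":
        """Both classes drawn from the healthy parameters (a null dataset)."""
        return cls(pathological=ClassParams(), **kwargs)

    def params_for(self, label: int) -> ClassParams:
        return self.pathological if label == 1 else self.healthy


@dataclass
class InjectedEvent:
    """One injected raised-cosine excursion, with its analytic geometry."""

    kind: str  # "accel" or "decel"
    start_sample: int
    duration_s: float  # full raised-cosine width
    amplitude_bpm: float  # peak deviation (positive for both kinds)

    def supra_threshold_duration_s(self, threshold_bpm: float) -> float:
        """Time the excursion exceeds ``threshold_bpm``.

        The bump is ``a/2 (1 - cos(2 pi t / T))``; it exceeds a threshold
        theta < a for a fraction ``1 - arccos(1 - 2 theta/a) / pi`` of its
        width T.
        """
        if threshold_bpm >= self.amplitude_bpm:
            return 0.0
        c = 1.0 - 2.0 * threshold_bpm / self.amplitude_bpm
        return self.duration_s * (1.0 - np.arccos(c) / np.pi)


@dataclass
class GroundTruth:
    """Everything injected into one record."""

    baseline: np.ndarray  # drifting baseline, bpm, per sample
    events: list[InjectedEvent]
    gap_spans: list[tuple[int, int]]  # half-open sample ranges
    band_powers: tuple[float, float, float]  # configured LF, MF, HF (bpm^2)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)


@dataclass
class LabeledDataset:
    records: list[RawCTGRecord]
    truths: list[GroundTruth]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def _band_noise(n: int, band: tuple[float, float], power: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise band-pass filtered to ``band`` and scaled to ``power`` (variance)."""
    if power <= 0:
        return np.zeros(n)
    lo, hi = band
    nyq = FS_HZ / 2.0
    hi = min(hi, 0.995 * nyq)
    sos = butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    white = rng.standard_normal(n + 400)
    x = sosfiltfilt(sos, white)[200:-200]
    sd = x.std()
    if sd == 0:
        return np.zeros(n)
    return x / sd * np.sqrt(power)


def _raised_cosine(n_samples: int) -> np.ndarray:
    t = np.arange(n_samples)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / max(n_samples - 1, 1)))


def _place_events(
    n: int,
    count: int,
    dur_mean_s: float,
    dur_sd_s: float,
    amp_mean: float,
    amp_sd: float,
    kind: str,
    rng: np.random.Generator,
    occupied: np.ndarray,
    min_amp: float = 5.0,
    min_dur_s: float = 10.0,
) -> list[InjectedEvent]:
    events: list[InjectedEvent] = []
    for _ in range(count):
        dur_s = max(min_dur_s, rng.normal(dur_mean_s, dur_sd_s))
        amp = max(min_amp, rng.normal(amp_mean, amp_sd))
        width = int(round(dur_s * FS_HZ))
        if width + 2 >= n:
            continue
        for _attempt in range(50):
            start = int(rng.integers(0, n - width))
            # keep events well apart so excursions never merge
            pad = 60
            lo, hi = max(0, start - pad), min(n, start + width + pad)
            if not occupied[lo:hi].any():
                occupied[start : start + width] = True
                events.append(InjectedEvent(kind, start, dur_s, amp))
                break
    return events


def generate_record(
    cfg: SyntheticConfig,
    class_label: int,
    seed: int,
    record_id: str | None = None,
) -> tuple[RawCTGRecord, GroundTruth]:
    """Generate one labeled 2 Hz FHR record with its ground truth."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    p = cfg.params_for(class_label)
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_min * SAMPLES_PER_MINUTE))

    level = rng.normal(p.baseline_mean_bpm, p.baseline_sd_bpm)
    t_min = np.arange(n) / SAMPLES_PER_MINUTE
    phase = rng.uniform(0, 2 * np.pi)
    baseline = level + p.drift_amp_bpm * np.sin(2 * np.pi * t_min / p.drift_period_min + phase)

    noise = (
        _band_noise(n, (0.03, 0.15), p.lf_power, rng)
        + _band_noise(n, (0.15, 0.5), p.mf_power, rng)
        + _band_noise(n, (0.5, 1.0), p.hf_power, rng)
    )

    scale = cfg.duration_min / 20.0
    occupied = np.zeros(n, dtype=bool)
    events = _place_events(
        n, rng.poisson(p.accel_rate * scale), p.accel_dur_mean_s, p.accel_dur_sd_s,
        p.accel_amp_mean_bpm, p.accel_amp_sd_bpm, "accel", rng, occupied,
    )
    events += _place_events(
        n, rng.poisson(p.decel_rate * scale), p.decel_dur_mean_s, p.decel_dur_sd_s,
        p.decel_amp_mean_bpm, p.decel_amp_sd_bpm, "decel", rng, occupied,
    )

    bumps = np.zeros(n)
    for ev in events:
        width = int(round(ev.duration_s * FS_HZ))
        shape = ev.amplitude_bpm * _raised_cosine(width)
        sign = 1.0 if ev.kind == "accel" else -1.0
        bumps[ev.start_sample : ev.start_sample + width] += sign * shape

    fhr = baseline + noise + bumps
    fhr = np.clip(fhr, 30.0, 230.0)

    gap_spans: list[tuple[int, int]] = []
    for _ in range(rng.poisson(p.gap_rate * scale)):
        dur_s = max(1.0, rng.normal(p.gap_dur_mean_s, p.gap_dur_sd_s))
        width = int(round(dur_s * FS_HZ))
        if width >= n:
            continue
        start = int(rng.integers(0, n - width))
        fhr[start : start + width] = 0.0
        gap_spans.append((start, start + width))

    gw = rng.uniform(*cfg.gestational_week_range)
    age = float(np.clip(rng.normal(cfg.maternal_age_mean, cfg.maternal_age_sd), *cfg.maternal_age_range))
    record = RawCTGRecord.from_fhr(
        fhr,
        label=class_label,
        gestational_week=round(gw, 1),
        maternal_age=round(age, 1),
        record_id=record_id or f"syn{seed}_c{class_label}",
    )
    truth = GroundTruth(
        baseline=baseline,
        events=events,
        gap_spans=gap_spans,
        band_powers=(p.lf_power, p.mf_power, p.hf_power),
    )
    return record, truth


def generate_dataset(
    cfg: SyntheticConfig,
    n_per_class: int,
    seed: int = 0,
) -> LabeledDataset:
    """Balanced dataset of ``n_per_class`` records per label."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    records, truths = [], []
    counter = 0
    for label in (0, 1):
        for i in range(n_per_class):
            rec, truth = generate_record(
                cfg, label, seed=(seed + 7919 * counter) % (2**31),
                record_id=f"syn{seed:03d}_{label}_{i:04d}",
            )
            records.append(rec)
            truths.append(truth)
            counter += 1
    return LabeledDataset(records=records, truths=truths)
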