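"""The 15-parameter computerized-CTG feature suite.

Per clean 20-minute segment this module computes the classical quantitative
regressors of computerized cardiotocography:

* time-domain variability indices (STV, DELTA, II, LTI) on the T24
  interbeat-interval representation,
* frequency-domain band powers LF / MF / HF of the interval signal plus the
  sympatho-vagal-style ratio LF/(MF+HF),
* approximate entropy (ApEn), a nonlinear regularity statistic,
* the mean heart-rate baseline (FHRB) from a trimmed iterative baseline
  estimator, with acceleration / deceleration event counts against it,
* two anamnestic covariates: gestational week and maternal age.

All 15 values are min-max normalized (statistics learned on the training
partition) before they are fed to the tabular branch of the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .preprocessing import FS_HZ, SAMPLES_PER_MINUTE, FHRSegment

#: Fetal heart-rate-variability band edges (Hz).
LF_BAND = (0.03, 0.15)
MF_BAND = (0.15, 0.5)
HF_BAND = (0.5, 1.0)

#: Feature columns in canonical order (the tabular branch's input order).
FEATURE_NAMES = [
    "DELTA",
    "II",
    "STV",
    "LTI",
    "LF",
    "MF",
    "HF",
    "ratio",
    "ApEn",
    "FHRB",
    "small_accels",
    "large_accels",
    "decels",
    "gestational_week",
    "maternal_age",
]

T24_PER_MINUTE = 24  # one interval value per 2.5 s

__all__ = [
    "LF_BAND",
    "MF_BAND",
    "HF_BAND",
    "FEATURE_NAMES",
    "T24Series",
    "SpectralPowers",
    "EventCounts",
    "FeatureVector",
    "to_t24",
    "time_domain_indices",
    "spectral_powers",
    "approximate_entropy",
    "baseline_mantel",
    "detect_events",
    "extract_features",
    "MinMaxNormalizer",
    "assemble_and_normalize",
]


@dataclass
class T24Series:
    """Interbeat intervals (ms), 24 values per minute: T = 60000 / FHR."""

    intervals: np.ndarray
    minutes: int

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if len(self.intervals) != T24_PER_MINUTE * self.minutes:
            raise ValueError("T24 length must equal 24 x minutes")
        if np.any(self.intervals <= 0):
            raise ValueError("interbeat intervals must be positive")


@dataclass
class SpectralPowers:
    LF: float  # ms^2, 0.03-0.15 Hz
    MF: float  # ms^2, 0.15-0.5 Hz
    HF: float  # ms^2, 0.5-1.0 Hz
    ratio: float  # LF/(MF+HF); NaN when MF+HF == 0


@dataclass
class EventCounts:
    small_accels: int
    large_accels: int
    decels: int


@dataclass
class FeatureVector:
    """The 15 raw regressors for one segment, in canonical order."""

    DELTA: float
    II: float
    STV: float
    LTI: float
    LF: float
    MF: float
    HF: float
    ratio: float
    ApEn: float
    FHRB: float
    small_accels: int
    large_accels: int
    decels: int
    gestational_week: float
    maternal_age: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def to_t24(segment: FHRSegment | np.ndarray) -> T24Series:
    """Resample a 2 Hz bpm segment to 24 interval values per minute.

    Each T24 value is 60000 / (mean bpm over a 2.5 s block of 5 samples).
    A 2400-sample segment yields exactly 480 values.
    """
    fhr = segment.fhr if isinstance(segment, FHRSegment) else np.asarray(segment, dtype=float)
    block = int(round(FS_HZ * 2.5))  # 5 samples
    n_blocks = len(fhr) // block
    if n_blocks * block != len(fhr):
        raise ValueError("segment length must be a multiple of the 2.5 s block (5 samples)")
    means = fhr[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("non-positive bpm block mean; run preprocessing first")
    return T24Series(60000.0 / means, minutes=n_blocks // T24_PER_MINUTE)


def time_domain_indices(t24: T24Series) -> dict[str, float]:
    """Classical minute-wise variability indices on the T24 series.

    Per minute j over its 24 interval values T(i):

    * ``STV(j)  = mean_i |T(i+1) - T(i)|``  (short-term variability, ms)
    * ``DELTA(j) = max_i T(i) - min_i T(i)``  (minute range, ms)
    * ``II(j)   = std_i |T(i+1) - T(i)| / STV(j)``  (interval index)

    each averaged over complete minutes.  The long-term irregularity LTI is
    the interquartile range of ``m(i) = sqrt(T(i)^2 + T(i+1)^2)`` computed
    over consecutive 3-minute windows and averaged.
    """
    if t24.minutes < 1:
        raise ValueError("need at least one complete minute")
    if t24.minutes < 3:
        raise ValueError("LTI needs at least 3 complete minutes")

    per_min = t24.intervals.reshape(t24.minutes, T24_PER_MINUTE)
    abs_diff = np.abs(np.diff(per_min, axis=1))  # 23 values per minute
    stv_j = abs_diff.mean(axis=1)
    delta_j = per_min.max(axis=1) - per_min.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ii_j = np.where(stv_j > 0, abs_diff.std(axis=1) / np.where(stv_j > 0, stv_j, 1.0), 0.0)

    win = 3 * T24_PER_MINUTE
    ltis = []
    for start in range(0, t24.minutes - 2, 3):
        x = t24.intervals[start * T24_PER_MINUTE : start * T24_PER_MINUTE + win]
        m = np.sqrt(x[:-1] ** 2 + x[1:] ** 2)
        q75, q25 = np.percentile(m, [75, 25])
        ltis.append(q75 - q25)

    return {
        "STV": float(stv_j.mean()),
        "DELTA": float(delta_j.mean()),
        "II": float(ii_j.mean()),
        "LTI": float(np.mean(ltis)),
    }


def spectral_powers(
    segment: FHRSegment | np.ndarray,
    nperseg: int = 240,
    noverlap: int | None = None,
) -> SpectralPowers:
    """Band powers of the 2 Hz interbeat-interval signal (ms).

    The bpm trace is converted sample-wise to intervals (60000/bpm), and a
    Welch PSD (2-minute Hann windows, 50% overlap, per-window linear
    detrend) is integrated over the LF, MF and HF bands.  The ratio is
    LF/(MF+HF), reported as NaN when the denominator vanishes.
    """
    fhr = segment.fhr if isinstance(segment, FHRSegment) else np.asarray(segment, dtype=float)
    if np.any(fhr <= 0):
        raise ValueError("bpm values must be positive")
    intervals = 60000.0 / fhr
    if noverlap is None:
        noverlap = nperseg // 2
    freqs, psd = welch(
        intervals, fs=FS_HZ, window="hann", nperseg=nperseg, noverlap=noverlap, detrend="linear"
    )

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        if not sel.any():
            return 0.0
        return float(np.trapezoid(psd[sel], freqs[sel]))

    lf = band_power(*LF_BAND)
    mf = band_power(*MF_BAND)
    hf = band_power(HF_BAND[0], HF_BAND[1] + 1e-12)  # include the Nyquist edge
    denom = mf + hf
    ratio = lf / denom if denom > 0 else float("nan")
    return SpectralPowers(LF=lf, MF=mf, HF=hf, ratio=ratio)


def approximate_entropy(series, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy (Pincus), self-matches included.

    ``ApEn = Phi_m(r) - Phi_{m+1}(r)`` where ``Phi_m(r)`` is the mean over
    templates of ``ln C_i^m(r)`` and ``C_i^m(r)`` is the fraction of
    length-m templates within Chebyshev distance r of template i.  With
    self-matches counted, every C is strictly positive, so the statistic is
    defined for any series.  Defaults: m = 2, r = 0.2 x SD of the series.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        # a constant series has zero SD; every template matches exactly
        if np.ptp(x) == 0:
            return 0.0
        raise ValueError("tolerance r must be positive")

    def phi(mm: int) -> float:
        n_t = n - mm + 1
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)  # (n_t, mm)
        # Chebyshev distances between all template pairs
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        c = (d <= r).mean(axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def baseline_mantel(
    segment: FHRSegment | np.ndarray,
    window_s: float = 120.0,
    exclusion_bpm: float = 10.0,
    hysteresis_bpm: float = 5.0,
    tol_bpm: float = 0.1,
    max_iter: int = 10,
) -> tuple[np.ndarray, float]:
    """Trimmed iterative baseline of an FHR segment.

    The baseline is the slowly-varying reference level around which
    accelerations and decelerations are judged.  Starting from a 2-minute
    moving average, samples deviating more than ``exclusion_bpm`` from the
    current estimate are excluded — together with the rest of their
    contiguous excursion run out to where the deviation falls back inside
    ``hysteresis_bpm`` — and the moving average is recomputed over the
    remaining samples, until the estimate changes by less than ``tol_bpm``
    everywhere or ``max_iter`` passes.  The run expansion keeps excursion
    shoulders from dragging the local mean toward the event.  Returns the
    per-sample baseline and its mean (FHRB, bpm).
    """
    fhr = segment.fhr if isinstance(segment, FHRSegment) else np.asarray(segment, dtype=float)
    win = int(round(window_s * FS_HZ))
    kernel = np.ones(win)

    def masked_moving_mean(mask: np.ndarray) -> np.ndarray:
        num = np.convolve(np.where(mask, fhr, 0.0), kernel, mode="same")
        den = np.convolve(mask.astype(float), kernel, mode="same")
        out = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
        if np.isnan(out).any():  # windows with every sample excluded
            valid = ~np.isnan(out)
            out = np.interp(np.arange(len(out)), np.flatnonzero(valid), out[valid])
        return out

    def excursion_exclusion(dev: np.ndarray) -> np.ndarray:
        """Exclude whole excursion runs seeded by deviations > exclusion_bpm."""
        core = np.abs(dev) > exclusion_bpm
        if not core.any():
            return np.ones(len(dev), dtype=bool)
        candidate = np.abs(dev) > hysteresis_bpm
        # label contiguous candidate runs; drop those containing a core sample
        run_id = np.cumsum(np.r_[candidate[0], np.diff(candidate.astype(np.int8)) == 1])
        excluded = candidate.copy()
        seeded = np.unique(run_id[core])
        excluded &= np.isin(run_id, seeded)
        return ~excluded

    include = np.ones(len(fhr), dtype=bool)
    baseline = masked_moving_mean(include)
    for _ in range(max_iter):
        include = excursion_exclusion(fhr - baseline)
        if not include.any():
            include = np.ones(len(fhr), dtype=bool)
        new = masked_moving_mean(include)
        if np.max(np.abs(new - baseline)) < tol_bpm:
            baseline = new
            break
        baseline = new
    return baseline, float(baseline.mean())


def _runs_above(condition: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, stop) index pairs."""
    if not condition.any():
        return []
    d = np.diff(condition.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if condition[0]:
        starts.insert(0, 0)
    if condition[-1]:
        stops.append(len(condition))
    return list(zip(starts, stops))


def detect_events(
    segment: FHRSegment | np.ndarray,
    baseline: np.ndarray,
    accel_amp: float = 10.0,
    accel_large_amp: float = 15.0,
    accel_dur_s: float = 15.0,
    decel_deep_amp: float = 20.0,
    decel_deep_dur_s: float = 30.0,
    decel_shallow_amp: float = 10.0,
    decel_shallow_dur_s: float = 60.0,
) -> EventCounts:
    """Count accelerations and decelerations against a baseline.

    An acceleration candidate is a maximal run with deviation > 10 bpm
    above baseline lasting at least 15 s; it is *large* when its peak
    deviation exceeds 15 bpm and *small* otherwise (the small criterion
    being > 10 and < 15 bpm).  A deceleration is a maximal run below
    baseline whose deviation stays beyond 20 bpm for at least 30 s, or
    beyond 10 bpm for at least 60 s.  Each event is counted once.
    """
    fhr = segment.fhr if isinstance(segment, FHRSegment) else np.asarray(segment, dtype=float)
    dev = fhr - np.asarray(baseline, dtype=float)
    min_accel = int(round(accel_dur_s * FS_HZ))

    small = large = 0
    for start, stop in _runs_above(dev > accel_amp):
        if stop - start >= min_accel:
            if dev[start:stop].max() > accel_large_amp:
                large += 1
            else:
                small += 1

    deep_n = int(round(decel_deep_dur_s * FS_HZ))
    shallow_n = int(round(decel_shallow_dur_s * FS_HZ))
    decels = 0
    for start, stop in _runs_above(dev < -decel_shallow_amp):
        qualifies = stop - start >= shallow_n
        if not qualifies:
            sub = dev[start:stop] < -decel_deep_amp
            qualifies = any(s2 - s1 >= deep_n for s1, s2 in _runs_above(sub))
        if qualifies:
            decels += 1
    return EventCounts(small_accels=small, large_accels=large, decels=decels)


def extract_features(
    segment: FHRSegment,
    apen_m: int = 2,
    apen_r_factor: float = 0.2,
) -> FeatureVector:
    """Compute all 15 regressors for one clean segment."""
    t24 = to_t24(segment)
    td = time_domain_indices(t24)
    sp = spectral_powers(segment)
    sd = float(np.std(t24.intervals))
    apen = approximate_entropy(t24.intervals, m=apen_m, r=apen_r_factor * sd) if sd > 0 else 0.0
    baseline, fhrb = baseline_mantel(segment)
    ev = detect_events(segment, baseline)
    return FeatureVector(
        DELTA=td["DELTA"],
        II=td["II"],
        STV=td["STV"],
        LTI=td["LTI"],
        LF=sp.LF,
        MF=sp.MF,
        HF=sp.HF,
        ratio=0.0 if np.isnan(sp.ratio) else sp.ratio,
        ApEn=apen,
        FHRB=fhrb,
        small_accels=ev.small_accels,
        large_accels=ev.large_accels,
        decels=ev.decels,
        gestational_week=segment.gestational_week if segment.gestational_week is not None else 0.0,
        maternal_age=segment.maternal_age if segment.maternal_age is not None else 0.0,
    )


class MinMaxNormalizer:
    """Column-wise min-max scaling to [0,1], fit on the training partition.

    Constant columns map to 0 (with a warning); values outside the training
    range are clipped to [0,1] so test rows never leak outside the unit box.
    """

    def __init__(self) -> None:
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    def fit(self, table: np.ndarray) -> "MinMaxNormalizer":
        table = np.asarray(table, dtype=float)
        if table.ndim != 2 or table.shape[0] < 2:
            raise ValueError("need a 2-D table with at least 2 rows")
        self.min_ = table.min(axis=0)
        self.max_ = table.max(axis=0)
        constant = self.max_ <= self.min_
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature column(s); mapped to 0"
            )
        return self

    def transform(self, table: np.ndarray) -> np.ndarray:
        if self.min_ is None or self.max_ is None:
            raise RuntimeError("normalizer not fitted")
        table = np.asarray(table, dtype=float)
        span = self.max_ - self.min_
        scaled = np.where(span > 0, (table - self.min_) / np.where(span > 0, span, 1.0), 0.0)
        return np.clip(scaled, 0.0, 1.0)

    def fit_transform(self, table: np.ndarray) -> np.ndarray:
        return self.fit(table).transform(table)


def assemble_and_normalize(
    vectors: list[FeatureVector],
    normalizer: MinMaxNormalizer | None = None,
) -> tuple[np.ndarray, MinMaxNormalizer]:
    """Stack feature vectors into a table and min-max normalize it.

    Pass a fitted ``normalizer`` (learned on the training rows) to scale
    held-out rows with the training statistics; otherwise a new one is fit
    on the given rows.
    """
    raw = np.vstack([v.to_array() for v in vectors])
    if normalizer is None:
        normalizer = MinMaxNormalizer().fit(raw)
    return normalizer.transform(raw), normalizer
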