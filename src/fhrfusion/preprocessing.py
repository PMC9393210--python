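"""Cleaning of raw 2 Hz fetal heart rate recordings.

Antepartum cardiotocographic (CTG) monitors emit the fetal heart rate (FHR)
at 2 Hz in beats per minute; transducer displacement and fetal/maternal
movement produce readings of 0 bpm or physiologically impossible values
("signal loss").  This module turns such gappy recordings into fixed-length
clean segments:

1. :func:`mark_signal_loss` flags samples outside a validity range,
2. :func:`repair_gaps` linearly interpolates invalid runs shorter than a
   cutoff (default 15 s) and splices out longer runs,
3. :func:`extract_segments` tiles the repaired trace into non-overlapping
   20-minute (2400-sample) segments, discarding segments with too many
   interpolated samples.

At the 2 Hz sampling convention one minute is 120 samples and 20 minutes
are 2400 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FS_HZ = 2.0
SAMPLES_PER_MINUTE = 120
SEGMENT_SAMPLES = 2400  # 20 minutes at 2 Hz

#: Physiological FHR validity range (bpm).  Readings of 0 bpm are transducer
#: dropouts and always fall outside it.
VALID_BPM_RANGE = (50.0, 220.0)

__all__ = [
    "FS_HZ",
    "SAMPLES_PER_MINUTE",
    "SEGMENT_SAMPLES",
    "VALID_BPM_RANGE",
    "RawCTGRecord",
    "FHRSegment",
    "mark_signal_loss",
    "repair_gaps",
    "extract_segments",
    "preprocess_record",
    "read_record_csv",
    "write_record_csv",
]


@dataclass
class RawCTGRecord:
    """A raw 2 Hz FHR trace in bpm with a validity mask and metadata."""

    fhr: np.ndarray
    valid_mask: np.ndarray
    label: int
    gestational_week: float
    maternal_age: float
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.fhr.shape != self.valid_mask.shape:
            raise ValueError("fhr and valid_mask must have equal length")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 (healthy) or 1 (pathological), got {self.label}")

    @property
    def duration_minutes(self) -> float:
        return len(self.fhr) / SAMPLES_PER_MINUTE

    @classmethod
    def from_fhr(
        cls,
        fhr,
        label: int,
        gestational_week: float,
        maternal_age: float,
        record_id: str = "record",
        valid_range: tuple[float, float] = VALID_BPM_RANGE,
    ) -> "RawCTGRecord":
        """Build a record, deriving the validity mask from ``valid_range``."""
        fhr = np.asarray(fhr, dtype=float)
        mask = mark_signal_loss(fhr, *valid_range)
        return cls(fhr, mask, label, gestational_week, maternal_age, record_id)


@dataclass
class FHRSegment:
    """Exactly 2400 clean samples (20 min at 2 Hz), ready for analysis."""

    fhr: np.ndarray
    interpolated_fraction: float
    record_id: str = "record"
    start_offset: int = 0
    label: int | None = None
    gestational_week: float | None = None
    maternal_age: float | None = None
    interpolated_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        if len(self.fhr) != SEGMENT_SAMPLES:
            raise ValueError(
                f"a segment must contain exactly {SEGMENT_SAMPLES} samples, got {len(self.fhr)}"
            )

    @property
    def segment_id(self) -> str:
        return f"{self.record_id}_{self.start_offset}"


def mark_signal_loss(fhr, lo: float = VALID_BPM_RANGE[0], hi: float = VALID_BPM_RANGE[1]) -> np.ndarray:
    """Return a boolean mask, True where a sample is physiologically valid.

    A sample is valid iff it is finite and ``lo <= value <= hi`` (closed
    interval).  Zero readings — the monitor's signal-loss sentinel — are
    therefore invalid for any sensible range.
    """
    fhr = np.asarray(fhr, dtype=float)
    if fhr.size == 0:
        raise ValueError("cannot mark signal loss on an empty trace")
    with np.errstate(invalid="ignore"):
        return np.isfinite(fhr) & (fhr >= lo) & (fhr <= hi)


def _invalid_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of invalid samples as half-open ``(start, stop)`` pairs."""
    invalid = ~mask
    if not invalid.any():
        return []
    diff = np.diff(invalid.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    stops = list(np.flatnonzero(diff == -1) + 1)
    if invalid[0]:
        starts.insert(0, 0)
    if invalid[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def repair_gaps(
    record: RawCTGRecord, max_interp_s: float = 15.0
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate short signal losses and splice out long ones.

    Invalid runs strictly shorter than ``max_interp_s`` (< 30 samples at
    2 Hz for the 15 s default) are replaced by linear interpolation between
    the flanking valid samples; runs of at least ``max_interp_s``, and any
    run touching the start or end of the record (no flanking sample to
    interpolate from), are removed entirely, shortening the trace.

    Returns
    -------
    repaired : ndarray
        The repaired bpm sequence (possibly shorter than the input).
    interp_mask : ndarray of bool
        True where a sample of ``repaired`` was filled by interpolation.
    """
    fhr = record.fhr
    mask = record.valid_mask
    if not mask.any():
        raise ValueError(f"record {record.record_id!r} has no valid samples")

    max_run = int(round(max_interp_s * FS_HZ))  # runs of this length or more are spliced
    out = fhr.copy()
    interp = np.zeros(len(fhr), dtype=bool)
    keep = np.ones(len(fhr), dtype=bool)

    for start, stop in _invalid_runs(mask):
        run_len = stop - start
        at_boundary = start == 0 or stop == len(fhr)
        if run_len >= max_run or at_boundary:
            keep[start:stop] = False
        else:
            left, right = fhr[start - 1], fhr[stop]
            # linear ramp strictly between the flanking valid samples
            t = np.arange(1, run_len + 1) / (run_len + 1)
            out[start:stop] = left + t * (right - left)
            interp[start:stop] = True

    return out[keep], interp[keep]


def extract_segments(
    record: RawCTGRecord,
    repaired: np.ndarray,
    interp_mask: np.ndarray,
    segment_len: int = SEGMENT_SAMPLES,
    quality_cap: float = 0.10,
) -> list[FHRSegment]:
    """Tile a repaired trace into non-overlapping fixed-length segments.

    Windows are taken consecutively from offset 0; the trailing remainder is
    discarded, as is any window whose interpolated fraction exceeds
    ``quality_cap`` (an "excessive corruption" rejection).  A trace shorter
    than one window yields an empty list.
    """
    repaired = np.asarray(repaired, dtype=float)
    interp_mask = np.asarray(interp_mask, dtype=bool)
    segments: list[FHRSegment] = []
    n_windows = len(repaired) // segment_len
    for w in range(n_windows):
        sl = slice(w * segment_len, (w + 1) * segment_len)
        frac = float(interp_mask[sl].mean())
        if frac > quality_cap:
            continue
        segments.append(
            FHRSegment(
                fhr=repaired[sl],
                interpolated_fraction=frac,
                record_id=record.record_id,
                start_offset=w * segment_len,
                label=record.label,
                gestational_week=record.gestational_week,
                maternal_age=record.maternal_age,
                interpolated_mask=interp_mask[sl].copy(),
            )
        )
    return segments


def preprocess_record(
    record: RawCTGRecord,
    max_interp_s: float = 15.0,
    quality_cap: float = 0.10,
    segment_len: int = SEGMENT_SAMPLES,
) -> list[FHRSegment]:
    """Full cleaning chain: gap repair followed by segmentation."""
    repaired, interp = repair_gaps(record, max_interp_s=max_interp_s)
    return extract_segments(record, repaired, interp, segment_len=segment_len, quality_cap=quality_cap)


# ---------------------------------------------------------------------------
# CSV dialect: `time_s,fhr_bpm` rows at 0.5 s spacing, with a key-value
# sidecar (`<stem>.meta`) holding record_id, label, gestational_week,
# maternal_age.  A reading of 0 or an empty cell means signal loss.
# ---------------------------------------------------------------------------

def write_record_csv(record: RawCTGRecord, path: str | Path) -> None:
    path = Path(path)
    fhr = np.where(record.valid_mask, record.fhr, 0.0)
    df = pd.DataFrame({"time_s": np.arange(len(fhr)) / FS_HZ, "fhr_bpm": fhr})
    df.to_csv(path, index=False, float_format="%.3f")
    meta = {
        "record_id": record.record_id,
        "label": record.label,
        "gestational_week": record.gestational_week,
        "maternal_age": record.maternal_age,
    }
    sidecar = path.with_suffix(".meta")
    sidecar.write_text("".join(f"{k}={v}\n" for k, v in meta.items()))


def read_record_csv(path: str | Path, valid_range: tuple[float, float] = VALID_BPM_RANGE) -> RawCTGRecord:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_s", "fhr_bpm"}.issubset(df.columns):
        raise ValueError(f"{path} is not a time_s,fhr_bpm record file")
    fhr = df["fhr_bpm"].to_numpy(dtype=float)
    fhr = np.nan_to_num(fhr, nan=0.0)  # empty cells are losses

    sidecar = path.with_suffix(".meta")
    meta: dict[str, str] = {}
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    else:
        warnings.warn(f"no metadata sidecar for {path}; using defaults")
    return RawCTGRecord.from_fhr(
        fhr,
        label=int(meta.get("label", 0)),
        gestational_week=float(meta.get("gestational_week", 38.0)),
        maternal_age=float(meta.get("maternal_age", 31.0)),
        record_id=meta.get("record_id", path.stem),
        valid_range=valid_range,
    )
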