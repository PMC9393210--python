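import numpy as np
import pytest

from fhrfusion.preprocessing import SEGMENT_SAMPLES, FHRSegment, RawCTGRecord
from fhrfusion.synthetic import ClassParams, SyntheticConfig


@pytest.fixture
def flat_segment() -> FHRSegment:
    """A constant 140 bpm 20-minute segment."""
    return FHRSegment(
        fhr=np.full(SEGMENT_SAMPLES, 140.0),
        interpolated_fraction=0.0,
        record_id="flat",
        label=0,
        gestational_week=38.0,
        maternal_age=30.0,
    )


@pytest.fixture
def sinusoid_segment() -> FHRSegment:
    """140 bpm carrier with a 0.1 Hz, 5 bpm modulation."""
    t = np.arange(SEGMENT_SAMPLES) / 2.0
    return FHRSegment(
        fhr=140.0 + 5.0 * np.sin(2 * np.pi * 0.1 * t),
        interpolated_fraction=0.0,
        record_id="sine",
        label=0,
        gestational_week=36.0,
        maternal_age=28.0,
    )


@pytest.fixture
def noisy_segment() -> FHRSegment:
    """Reproducible noisy segment for property-style checks."""
    rng = np.random.default_rng(7)
    fhr = 140.0 + 6.0 * rng.standard_normal(SEGMENT_SAMPLES).cumsum() / 40.0
    fhr += 3.0 * rng.standard_normal(SEGMENT_SAMPLES)
    return FHRSegment(
        fhr=np.clip(fhr, 60.0, 200.0),
        interpolated_fraction=0.0,
        record_id="noisy",
        label=1,
        gestational_week=34.0,
        maternal_age=31.0,
    )


def make_record(fhr, label: int = 0, **kwargs) -> RawCTGRecord:
    return RawCTGRecord.from_fhr(
        fhr,
        label=label,
        gestational_week=kwargs.pop("gestational_week", 38.0),
        maternal_age=kwargs.pop("maternal_age", 30.0),
        **kwargs,
    )


@pytest.fixture
def quiet_event_params() -> ClassParams:
    """Low-noise generator settings where injected events clear the
    detection thresholds with comfortable amplitude and duration margins."""
    return ClassParams(
        lf_power=0.3,
        mf_power=0.1,
        hf_power=0.05,
        gap_rate=0.0,
        drift_amp_bpm=1.0,
        accel_rate=3.0,
        accel_amp_sd_bpm=0.0,
        accel_dur_sd_s=0.0,
        decel_rate=1.0,
        decel_amp_sd_bpm=0.0,
        decel_dur_sd_s=0.0,
    )


@pytest.fixture
def quiet_config(quiet_event_params) -> SyntheticConfig:
    return SyntheticConfig(healthy=quiet_event_params, pathological=quiet_event_params)
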