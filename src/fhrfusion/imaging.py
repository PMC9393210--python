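"""Signal-to-image encodings of FHR segments for the convolutional branch.

Eight encoders turn a 2400-sample (20-minute, 2 Hz) heart-rate segment into
single-channel images: a Morlet-wavelet scalogram (CWT), the Gramian angular
summation and difference fields (GASF / GADF), a Markov transition field
(MTF), the recurrence distance matrix S and its thresholded binary form R,
a short-time-Fourier power spectrogram (PS), and a persistence spectrum
(PSP).  Every encoder output is min-max normalized to [0,1] and resized to
64 x 64 by :func:`finalize`; :func:`stack` assembles a configurable ordered
subset of encoders into the network's image input.

Pairwise encoders (GASF/GADF/MTF/S/R) first reduce the segment to 64 points
by piecewise aggregate approximation (PAA), producing native 64 x 64 fields;
the time-frequency encoders work on the full-resolution signal and are
resized afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import get_window
from skimage.transform import resize as _sk_resize

from .preprocessing import FS_HZ, FHRSegment

IMAGE_SIZE = 64

ENCODER_NAMES = ("CWT", "GASF", "GADF", "MTF", "S", "R", "PS", "PSP")

#: Encoder subset found most discriminative for the convolutional branch.
DEFAULT_STACK = ("GADF", "PS", "PSP")

__all__ = [
    "IMAGE_SIZE",
    "ENCODER_NAMES",
    "DEFAULT_STACK",
    "EncodedImage",
    "ImageStack",
    "paa_downsample",
    "rescale_unit_interval",
    "gaf",
    "mtf",
    "recurrence",
    "cwt_scalogram",
    "power_spectrogram",
    "persistence_spectrum",
    "finalize",
    "encode",
    "stack",
]


@dataclass
class EncodedImage:
    """A 64 x 64 single-channel image with pixel values in [0,1]."""

    pixels: np.ndarray
    encoder_name: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"image must be {IMAGE_SIZE}x{IMAGE_SIZE}, got {self.pixels.shape}")
        if self.encoder_name not in ENCODER_NAMES:
            raise ValueError(f"unknown encoder {self.encoder_name!r}")


@dataclass
class ImageStack:
    """An ordered stack of distinct encoded images for one segment."""

    images: list[EncodedImage]

    def __post_init__(self) -> None:
        names = [im.encoder_name for im in self.images]
        if not 1 <= len(names) <= len(ENCODER_NAMES):
            raise ValueError("a stack holds between 1 and 8 images")
        if len(set(names)) != len(names):
            raise ValueError("encoder names in a stack must be distinct")

    @property
    def encoder_names(self) -> tuple[str, ...]:
        return tuple(im.encoder_name for im in self.images)

    def to_array(self) -> np.ndarray:
        """Channels-last array of shape (64, 64, n)."""
        return np.stack([im.pixels for im in self.images], axis=-1)


def paa_downsample(series, target_len: int) -> np.ndarray:
    """Piecewise aggregate approximation: block means down to ``target_len``.

    The series is split into ``target_len`` contiguous blocks of equal
    length where possible; any trailing remainder is folded into the last
    block.
    """
    x = np.asarray(series, dtype=float)
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    if len(x) < target_len:
        raise ValueError("series shorter than target length")
    if len(x) == target_len:
        return x.copy()
    block = len(x) // target_len
    out = x[: block * target_len].reshape(target_len, block).mean(axis=1)
    rem = len(x) - block * target_len
    if rem:
        # fold the remainder into the final block's mean
        out[-1] = x[block * (target_len - 1) :].mean()
    return out


def rescale_unit_interval(series, lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    """Min-max rescale to [lo, hi]; a constant series maps to the midpoint."""
    x = np.asarray(series, dtype=float)
    span = np.ptp(x)
    if span == 0:
        warnings.warn("constant series; rescaled to the interval midpoint")
        return np.full_like(x, (lo + hi) / 2.0)
    return lo + (hi - lo) * (x - x.min()) / span


def gaf(series, mode: str = "summation") -> np.ndarray:
    """Gramian angular field of a series rescaled to [-1, 1].

    With phases ``phi_i = arccos(x_i)`` of the rescaled series, the
    summation field is ``cos(phi_i + phi_j)`` and the difference field
    ``sin(phi_i - phi_j)``.  GASF is symmetric with diagonal 2x^2 - 1;
    GADF is antisymmetric with a zero diagonal.
    """
    if mode not in ("summation", "difference"):
        raise ValueError(f"mode must be 'summation' or 'difference', got {mode!r}")
    x = rescale_unit_interval(series, -1.0, 1.0)
    phi = np.arccos(np.clip(x, -1.0, 1.0))
    if mode == "summation":
        return np.cos(phi[:, None] + phi[None, :])
    return np.sin(phi[:, None] - phi[None, :])


def mtf(series, n_bins: int = 8, patch: int = 1) -> np.ndarray:
    """Markov transition field with optional patch aggregation.

    The series is quantile-binned into ``n_bins`` states; W is the
    row-normalized one-step transition matrix of successive states (a state
    with no outgoing transitions gets a uniform row); the full field is
    ``F[i, j] = W[state(i), state(j)]``, then averaged over non-overlapping
    ``patch`` x ``patch`` blocks.
    """
    x = np.asarray(series, dtype=float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if patch < 1 or len(x) % patch:
        raise ValueError("series length must divide into patch x patch blocks")
    # quantile binning; duplicate edges collapse for low-variance series
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    states = np.searchsorted(edges, x, side="left")

    w = np.zeros((n_bins, n_bins))
    np.add.at(w, (states[:-1], states[1:]), 1.0)
    row_sums = w.sum(axis=1, keepdims=True)
    uniform = np.full(n_bins, 1.0 / n_bins)
    w = np.where(row_sums > 0, w / np.maximum(row_sums, 1.0), uniform)

    field = w[states[:, None], states[None, :]]
    if patch > 1:
        k = len(x) // patch
        field = field.reshape(k, patch, k, patch).mean(axis=(1, 3))
    return field


def recurrence(series, eps: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Recurrence images: distance matrix S and binary matrix R.

    ``S[i, j] = |x_i - x_j|``; ``R[i, j] = 1`` iff ``S[i, j] <= eps``.  When
    ``eps`` is None it defaults to the 20th percentile of the off-diagonal
    distances, making the threshold scale-adaptive per segment.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    s = np.abs(x[:, None] - x[None, :])
    if eps is None:
        off = s[~np.eye(len(x), dtype=bool)]
        eps = float(np.percentile(off, 20)) if off.size else 0.0
    if eps < 0:
        raise ValueError("threshold eps must be non-negative")
    r = (s <= eps).astype(float)
    return s, r


def cwt_scalogram(
    segment: FHRSegment | np.ndarray,
    n_scales: int = 64,
    freq_range: tuple[float, float] = (0.01, 1.0),
    wavelet: str = "morl",
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet continuous-wavelet scalogram (coefficient magnitudes).

    Scales are geometrically spaced so their pseudo-frequencies cover
    ``freq_range``; rows are ordered from low to high pseudo-frequency.
    Returns (magnitude matrix of shape (n_scales, n_samples),
    pseudo-frequencies in Hz).
    """
    x = segment.fhr if isinstance(segment, FHRSegment) else np.asarray(segment, dtype=float)
    freqs = np.geomspace(freq_range[0], freq_range[1], n_scales)
    centre = pywt.central_frequency(wavelet)
    scales = centre * FS_HZ / freqs
    coeffs, actual = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / FS_HZ)
    return np.abs(coeffs), actual


def power_spectrogram(
    segment: FHRSegment | np.ndarray,
    window: int = 120,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """|STFT|^2 power spectrogram with a Hann window.

    Frames of ``window`` samples at ``overlap`` fractional overlap are Hann
    tapered and transformed (one-sided); power is the squared DFT magnitude
    with no additional scaling, so summing a frame's power over frequency
    (doubling the interior one-sided bins) recovers the windowed frame's
    energy exactly (Parseval).

    Returns (power of shape (n_freqs, n_frames), frequencies Hz, frame
    start times s).
    """
    x = segment.fhr if isinstance(segment, FHRSegment) else np.asarray(segment, dtype=float)
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    if window > len(x):
        raise ValueError("window longer than the signal")
    hop = max(1, int(round(window * (1 - overlap))))
    frames = np.lib.stride_tricks.sliding_window_view(x, window)[::hop]
    win = get_window("hann", window, fftbins=True)
    spec = np.fft.rfft(frames * win, axis=1)
    power = (np.abs(spec) ** 2).T / window
    freqs = np.fft.rfftfreq(window, d=1.0 / FS_HZ)
    times = np.arange(frames.shape[0]) * hop / FS_HZ
    return power, freqs, times


def persistence_spectrum(
    segment: FHRSegment | np.ndarray,
    n_freq_bins: int = 64,
    n_power_bins: int = 64,
    window: int = 120,
    overlap: float = 0.5,
    db_floor: float = -120.0,
) -> np.ndarray:
    """Occupancy histogram of the spectrogram in (frequency, dB-power) space.

    For every spectrogram frame and frequency bin, the 2-D histogram cell
    containing that frame's log-power is incremented; the summed counts show
    how persistently each frequency carries a given power.  The frequency
    axis is aggregated to ``n_freq_bins`` columns and the dB axis spans the
    observed dynamic range in ``n_power_bins`` rows.  Total count equals
    n_frames x n_freq_bins.
    """
    power, freqs, _ = power_spectrogram(segment, window=window, overlap=overlap)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power)
    db = np.maximum(db, db_floor)

    freq_idx = np.minimum(
        (np.arange(len(freqs)) * n_freq_bins) // len(freqs), n_freq_bins - 1
    )
    lo, hi = float(db.min()), float(db.max())
    if hi <= lo:
        hi = lo + 1.0
    pow_idx = np.clip(((db - lo) / (hi - lo) * n_power_bins).astype(int), 0, n_power_bins - 1)

    hist = np.zeros((n_power_bins, n_freq_bins))
    f_grid = np.broadcast_to(freq_idx[:, None], db.shape)
    np.add.at(hist, (pow_idx.ravel(), f_grid.ravel()), 1.0)
    return hist[::-1]  # high power at the top, as conventionally displayed


def finalize(matrix: np.ndarray, encoder_name: str) -> EncodedImage:
    """Min-max normalize a 2-D matrix to [0,1] and bilinearly resize to 64 x 64."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("finalize expects a 2-D matrix")
    span = np.ptp(m)
    if span == 0:
        warnings.warn(f"constant {encoder_name} matrix; emitting an all-zero image")
        m = np.zeros_like(m)
    else:
        m = (m - m.min()) / span
    if m.shape != (IMAGE_SIZE, IMAGE_SIZE):
        m = _sk_resize(m, (IMAGE_SIZE, IMAGE_SIZE), order=1, anti_aliasing=False, preserve_range=True)
    return EncodedImage(np.clip(m, 0.0, 1.0), encoder_name)


def encode(segment: FHRSegment | np.ndarray, encoder_name: str) -> EncodedImage:
    """Run a single named encoder on one segment and finalize its image."""
    x = segment.fhr if isinstance(segment, FHRSegment) else np.asarray(segment, dtype=float)
    if encoder_name in ("GASF", "GADF", "MTF", "S", "R"):
        series = paa_downsample(x, IMAGE_SIZE)
        if encoder_name == "GASF":
            mat = gaf(series, "summation")
        elif encoder_name == "GADF":
            mat = gaf(series, "difference")
        elif encoder_name == "MTF":
            mat = mtf(series, n_bins=8, patch=1)
        else:
            s, r = recurrence(series)
            mat = s if encoder_name == "S" else r
    elif encoder_name == "CWT":
        mat, _ = cwt_scalogram(x)
    elif encoder_name == "PS":
        mat, _, _ = power_spectrogram(x)
    elif encoder_name == "PSP":
        mat = persistence_spectrum(x)
    else:
        raise ValueError(f"unknown encoder {encoder_name!r}")
    return finalize(mat, encoder_name)


def stack(segment: FHRSegment | np.ndarray, encoders: tuple[str, ...] = DEFAULT_STACK) -> ImageStack:
    """Encode a segment with each configured encoder, in the declared order."""
    return ImageStack([encode(segment, name) for name in encoders])
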