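"""Feature extraction: STFT spectrograms, MFCCs and acoustic descriptors.

Two representations feed the classifiers:

* a short-time Fourier transform power spectrogram (the CNN input and
  the rule classifier's substrate), and
* mel-frequency cepstral coefficients in two variants, MFCC(20) and
  MFCC(40), extracted over the same frequency range as the spectrogram
  content (0--12 kHz) and pooled per cycle for the SVM/kNN models.

Three scalar descriptors operationalize the visual spectrogram
signatures: per-band energy fractions, the amplitude-modulation peak of
the high-band envelope ("vertical lines"), and the persistence of
stable high-frequency spectral lines ("horizontal lines").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import dct, rfft, rfftfreq
from scipy.signal import get_window, hilbert, resample_poly, welch

from .preprocess import BreathCycle, noise_filter

__all__ = [
    "FeatureParams",
    "Spectrogram",
    "MFCCMatrix",
    "AcousticDescriptors",
    "compute_spectrogram",
    "mel_filterbank",
    "compute_mfcc",
    "mfcc_feature_vector",
    "band_energy_fraction",
    "modulation_peak",
    "line_persistence",
    "describe_cycle",
    "spectrogram_image",
]


@dataclass(frozen=True)
class FeatureParams:
    """Extraction settings shared by spectrogram and MFCC stages."""

    window_s: float = 0.025
    hop_s: float = 0.010
    window: str = "hann"
    n_mels: int = 48
    mel_fmin: float = 0.0
    mel_fmax: float = 12000.0
    db_floor: float = -80.0
    image_size: int = 128
    image_fmax: float = 12000.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.hop_s <= 0:
            raise ValueError("window_s and hop_s must be positive")
        if self.n_mels < 2 or not 0 <= self.mel_fmin < self.mel_fmax:
            raise ValueError("invalid mel filter bank parameters")

    def with_(self, **kwargs) -> "FeatureParams":
        return replace(self, **kwargs)


@dataclass
class Spectrogram:
    """Time x frequency power matrix (linear power) with axis metadata."""

    power: np.ndarray  # shape (n_frames, n_freqs)
    freqs: np.ndarray  # Hz, 0 .. Nyquist
    times: np.ndarray  # s, frame centers
    sample_rate: int
    params: FeatureParams

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    def db(self, floor: float | None = None) -> np.ndarray:
        """Decibel view, floored (default: ``params.db_floor``) relative to peak."""
        floor = self.params.db_floor if floor is None else floor
        peak = float(np.max(self.power))
        if peak == 0.0:
            return np.full_like(self.power, floor)
        with np.errstate(divide="ignore"):
            d = 10.0 * np.log10(self.power / peak)
        return np.maximum(d, floor)


@dataclass
class MFCCMatrix:
    """Per-frame cepstral coefficients, ``n_coeffs`` x ``n_frames``."""

    coeffs: np.ndarray
    n_coeffs: int
    sample_rate: int
    params: FeatureParams
    metadata: dict = field(default_factory=dict)


@dataclass
class AcousticDescriptors:
    """Per-cycle scalars consumed by the rule-based classifier."""

    band_fractions: dict[str, float]
    modulation_peak_hz: float | None
    modulation_prominence: float
    line_persistence: float


def _as_samples(cycle) -> tuple[np.ndarray, int]:
    if isinstance(cycle, BreathCycle):
        return np.asarray(cycle.samples, dtype=float), cycle.sample_rate
    samples, sr = cycle
    return np.asarray(samples, dtype=float), int(sr)


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def compute_spectrogram(cycle, params: FeatureParams | None = None) -> Spectrogram:
    """Magnitude-squared STFT of one cycle.

    Frames of ``window_s`` seconds advance by ``hop_s``; each frame is
    windowed and transformed with a real FFT, and the power is the
    squared magnitude of the *unscaled* frame DFT (so per-frame Parseval
    holds directly).  Frequency coverage is 0 to Nyquist.
    """
    params = params or FeatureParams()
    x, sr = _as_samples(cycle)
    frame_len = int(round(params.window_s * sr))
    hop = int(round(params.hop_s * sr))
    if len(x) < frame_len:
        raise ValueError(
            f"cycle of {len(x)} samples is shorter than one window ({frame_len})"
        )
    win = get_window(params.window, frame_len, fftbins=True)
    frames = _frame_signal(x, frame_len, hop) * win
    power = np.abs(rfft(frames, axis=1)) ** 2
    freqs = rfftfreq(frame_len, d=1.0 / sr)
    times = (np.arange(power.shape[0]) * hop + frame_len / 2) / sr
    return Spectrogram(power, freqs, times, sr, params)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft_bins: int, sample_rate: float,
    fmin: float, fmax: float,
) -> np.ndarray:
    """Triangular mel filter bank, shape ``(n_mels, n_fft_bins)``.

    Filter centers are equally spaced on the mel scale between ``fmin``
    and ``fmax``; triangles peak at 1 (no area normalization).
    """
    frame_len = 2 * (n_fft_bins - 1)
    freqs = rfftfreq(frame_len, d=1.0 / sample_rate)
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_fft_bins))
    for m in range(n_mels):
        lo, center, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / (center - lo)
        down = (hi - freqs) / (hi - center)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def compute_mfcc(
    cycle,
    n_coeffs: int = 20,
    params: FeatureParams | None = None,
    allow_any_n: bool = False,
) -> MFCCMatrix:
    """Mel-frequency cepstral coefficients, MFCC(20) or MFCC(40).

    Per frame: power spectrum -> triangular mel filter bank (covering
    ``mel_fmin``..``mel_fmax``, the spectrogram content range) ->
    natural log -> orthonormal DCT-II, keeping the first ``n_coeffs``
    coefficients.  Other coefficient counts require ``allow_any_n``.
    """
    params = params or FeatureParams()
    if n_coeffs not in (20, 40) and not allow_any_n:
        raise ValueError(
            f"n_coeffs must be 20 or 40 (got {n_coeffs}); pass allow_any_n=True to override"
        )
    if n_coeffs < 1 or n_coeffs > params.n_mels:
        raise ValueError(f"n_coeffs must be in [1, n_mels={params.n_mels}]")
    spec = compute_spectrogram(cycle, params)
    fb = mel_filterbank(
        params.n_mels, spec.power.shape[1], spec.sample_rate,
        params.mel_fmin, params.mel_fmax,
    )
    mel_energy = spec.power @ fb.T
    log_e = np.log(mel_energy + 1e-10)
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, :n_coeffs].T
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite MFCC values")
    return MFCCMatrix(
        coeffs=coeffs,
        n_coeffs=n_coeffs,
        sample_rate=spec.sample_rate,
        params=params,
        metadata={
            "n_mels": params.n_mels,
            "mel_fmin": params.mel_fmin,
            "mel_fmax": params.mel_fmax,
            "filterbank": "triangular, stand-in design (supplementary banks unavailable)",
        },
    )


def mfcc_feature_vector(m: MFCCMatrix) -> np.ndarray:
    """Fixed-length per-cycle vector: per-coefficient mean then SD across frames."""
    mean = m.coeffs.mean(axis=1)
    sd = m.coeffs.std(axis=1)
    return np.concatenate([mean, sd])


def band_energy_fraction(spec: Spectrogram, band: tuple[float, float]) -> float:
    """Fraction of total spectrogram energy inside ``[low, high)`` Hz.

    The interval is half-open so a partition of 0..Nyquist sums to one;
    the upper edge is included when it reaches the last frequency bin.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"empty band {band}")
    if lo < 0 or hi > spec.freqs[-1] + 1e-9:
        raise ValueError(
            f"band {band} outside spectrogram range [0, {spec.freqs[-1]:.1f}] Hz"
        )
    mask = (spec.freqs >= lo) & (spec.freqs < hi)
    if hi >= spec.freqs[-1]:
        mask |= spec.freqs == spec.freqs[-1]
    total = float(np.sum(spec.power))
    if total == 0.0:
        return 0.0
    return float(np.sum(spec.power[:, mask]) / total)


def _suppress_spectral_lines(
    y: np.ndarray, sample_rate: float, block_hz: float = 100.0, clip_rel: float = 3.0
) -> np.ndarray:
    """Clip narrowband spectral spikes to ``clip_rel`` x the local floor.

    Stationary tones beat against each other and masquerade as amplitude
    modulation; flattening any FFT magnitude above ``clip_rel`` times the
    median of its ``block_hz``-wide neighbourhood removes the beats
    while leaving broadband (noise-like) content essentially untouched.
    """
    spectrum = rfft(y)
    mag = np.abs(spectrum)
    bins_per_block = max(int(round(block_hz * len(y) / sample_rate)), 1)
    n_blocks = int(np.ceil(len(mag) / bins_per_block))
    padded = np.pad(mag, (0, n_blocks * bins_per_block - len(mag)), constant_values=np.nan)
    block_med = np.nanmedian(padded.reshape(n_blocks, bins_per_block), axis=1)
    floor = np.repeat(block_med, bins_per_block)[: len(mag)]
    ceiling = clip_rel * np.maximum(floor, 1e-300)
    gain = np.minimum(1.0, ceiling / np.maximum(mag, 1e-300))
    from scipy.fft import irfft

    return irfft(spectrum * gain, n=len(y))


def modulation_peak(
    cycle,
    band_low: float = 1500.0,
    mod_range: tuple[float, float] = (20.0, 300.0),
    prominence_min: float = 6.0,
    env_rate: float = 2000.0,
) -> tuple[float, float] | None:
    """Dominant amplitude-modulation peak of the high-band envelope.

    The signal is high-passed at ``band_low``, narrowband spectral lines
    are suppressed (so stationary-tone beats do not register as
    modulation), and the Hilbert envelope is decimated to ``env_rate``
    Hz and Welch-averaged; the return value is ``(peak_hz, prominence)``
    where prominence is the peak amplitude relative to the median
    modulation spectrum in ``mod_range``.  Returns ``None`` when the
    prominence falls below ``prominence_min``.
    """
    x, sr = _as_samples(cycle)
    if len(x) < 0.5 * sr:
        raise ValueError("cycle shorter than 0.5 s; modulation spectrum unreliable")
    y = noise_filter(x, sr, band_low)
    y = _suppress_spectral_lines(y, sr)
    env = np.abs(hilbert(y))
    up, down = int(env_rate), int(sr)
    g = np.gcd(up, down)
    env_ds = resample_poly(env, up // g, down // g)
    env_ds = env_ds - np.mean(env_ds)
    nperseg = min(len(env_ds), int(env_rate))  # 1 s segments -> 1 Hz resolution
    f, pxx = welch(env_ds, fs=env_rate, nperseg=nperseg)
    amp = np.sqrt(pxx)
    sel = (f >= mod_range[0]) & (f <= mod_range[1])
    if not np.any(sel):
        return None
    med = float(np.median(amp[sel]))
    if med == 0.0:
        return None
    k = int(np.argmax(amp[sel]))
    peak_hz = float(f[sel][k])
    prominence = float(amp[sel][k] / med)
    if prominence < prominence_min:
        return None
    return peak_hz, prominence


def line_persistence(
    spec: Spectrogram,
    min_freq: float = 2000.0,
    peak_rel: float = 5.0,
    peak_percentile: float = 75.0,
    persist_frac: float = 0.8,
) -> float:
    """Fraction of frames carrying a stable high-frequency spectral line.

    A frame-level peak is a local maximum above ``min_freq`` exceeding
    ``peak_rel`` times the frame's ``peak_percentile`` power level in
    that region (a percentile reference rather than the median, so the
    near-empty bins between content and Nyquist cannot drag the floor to
    zero).  A bin is a *line* when a peak falls on it (+/- 1 bin) in at
    least ``persist_frac`` of the frames; the returned value is the
    fraction of frames containing at least one line peak.
    """
    if spec.n_frames < 5:
        raise ValueError("need at least 5 frames to assess line persistence")
    region = spec.freqs > min_freq
    if np.count_nonzero(region) < 3:
        raise ValueError(f"no spectrogram content above {min_freq} Hz")
    p = spec.power[:, region]
    ref = np.percentile(p, peak_percentile, axis=1, keepdims=True)
    local_max = np.zeros_like(p, dtype=bool)
    local_max[:, 1:-1] = (p[:, 1:-1] >= p[:, :-2]) & (p[:, 1:-1] >= p[:, 2:])
    peaks = local_max & (p > peak_rel * np.maximum(ref, 1e-300))
    # dilate +/- 1 bin so slow drift within a bin still counts
    dilated = peaks.copy()
    dilated[:, 1:] |= peaks[:, :-1]
    dilated[:, :-1] |= peaks[:, 1:]
    line_bins = dilated.mean(axis=0) >= persist_frac
    if not np.any(line_bins):
        return 0.0
    frame_has_line = np.any(dilated[:, line_bins], axis=1)
    return float(np.mean(frame_has_line))


def describe_cycle(cycle, params: FeatureParams | None = None) -> AcousticDescriptors:
    """Compute every descriptor the rule classifier needs, in one pass."""
    params = params or FeatureParams()
    spec = compute_spectrogram(cycle, params)
    nyq = spec.freqs[-1]
    fractions = {
        "low": band_energy_fraction(spec, (0.0, 1500.0)),
        "ns_band": band_energy_fraction(spec, (1500.0, 2000.0)),
        "highband": band_energy_fraction(spec, (2000.0, nyq)),
        "abnormal": band_energy_fraction(spec, (500.0, min(12000.0, nyq))),
    }
    mod = modulation_peak(cycle, prominence_min=0.0)
    peak_hz, prominence = mod if mod is not None else (None, 0.0)
    persistence = line_persistence(spec)
    return AcousticDescriptors(
        band_fractions=fractions,
        modulation_peak_hz=peak_hz,
        modulation_prominence=prominence,
        line_persistence=persistence,
    )


def spectrogram_image(spec: Spectrogram, params: FeatureParams | None = None) -> np.ndarray:
    """Fixed-size grayscale dB image for the CNN, values in [0, 1].

    Rows are frequency (row 0 = lowest, capped at ``image_fmax``),
    columns are time normalized to the cycle length.
    """
    from scipy.ndimage import zoom

    params = params or spec.params
    size = params.image_size
    keep = spec.freqs <= params.image_fmax
    d = spec.db()[:, keep].T  # (freq, time)
    d = (d - params.db_floor) / (-params.db_floor)
    d = np.clip(d, 0.0, 1.0)
    factors = (size / d.shape[0], size / d.shape[1])
    img = zoom(d, factors, order=1, grid_mode=True, mode="nearest")
    return np.clip(img[:size, :size], 0.0, 1.0).astype(np.float32)


def save_spectrogram_png(spec: Spectrogram, path, params: FeatureParams | None = None) -> None:
    """Export a dB-grayscale PNG (frequency up, time rightward)."""
    import matplotlib.image

    img = spectrogram_image(spec, params)
    matplotlib.image.imsave(path, img[::-1], cmap="gray", vmin=0.0, vmax=1.0)
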