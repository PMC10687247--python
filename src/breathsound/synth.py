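"""Synthetic labeled breathing-sound generation.

Every downstream stage of the pipeline (filtering, segmentation, feature
extraction, rule-based and ML classification) is testable against
corpora produced here, with exact ground-truth cycle bounds and labels.

Acoustic structure per class
----------------------------
NS  band-limited noise concentrated in ``ns_band`` (1500--2000 Hz) with a
    faint broadband floor.
VS  broadband excitation over ``abnormal_band`` (500--12000 Hz),
    amplitude-modulated by a raised cosine at ``vs_modulation_rate``
    (default 100 Hz, depth 0.9).
SS  3--6 stationary, harmonically unrelated sinusoids above 2000 Hz on a
    low broadband floor, sustained for the whole cycle.

All cycles are shaped by a rise--plateau--fall breath envelope
(20/60/20 % of the cycle, half-cosine ramps).  Generation is
deterministic: identical parameters and seed give bit-identical arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .labels import CLASS_LABELS, validate_label

__all__ = [
    "GeneratorParams",
    "LabeledSegment",
    "band_limited_noise",
    "breath_envelope",
    "generate_breath_cycle",
    "generate_recording",
    "draw_cycle_durations",
    "add_noise",
    "corpus_of_cycles",
]

# Per-class cycle-duration (mean, sd) in seconds for the default cohort.
DEFAULT_CYCLE_DURATIONS: dict[str, tuple[float, float]] = {
    "NS": (3.801, 1.592),
    "VS": (3.033, 0.949),
    "SS": (3.876, 1.246),
}


def _check_band(name: str, band: tuple[float, float], nyquist: float) -> None:
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError(f"{name}: band edges must satisfy 0 < low < high, got {band}")
    if hi >= nyquist:
        raise ValueError(
            f"{name}: upper edge {hi} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz"
        )


@dataclass(frozen=True)
class GeneratorParams:
    """Configuration for the synthetic breathing-sound generator."""

    sample_rate: int = 44100
    cycle_duration: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CYCLE_DURATIONS)
    )
    min_cycle_duration: float = 0.5  # truncation point of the duration draw
    breaths_per_minute: float = 10.5
    vs_modulation_rate: float = 100.0
    vs_modulation_depth: float = 0.9
    ns_band: tuple[float, float] = (1500.0, 2000.0)
    abnormal_band: tuple[float, float] = (500.0, 12000.0)
    ss_line_band: tuple[float, float] = (2000.0, 12000.0)
    ss_n_lines: tuple[int, int] = (3, 6)  # inclusive range of tone counts
    background_noise_max_hz: float = 1000.0
    event_noise_max_hz: float = 1500.0
    snr_db: float = 10.0
    peak_amplitude: float = 0.5

    def __post_init__(self) -> None:
        nyq = self.sample_rate / 2.0
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.breaths_per_minute <= 0:
            raise ValueError("breaths_per_minute must be positive")
        if self.vs_modulation_rate <= 0:
            raise ValueError("vs_modulation_rate must be positive")
        if not (0.0 < self.vs_modulation_depth <= 1.0):
            raise ValueError("vs_modulation_depth must be in (0, 1]")
        if self.min_cycle_duration <= 0:
            raise ValueError("min_cycle_duration must be positive")
        for name in ("ns_band", "abnormal_band", "ss_line_band"):
            _check_band(name, getattr(self, name), nyq)
        for name in ("background_noise_max_hz", "event_noise_max_hz"):
            val = getattr(self, name)
            if not (0 < val < nyq):
                raise ValueError(f"{name} must lie in (0, Nyquist), got {val}")
        for lab, (mean, sd) in self.cycle_duration.items():
            validate_label(lab)
            if mean <= 0 or sd < 0:
                raise ValueError(
                    f"cycle_duration[{lab}]: mean must be > 0 and sd >= 0"
                )
        lo, hi = self.ss_n_lines
        if not (1 <= lo <= hi):
            raise ValueError("ss_n_lines must be an increasing pair of counts >= 1")

    def with_(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


@dataclass
class LabeledSegment:
    """Audio plus per-cycle ground truth.

    ``cycle_bounds`` are half-open ``[start, end)`` intervals in seconds,
    sorted, non-overlapping and contained in the signal duration;
    ``labels`` is the parallel list of true class labels.
    """

    samples: np.ndarray
    sample_rate: int
    labels: list[str]
    cycle_bounds: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cycle_bounds):
            raise ValueError("labels and cycle_bounds must be parallel")
        dur = len(self.samples) / self.sample_rate
        prev_end = 0.0
        for start, end in self.cycle_bounds:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"cycle bound ({start}, {end}) outside signal duration {dur}"
                )
            if start < prev_end - 1e-9:
                raise ValueError("cycle_bounds must be sorted and non-overlapping")
            prev_end = end

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def label_table(self) -> pd.DataFrame:
        """Ground-truth table with columns ``cycle_id,start_s,end_s,label``."""
        return pd.DataFrame(
            {
                "cycle_id": np.arange(len(self.labels)),
                "start_s": [round(s, 3) for s, _ in self.cycle_bounds],
                "end_s": [round(e, 3) for _, e in self.cycle_bounds],
                "label": self.labels,
            }
        )


def band_limited_noise(
    rng: np.random.Generator, n: int, sample_rate: float,
    low_hz: float, high_hz: float,
) -> np.ndarray:
    """Gaussian noise confined to ``[low_hz, high_hz]``, unit RMS.

    Synthesized by masking the rFFT of white noise, so the out-of-band
    energy is zero up to numerical precision.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spectrum[(freqs < low_hz) | (freqs > high_hz)] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0.0:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz contains no FFT bins at n={n}"
        )
    return x / rms


def breath_envelope(n: int, rise_frac: float = 0.2, fall_frac: float = 0.2) -> np.ndarray:
    """Rise--plateau--fall amplitude envelope with half-cosine ramps."""
    n_rise = int(round(n * rise_frac))
    n_fall = int(round(n * fall_frac))
    n_plateau = n - n_rise - n_fall
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / max(n_rise, 1)))
    fall = 0.5 * (1 + np.cos(np.pi * np.arange(n_fall) / max(n_fall, 1)))
    return np.concatenate([rise, np.ones(n_plateau), fall])


def _ns_cycle(rng: np.random.Generator, n: int, p: GeneratorParams) -> np.ndarray:
    lo, hi = p.ns_band
    core = band_limited_noise(rng, n, p.sample_rate, lo, hi)
    # faint broadband floor, ~26 dB below the in-band content
    floor = band_limited_noise(rng, n, p.sample_rate, 100.0, p.abnormal_band[1])
    return core + 0.05 * floor


def _vs_excitation(rng: np.random.Generator, n: int, p: GeneratorParams) -> np.ndarray:
    lo, hi = p.abnormal_band
    carrier = band_limited_noise(rng, n, p.sample_rate, lo, hi)
    t = np.arange(n) / p.sample_rate
    d = p.vs_modulation_depth
    am = (1.0 - d) + d * 0.5 * (1.0 - np.cos(2 * np.pi * p.vs_modulation_rate * t))
    return carrier * am


def _ss_excitation(rng: np.random.Generator, n: int, p: GeneratorParams) -> np.ndarray:
    lo, hi = p.ss_line_band
    k = int(rng.integers(p.ss_n_lines[0], p.ss_n_lines[1] + 1))
    # harmonically unrelated tones: rejection-sample a minimum spacing
    freqs: list[float] = []
    margin = 100.0
    while len(freqs) < k:
        f = float(rng.uniform(lo + margin, hi - margin))
        if all(abs(f - g) > 300.0 for g in freqs):
            freqs.append(f)
    t = np.arange(n) / p.sample_rate
    x = np.zeros(n)
    for f in freqs:
        amp = float(rng.uniform(0.5, 1.0))
        phase = float(rng.uniform(0, 2 * np.pi))
        x += amp * np.sin(2 * np.pi * f * t + phase)
    x /= np.sqrt(np.mean(x**2))
    floor = band_limited_noise(rng, n, p.sample_rate, *p.abnormal_band)
    return x + 0.15 * floor


def generate_breath_cycle(
    label: str,
    duration: float,
    params: GeneratorParams | None = None,
    seed: int = 0,
    mixed: bool = False,
) -> LabeledSegment:
    """Generate one labeled respiratory cycle.

    Parameters
    ----------
    label
        ``NS``, ``VS`` or ``SS``.
    duration
        Cycle length in seconds (must be positive).
    mixed
        If True, superimpose the SS spectral lines on a VS excitation.
        The result carries both signatures and is labeled ``VS`` per the
        tie-break rule (mixed patterns indicate a still-movable obstacle).
    """
    params = params or GeneratorParams()
    validate_label(label)
    if duration <= 0:
        raise ValueError(f"cycle duration must be positive, got {duration}")
    if mixed and label != "VS":
        raise ValueError("mixed VS+SS cycles are labeled VS by the tie-break rule")
    n = int(round(duration * params.sample_rate))
    rng = np.random.default_rng(seed)
    if mixed:
        x = _vs_excitation(rng, n, params) + 0.8 * _ss_excitation(rng, n, params)
    elif label == "NS":
        x = _ns_cycle(rng, n, params)
    elif label == "VS":
        x = _vs_excitation(rng, n, params)
    else:
        x = _ss_excitation(rng, n, params)
    x *= breath_envelope(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= params.peak_amplitude / peak
    return LabeledSegment(
        samples=x,
        sample_rate=params.sample_rate,
        labels=[label],
        cycle_bounds=[(0.0, n / params.sample_rate)],
    )


def _draw_duration(rng: np.random.Generator, label: str, p: GeneratorParams) -> float:
    mean, sd = p.cycle_duration[label]
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if d >= p.min_cycle_duration:
            return float(d)
    raise RuntimeError("could not draw a cycle duration above the truncation point")


def draw_cycle_durations(
    label: str, n: int, params: GeneratorParams | None = None, seed: int = 0
) -> np.ndarray:
    """Sample ``n`` cycle durations for ``label`` (truncated normal)."""
    params = params or GeneratorParams()
    validate_label(label)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return np.array([_draw_duration(rng, label, params) for _ in range(n)])


def generate_recording(
    n_cycles_per_class: dict[str, int],
    params: GeneratorParams | None = None,
    seed: int = 0,
    n_mixed: int = 0,
) -> LabeledSegment:
    """Assemble a continuous annotated recording.

    Cycles of the requested classes are shuffled, given durations drawn
    from the per-class truncated normal, and concatenated with silent
    gaps sized so the overall breath rate approximates
    ``params.breaths_per_minute``.  ``n_mixed`` extra cycles carry both
    VS and SS signatures and are labeled VS.

    Noise is *not* added here; compose with :func:`add_noise`.
    """
    params = params or GeneratorParams()
    counts = {lab: int(c) for lab, c in n_cycles_per_class.items() if c}
    for lab in counts:
        validate_label(lab)
    total = sum(counts.values()) + n_mixed
    if total < 1:
        raise ValueError("at least one cycle must be requested")

    rng = np.random.default_rng(seed)
    plan: list[tuple[str, bool]] = [
        (lab, False) for lab, c in counts.items() for _ in range(c)
    ] + [("VS", True) for _ in range(n_mixed)]
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    sr = params.sample_rate
    period = 60.0 / params.breaths_per_minute
    min_gap_s = 0.3
    chunks: list[np.ndarray] = []
    labels: list[str] = []
    bounds: list[tuple[float, float]] = []
    cursor = 0  # in samples

    lead = np.zeros(int(round(0.5 * sr)))
    chunks.append(lead)
    cursor += len(lead)

    for lab, mixed in plan:
        dur = _draw_duration(rng, lab, params)
        cyc_seed = int(rng.integers(0, 2**31 - 1))
        cyc = generate_breath_cycle(lab, dur, params, seed=cyc_seed, mixed=mixed)
        start = cursor / sr
        chunks.append(cyc.samples)
        cursor += len(cyc.samples)
        bounds.append((start, cursor / sr))
        labels.append(lab)
        gap_s = max(min_gap_s, period - len(cyc.samples) / sr)
        gap = np.zeros(int(round(gap_s * sr)))
        chunks.append(gap)
        cursor += len(gap)

    return LabeledSegment(
        samples=np.concatenate(chunks),
        sample_rate=sr,
        labels=labels,
        cycle_bounds=bounds,
    )


def add_noise(
    signal: np.ndarray,
    sample_rate: float,
    kind: str = "background",
    snr_db: float = 10.0,
    seed: int = 0,
    params: GeneratorParams | None = None,
) -> np.ndarray:
    """Add band-limited noise at an exact signal-to-noise ratio.

    ``background`` noise is confined below 1000 Hz, ``event`` noise
    (speech etc.) below 1500 Hz.  The SNR is measured over the full
    signal; ``snr_db=inf`` returns the input unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("cannot add noise to an empty signal")
    if math.isinf(snr_db) and snr_db > 0:
        return signal.copy()
    params = params or GeneratorParams(sample_rate=int(sample_rate))
    if kind == "background":
        hi = params.background_noise_max_hz
    elif kind == "event":
        hi = params.event_noise_max_hz
    else:
        raise ValueError(f"noise kind must be 'background' or 'event', got {kind!r}")
    rng = np.random.default_rng(seed)
    noise = band_limited_noise(rng, signal.size, sample_rate, 20.0, hi)
    sig_rms = np.sqrt(np.mean(signal**2))
    if sig_rms == 0.0:
        raise ValueError("signal is silent; SNR is undefined")
    noise_rms = sig_rms / (10.0 ** (snr_db / 20.0))
    return signal + noise * noise_rms


def corpus_of_cycles(
    n_per_class: int,
    params: GeneratorParams | None = None,
    seed: int = 0,
    snr_db: float | None = None,
    labels: tuple[str, ...] = CLASS_LABELS,
) -> list[LabeledSegment]:
    """Independent noisy cycles, ``n_per_class`` of each label.

    Convenience builder for benchmarks: durations follow the per-class
    truncated normal and, when ``snr_db`` is given (default: the value in
    ``params``), background noise is added at that SNR.
    """
    params = params or GeneratorParams()
    snr = params.snr_db if snr_db is None else snr_db
    rng = np.random.default_rng(seed)
    out: list[LabeledSegment] = []
    for lab in labels:
        for _ in range(n_per_class):
            dur = _draw_duration(rng, lab, params)
            s1 = int(rng.integers(0, 2**31 - 1))
            s2 = int(rng.integers(0, 2**31 - 1))
            cyc = generate_breath_cycle(lab, dur, params, seed=s1)
            noisy = add_noise(cyc.samples, params.sample_rate, "background", snr, s2, params)
            out.append(
                LabeledSegment(noisy, params.sample_rate, [lab], [(0.0, cyc.duration)])
            )
    return out
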