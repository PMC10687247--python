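"""Noise filtering and respiratory-cycle segmentation.

Recorded tracheostomy breathing noise is concentrated below 1500 Hz
(background below 1000 Hz, event noise such as speech below 1500 Hz), so
the filtering stage is a linear-phase high-pass at 1500 Hz.  A
continuous recording is then cut into respiratory cycles — the analysis
unit of the whole pipeline — by hysteresis thresholding of a
band-limited short-time energy envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin

__all__ = [
    "BreathCycle",
    "SegmentationConfig",
    "noise_filter",
    "bandpass_filter",
    "segment_cycles",
    "cycle_duration_stats",
    "quality_gate",
]


@dataclass
class BreathCycle:
    """One respiratory cycle cut from a recording.

    ``start``/``end`` are seconds in the parent recording (half-open
    interval); ``true_label`` is optional ground truth.
    """

    start: float
    end: float
    samples: np.ndarray
    sample_rate: int
    true_label: str | None = None

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"cycle end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationConfig:
    """Hysteresis energy-envelope detector settings.

    The noise floor is the 10th percentile of frame RMS values, but never
    less than ``floor_rel_min`` times the peak frame RMS (guards against
    digitally-silent gaps driving the floor to zero).
    """

    highpass_cutoff: float = 1500.0
    energy_band: tuple[float, float] = (1500.0, 12000.0)
    frame: float = 0.05
    on_threshold: float = 3.0
    off_threshold: float = 1.5
    min_cycle: float = 0.5
    min_gap: float = 0.2
    floor_percentile: float = 10.0
    floor_rel_min: float = 1e-3

    def __post_init__(self) -> None:
        if not self.on_threshold > self.off_threshold > 0:
            raise ValueError("need on_threshold > off_threshold > 0")
        if self.min_cycle <= 0 or self.min_gap < 0 or self.frame <= 0:
            raise ValueError("frame and min_cycle must be positive, min_gap >= 0")
        lo, hi = self.energy_band
        if not 0 < lo < hi:
            raise ValueError(f"invalid energy_band {self.energy_band}")

    def with_(self, **kwargs) -> "SegmentationConfig":
        return replace(self, **kwargs)


def _highpass_taps(cutoff: float, sample_rate: float) -> np.ndarray:
    # transition width ~cutoff/2 keeps -1 dB at 1.25*cutoff and
    # >40 dB rejection at 0.75*cutoff with a Hamming window
    numtaps = int(round(8.0 * sample_rate / cutoff))
    numtaps += 1 - numtaps % 2  # type I (odd) for a high-pass
    numtaps = max(numtaps, 101)
    return firwin(numtaps, cutoff, fs=sample_rate, pass_zero=False)


def _apply_fir(signal: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # linear phase: convolve and remove the group delay, keeping length
    delay = (len(taps) - 1) // 2
    full = fftconvolve(signal, taps, mode="full")
    return full[delay : delay + len(signal)]


def noise_filter(signal: np.ndarray, sample_rate: float, cutoff: float = 1500.0) -> np.ndarray:
    """Linear-phase FIR high-pass removing sub-``cutoff`` noise.

    The -6 dB point sits at ``cutoff``; attenuation is <= 1 dB above
    1.25x cutoff and >= 40 dB below 0.75x cutoff.  Output length equals
    input length and the operation is exactly linear.
    """
    signal = np.asarray(signal, dtype=float)
    nyq = sample_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    return _apply_fir(signal, _highpass_taps(cutoff, sample_rate))


def bandpass_filter(
    signal: np.ndarray, sample_rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Linear-phase FIR band-pass used for the detection envelope."""
    signal = np.asarray(signal, dtype=float)
    lo, hi = band
    nyq = sample_rate / 2.0
    hi = min(hi, 0.98 * nyq)
    if not 0 < lo < hi:
        raise ValueError(f"invalid band {band} for sample rate {sample_rate}")
    numtaps = max(int(round(8.0 * sample_rate / lo)), 101)
    numtaps += 1 - numtaps % 2
    taps = firwin(numtaps, [lo, hi], fs=sample_rate, pass_zero=False)
    return _apply_fir(signal, taps)


def _frame_rms(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    return np.sqrt(np.mean(frames**2, axis=1))


def segment_cycles(
    signal: np.ndarray,
    sample_rate: float,
    config: SegmentationConfig | None = None,
    true_table: pd.DataFrame | None = None,
) -> list[BreathCycle]:
    """Detect respiratory cycles in a continuous recording.

    The detector computes frame RMS of the band-passed signal
    (``energy_band``), estimates the noise floor, then walks the
    envelope with hysteresis: a cycle opens when the envelope exceeds
    ``on_threshold x floor`` and closes when it drops below
    ``off_threshold x floor``.  Events closer than ``min_gap`` are
    merged; events shorter than ``min_cycle`` are discarded.

    If ``true_table`` (columns ``start_s,end_s,label``) is given, each
    detected cycle inherits the label of the ground-truth interval it
    overlaps most.
    """
    config = config or SegmentationConfig()
    signal = np.asarray(signal, dtype=float)
    frame_len = int(round(config.frame * sample_rate))
    hop = max(frame_len // 2, 1)
    if len(signal) < frame_len:
        raise ValueError(
            f"signal ({len(signal)} samples) is shorter than one frame ({frame_len})"
        )

    banded = bandpass_filter(signal, sample_rate, config.energy_band)
    env = _frame_rms(banded, frame_len, hop)

    peak = float(np.max(env))
    if peak == 0.0:
        return []
    floor = max(
        float(np.percentile(env, config.floor_percentile)),
        config.floor_rel_min * peak,
    )
    on_level = config.on_threshold * floor
    off_level = config.off_threshold * floor

    events: list[tuple[int, int]] = []  # frame index intervals [i, j)
    open_at: int | None = None
    for i, e in enumerate(env):
        if open_at is None and e > on_level:
            open_at = i
        elif open_at is not None and e < off_level:
            events.append((open_at, i))
            open_at = None
    if open_at is not None:
        events.append((open_at, len(env)))

    def to_seconds(iv: tuple[int, int]) -> tuple[float, float]:
        start = iv[0] * hop / sample_rate
        end = min((iv[1] - 1) * hop + frame_len, len(signal)) / sample_rate
        return start, end

    merged: list[tuple[float, float]] = []
    for iv in events:
        s, e = to_seconds(iv)
        if merged and s - merged[-1][1] < config.min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    kept = [(s, e) for s, e in merged if e - s >= config.min_cycle]

    cycles = []
    for s, e in kept:
        i0, i1 = int(round(s * sample_rate)), int(round(e * sample_rate))
        label = None
        if true_table is not None:
            label = _best_overlap_label(s, e, true_table)
        cycles.append(BreathCycle(s, e, signal[i0:i1], int(sample_rate), label))
    return cycles


def _best_overlap_label(start: float, end: float, table: pd.DataFrame) -> str | None:
    overlaps = np.minimum(end, table["end_s"]) - np.maximum(start, table["start_s"])
    best = int(np.argmax(overlaps.to_numpy()))
    if overlaps.iloc[best] <= 0:
        return None
    return str(table["label"].iloc[best]) if "label" in table else None


def cycle_duration_stats(
    cycles: Sequence[BreathCycle],
    by_label: bool = False,
) -> pd.DataFrame:
    """Mean and sample SD (``ddof=1``) of cycle durations.

    Returns a table with columns ``n, mean_s, sd_s`` (indexed by label
    when ``by_label``).  For a single cycle the SD is undefined and
    reported as NaN, with ``n == 1`` flagging the case.
    """
    if len(cycles) == 0:
        raise ValueError("no cycles given")
    df = pd.DataFrame(
        {
            "duration": [c.duration for c in cycles],
            "label": [c.true_label for c in cycles],
        }
    )

    def stats(d: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "n": int(len(d)),
                "mean_s": float(d.mean()),
                "sd_s": float(d.std(ddof=1)) if len(d) > 1 else float("nan"),
            }
        )

    if by_label:
        out = df.groupby("label", sort=False)["duration"].apply(stats).unstack()
        out["n"] = out["n"].astype(int)
        return out
    return stats(df["duration"]).to_frame().T


def quality_gate(
    cycles: Sequence[BreathCycle],
    config: SegmentationConfig | None = None,
) -> list[BreathCycle]:
    """Drop cycles that would have been excluded from analysis.

    Two exclusion rules: (1) very low breathing sounds — peak in-band
    envelope under twice the in-band noise floor; (2) severe noise
    contamination — out-of-band (< 1500 Hz) energy exceeding in-band
    energy by more than 10 dB.
    """
    config = config or SegmentationConfig()
    kept = []
    for c in cycles:
        frame_len = int(round(config.frame * c.sample_rate))
        if len(c.samples) < frame_len:
            continue
        banded = bandpass_filter(c.samples, c.sample_rate, config.energy_band)
        env = _frame_rms(banded, frame_len, max(frame_len // 2, 1))
        floor = max(float(np.percentile(env, config.floor_percentile)), 1e-12)
        if float(np.max(env)) < 2.0 * floor:
            continue
        in_band = float(np.sum(banded**2))
        out_band = float(np.sum(c.samples**2)) - in_band
        if out_band > in_band * 10.0 and in_band > 0:
            continue
        kept.append(c)
    return kept
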