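"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: band energies
come from a full-signal FFT, MFCCs from an explicit per-frame loop with
the DCT written out as a sum, kNN from an exhaustive distance scan, and
AUC from all pairwise comparisons.
"""

from __future__ import annotations

import numpy as np


def fft_band_energy_fraction(
    x: np.ndarray, sample_rate: float, low_hz: float, high_hz: float
) -> float:
    """Energy fraction in [low, high) Hz from one full-signal FFT."""
    spectrum = np.fft.rfft(np.asarray(x, dtype=float))
    power = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sample_rate)
    total = power.sum()
    if total == 0:
        return 0.0
    sel = (freqs >= low_hz) & (freqs < high_hz)
    return float(power[sel].sum() / total)


def mfcc_bruteforce(
    frames_power: np.ndarray,
    sample_rate: float,
    frame_len: int,
    n_mels: int,
    n_coeffs: int,
    fmin: float,
    fmax: float,
) -> np.ndarray:
    """Loop-based mel filter bank + explicit DCT-II on power frames.

    ``frames_power`` has shape (n_frames, n_bins) with
    ``n_bins = frame_len // 2 + 1``.  Returns (n_coeffs, n_frames).
    """

    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def inv_mel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    n_bins = frames_power.shape[1]
    freqs = np.arange(n_bins) * sample_rate / frame_len
    pts = inv_mel(np.linspace(mel(fmin), mel(fmax), n_mels + 2))
    out = np.zeros((n_coeffs, frames_power.shape[0]))
    for t in range(frames_power.shape[0]):
        mel_e = np.zeros(n_mels)
        for m in range(n_mels):
            lo, c, hi = pts[m], pts[m + 1], pts[m + 2]
            for b in range(n_bins):
                f = freqs[b]
                if lo < f < c:
                    w = (f - lo) / (c - lo)
                elif c <= f < hi:
                    w = (hi - f) / (hi - c)
                elif f == c:
                    w = 1.0
                else:
                    w = 0.0
                mel_e[m] += w * frames_power[t, b]
        log_e = np.log(mel_e + 1e-10)
        for k in range(n_coeffs):
            s = 0.0
            for m in range(n_mels):
                s += log_e[m] * np.cos(np.pi * k * (2 * m + 1) / (2 * n_mels))
            scale = np.sqrt(1.0 / n_mels) if k == 0 else np.sqrt(2.0 / n_mels)
            out[k, t] = scale * s
    return out


def knn_bruteforce(
    X_train: np.ndarray, y_train: np.ndarray, X_query: np.ndarray, k: int,
    class_order: list,
) -> np.ndarray:
    """Exhaustive-scan kNN with majority vote (first class wins ties)."""
    preds = []
    for q in X_query:
        d = np.sqrt(((X_train - q) ** 2).sum(axis=1))
        nearest = np.argsort(d, kind="stable")[:k]
        votes = [np.sum(y_train[nearest] == c) for c in class_order]
        preds.append(class_order[int(np.argmax(votes))])
    return np.array(preds)


def auc_pairwise(y_true: np.ndarray, scores: np.ndarray, positive) -> float:
    """AUC as the pairwise rank statistic (ties count one half)."""
    pos = scores[np.asarray(y_true) == positive]
    neg = scores[np.asarray(y_true) != positive]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
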