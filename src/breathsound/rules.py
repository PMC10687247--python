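"""Rule-based three-category classifier.

Deterministic operationalization of the visual spectrogram signatures:

* VS — repetitive amplitude bursts around 100 per second, detected as a
  prominent peak of the high-band envelope modulation spectrum within
  ``vs_modulation_band``.
* SS — sustained high-frequency spectral lines, detected as a high
  energy fraction above 2 kHz combined with persistent line peaks.
* NS — the default when neither abnormal pattern fires.

A cycle exhibiting both patterns is labeled VS: a mixed pattern points
to a still-movable obstacle, and suction is the faster, lower-risk
first intervention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .features import AcousticDescriptors, FeatureParams, describe_cycle
from .labels import validate_label  # noqa: F401  (re-exported convenience)

__all__ = [
    "RuleThresholds",
    "detect_vs_pattern",
    "detect_ss_pattern",
    "classify_cycle",
    "classify_signal",
]


@dataclass(frozen=True)
class RuleThresholds:
    """Quantitative thresholds for the qualitative signatures.

    Defaults were tuned on the default synthetic corpus and are all
    config-exposed.
    """

    vs_modulation_band: tuple[float, float] = (50.0, 150.0)
    vs_prominence_min: float = 6.0
    ss_highband_fraction_min: float = 0.4
    ss_persistence_min: float = 0.6
    ns_band_fraction_min: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.vs_modulation_band
        if not 0 < lo < hi:
            raise ValueError("invalid vs_modulation_band")
        for name in ("ss_highband_fraction_min", "ss_persistence_min", "ns_band_fraction_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.vs_prominence_min <= 0:
            raise ValueError("vs_prominence_min must be positive")

    def with_(self, **kwargs) -> "RuleThresholds":
        return replace(self, **kwargs)


def _check(desc: AcousticDescriptors) -> None:
    if desc is None or desc.band_fractions is None:
        raise ValueError("descriptors are incomplete")
    for key in ("highband", "ns_band"):
        if key not in desc.band_fractions:
            raise ValueError(f"descriptor band_fractions missing {key!r}")


def detect_vs_pattern(
    desc: AcousticDescriptors, thr: RuleThresholds | None = None
) -> tuple[bool, float]:
    """Vertical-line (amplitude burst) detector.

    Fires when the modulation peak lies inside ``vs_modulation_band``
    with prominence at least ``vs_prominence_min``.  The score is the
    prominence normalized by its threshold (>= 1 means detected).
    """
    thr = thr or RuleThresholds()
    _check(desc)
    lo, hi = thr.vs_modulation_band
    if desc.modulation_peak_hz is None or not lo <= desc.modulation_peak_hz <= hi:
        return False, 0.0
    score = desc.modulation_prominence / thr.vs_prominence_min
    return score >= 1.0, score


def detect_ss_pattern(
    desc: AcousticDescriptors, thr: RuleThresholds | None = None
) -> tuple[bool, float]:
    """Horizontal-line detector.

    Fires when the energy fraction above 2 kHz reaches
    ``ss_highband_fraction_min`` *and* line persistence reaches
    ``ss_persistence_min``.  The score is the weaker of the two
    normalized ratios (>= 1 means detected).
    """
    thr = thr or RuleThresholds()
    _check(desc)
    frac = desc.band_fractions["highband"] / thr.ss_highband_fraction_min
    pers = desc.line_persistence / thr.ss_persistence_min
    score = min(frac, pers)
    return score >= 1.0, score


def classify_cycle(
    desc: AcousticDescriptors, thr: RuleThresholds | None = None
) -> tuple[str, dict]:
    """Label one cycle; VS takes precedence over SS (clinical tie-break).

    Returns ``(label, trace)`` where the trace records both pattern
    scores and which rule fired.
    """
    thr = thr or RuleThresholds()
    vs_flag, vs_score = detect_vs_pattern(desc, thr)
    ss_flag, ss_score = detect_ss_pattern(desc, thr)
    if vs_flag:
        label, rule = "VS", "vs_pattern"
    elif ss_flag:
        label, rule = "SS", "ss_pattern"
    else:
        label, rule = "NS", "default_ns"
    trace = {
        "vs_detected": vs_flag,
        "ss_detected": ss_flag,
        "vs_score": vs_score,
        "ss_score": ss_score,
        "rule_fired": rule,
    }
    return label, trace


def classify_signal(
    samples, sample_rate: int,
    thr: RuleThresholds | None = None,
    feature_params: FeatureParams | None = None,
) -> tuple[str, dict]:
    """Descriptor extraction plus rule classification for raw samples."""
    desc = describe_cycle((samples, sample_rate), feature_params)
    return classify_cycle(desc, thr)
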