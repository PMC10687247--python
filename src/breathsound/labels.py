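"""Breathing-sound class labels and the binary (normal/abnormal) view.

Three categories are used throughout the pipeline:

``NS``
    Normal breathing sound: low acoustic energy concentrated roughly in
    the 1500--2000 Hz band.
``VS``
    Vibrant breathing sound: a movable obstacle produces repetitive
    amplitude bursts at roughly 100 events per second ("vertical lines"
    in the spectrogram).  Clinical action: suction.
``SS``
    Sharp breathing sound: a fixed obstacle narrows the airway and
    produces sustained high-frequency spectral lines ("horizontal
    lines").  Clinical action: suction or tube/inner-cannula change.

The binary view maps ``NS`` to ``normal`` and both ``VS`` and ``SS`` to
``abnormal``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

#: Canonical label order used everywhere (tables, confusion matrices).
CLASS_LABELS: tuple[str, ...] = ("NS", "VS", "SS")

#: Labels considered abnormal in the binary view.
ABNORMAL_LABELS: frozenset[str] = frozenset({"VS", "SS"})

NORMAL = "normal"
ABNORMAL = "abnormal"
BINARY_LABELS: tuple[str, str] = (NORMAL, ABNORMAL)


def validate_label(label: str) -> str:
    """Return *label* if it is one of ``NS``/``VS``/``SS``, else raise.

    Labels are case-sensitive by contract: ``"ns"`` is rejected.
    """
    if label not in CLASS_LABELS:
        raise ValueError(
            f"unknown class label {label!r}; expected one of {CLASS_LABELS}"
        )
    return label


def validate_labels(labels: Iterable[str]) -> list[str]:
    """Validate a sequence of labels, reporting every offending entry."""
    labels = list(labels)
    bad = [(i, lab) for i, lab in enumerate(labels) if lab not in CLASS_LABELS]
    if bad:
        detail = ", ".join(f"row {i}: {lab!r}" for i, lab in bad[:20])
        raise ValueError(
            f"{len(bad)} unknown class label(s) (expected one of {CLASS_LABELS}): {detail}"
        )
    return labels


def to_binary(labels: Sequence[str] | str) -> np.ndarray | str:
    """Collapse three-class labels to the normal/abnormal binary view."""
    if isinstance(labels, str):
        validate_label(labels)
        return ABNORMAL if labels in ABNORMAL_LABELS else NORMAL
    validate_labels(labels)
    return np.array(
        [ABNORMAL if lab in ABNORMAL_LABELS else NORMAL for lab in labels]
    )


def is_abnormal(label: str) -> bool:
    validate_label(label)
    return label in ABNORMAL_LABELS
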