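"""Shared fixtures: synthetic corpora and derived features.

Heavy artifacts are session-scoped and reused across test modules to
keep the suite inside its runtime budget.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("breathsound", database=None, deadline=None)
settings.load_profile("breathsound")

from breathsound.features import (
    compute_mfcc,
    describe_cycle,
    mfcc_feature_vector,
)
from breathsound.synth import GeneratorParams, corpus_of_cycles

#: Seed of the default benchmark corpus (100 cycles/class, SNR 10 dB).
CORPUS_SEED = 1


@pytest.fixture(scope="session")
def gen_params() -> GeneratorParams:
    return GeneratorParams()


@pytest.fixture(scope="session")
def corpus100(gen_params):
    """The default benchmark corpus: 100 noisy cycles per class."""
    return corpus_of_cycles(100, gen_params, seed=CORPUS_SEED, snr_db=10.0)


@pytest.fixture(scope="session")
def corpus30(gen_params):
    """A smaller corpus for unit-level checks."""
    return corpus_of_cycles(30, gen_params, seed=CORPUS_SEED + 1, snr_db=10.0)


@pytest.fixture(scope="session")
def descriptors100(corpus100):
    """(true_label, AcousticDescriptors) for every corpus100 cycle."""
    return [
        (seg.labels[0], describe_cycle((seg.samples, seg.sample_rate)))
        for seg in corpus100
    ]


@pytest.fixture(scope="session")
def mfcc20_corpus(corpus100):
    """Pooled MFCC(20) feature matrix and labels for corpus100."""
    X = np.array(
        [
            mfcc_feature_vector(compute_mfcc((seg.samples, seg.sample_rate), 20))
            for seg in corpus100
        ]
    )
    y = np.array([seg.labels[0] for seg in corpus100])
    return X, y
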