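"""Shared fixtures: the desk corpus and self-distilled models.

Training the small backbone takes about a minute and a half per seed, so
the three-seed model set is built once per session and shared between the
training-signal, heterogeneity and determinism checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from celldistill import protocols


@pytest.fixture(scope="session")
def corpus():
    """2,000 training and 400 held-out 4-class localization scenes."""
    return protocols.default_corpus()


@pytest.fixture(scope="session")
def ssl_runs(corpus):
    """Training-signal experiments for three training seeds (models included)."""
    return {seed: protocols.training_signal_experiment(seed, corpus=corpus)
            for seed in (0, 1, 2)}


@pytest.fixture(scope="session")
def trained_model(ssl_runs):
    """The seed-0 self-distilled teacher backbone."""
    return ssl_runs[0]["model"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
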