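"""Shared fixtures: small synthetic epoch sets generated at test time."""

import numpy as np
import pytest

from ssafbcsp import SynthConfig, generate_epochs


@pytest.fixture(scope="session")
def mi_epochs_small():
    """Cheap 2-class set for structural tests: 6 channels, 160 Hz, 2 s."""
    cfg = SynthConfig(
        n_classes=2, trials_per_class=10, n_channels=6, fs=160.0,
        epoch_len=2.0, planted_bands=[(10.0, 14.0), (20.0, 24.0)],
        erd_depth=0.6, source_channels=(0, 1), seed=7,
    )
    return generate_epochs(cfg)


@pytest.fixture(scope="session")
def separable_epochs():
    """Strongly separable 2-class set: deep ERD, no distractor rhythms."""
    cfg = SynthConfig(
        n_classes=2, trials_per_class=40, n_channels=8, fs=250.0,
        epoch_len=4.0, planted_bands=[(10.0, 14.0)], erd_depth=0.8,
        source_channels=(0, 1), distractor_bands=[], seed=11,
    )
    return generate_epochs(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
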