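import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from myofeat import SynthConfig, generate_dataset
from myofeat.evaluate import extract_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic conditions: 10 movements x 6 trials x 5 s @ 2 kHz,
    2 channels, noise RMS 0.03."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def proposed_features(default_dataset):
    """PROPOSED-set feature matrix for the default dataset (250 ms windows)."""
    return extract_dataset(default_dataset, "PROPOSED")


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced conditions for sweep-style tests: 4 movements x 3 trials x
    1.4 s, enough for four 350 ms windows per trial."""
    amps = {"A": (0.05, 0.04), "B": (0.10, 0.08), "C": (0.18, 0.14), "D": (0.30, 0.24)}
    cfg = SynthConfig(
        movements=tuple(amps), amplitudes=amps, n_trials=3, duration_s=1.4, seed=3
    )
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
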