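import numpy as np
import pytest

from crescan.align import ScoringScheme
from crescan.significance import BackgroundModel, CalibrationCache


@pytest.fixture(scope="session")
def default_scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def gapped_params(default_scheme):
    """One shared gapped calibration for the whole suite (deterministic)."""
    return CalibrationCache().get(default_scheme, BackgroundModel(), seq_len=500, n_sims=500, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dna(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def sharp_pfm():
    """Near-unanimous width-8 PFM (planted-motif recovery fixture).

    Consensus ACGATGTA; off-consensus bases at 0.1% per column, so
    sampled instances are almost always the consensus word.
    """
    return np.array(
        [
            [997, 1, 1, 997, 1, 1, 1, 997],
            [1, 997, 1, 1, 1, 1, 1, 1],
            [1, 1, 997, 1, 1, 997, 1, 1],
            [1, 1, 1, 1, 997, 1, 997, 1],
        ],
        dtype=float,
    )
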