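import pandas as pd
import pytest

from cofracnet.io import FractionationExperiment
from cofracnet.simulate import NoiseParams, apply_rewiring, simulate_catalog


def make_experiment(counts, state="ECSC", technique="SEC", replicate="r1", proteins=None):
    """Small in-memory elution matrix for unit tests."""
    df = pd.DataFrame(counts)
    df.index = proteins if proteins is not None else [f"P{i}" for i in range(len(df))]
    df.columns = [f"F{j+1}" for j in range(df.shape[1])]
    return FractionationExperiment(state=state, technique=technique, replicate=replicate, data=df)


@pytest.fixture
def quiet_noise():
    """Noise-free generative settings: deterministic counts, no dropout."""
    return NoiseParams(
        count_dispersion=0.0, dropout_prob=0.0, monomer_prob=0.0, counting_noise=False
    )


@pytest.fixture
def small_truth():
    truth = simulate_catalog(
        n_complexes=8, size_distribution=(2, 5), n_background_proteins=30, seed=11
    )
    return apply_rewiring(truth, 0.25)
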