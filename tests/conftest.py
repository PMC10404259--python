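import numpy as np
import pandas as pd
import pytest

from metstab import METDataset, SyntheticConfig, generate_met, groundnut_trial_config


def make_dataset(values, trait="value"):
    """Build a METDataset from a (g, e, r) array of values."""
    values = np.asarray(values, dtype=float)
    g, e, r = values.shape
    rows = [
        (f"G{i+1:02d}", f"E{j+1}", f"R{l+1}", values[i, j, l])
        for i in range(g) for j in range(e) for l in range(r)
    ]
    df = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "value"])
    return METDataset(df, trait=trait)


def random_dataset(rng, g, e, r, scale=10.0):
    return make_dataset(rng.normal(0.0, scale, size=(g, e, r)) + 50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20170725)


@pytest.fixture
def toy_2x2x2():
    """Replicate pairs (10,12), (0,0), (5,7), (3,3): cell means [[11,0],[6,3]]."""
    return make_dataset([[[10, 12], [0, 0]], [[5, 7], [3, 3]]])


@pytest.fixture(scope="session")
def trial_config():
    return groundnut_trial_config(seed=7)


@pytest.fixture(scope="session")
def trial_data(trial_config):
    return generate_met(trial_config)


def noiseless_config(seed=3, k=1, **kw):
    """Exact additive + planted low-rank interaction, no noise, no blocks."""
    lam = tuple([120.0, 40.0][:k])
    base = dict(g=8, e=4, r=2, mu=100.0, genotype_sd=12.0, environment_sd=30.0,
                gei_singular_values=lam, rep_sd=0.0, noise_sd=0.0,
                rainfall=(400.0, 250.0, 500.0, 320.0), seed=seed)
    base.update(kw)
    return SyntheticConfig(**base)
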