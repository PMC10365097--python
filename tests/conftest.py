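import numpy as np
import pytest

from fedchow import SimulationSpec, simulate_trio_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trio_dataset():
    """60-gene planted dataset reused by scan-level tests."""
    spec = SimulationSpec(
        n_samples=300,
        n_genes=60,
        n_causal_genes=1,
        n_snps=6,
        n_causal_snps=1,
        balanced_groups=True,
        seed=7,
    )
    return spec, simulate_trio_dataset(spec)


def three_group_data(rng, slopes=(1.0, 1.0, 1.0), n_per_group=30,
                     noise_sd=0.5, intercepts=(0.0, 0.0, 0.0)):
    """Hand-rolled generator independent of the synth module, for oracle
    tests of the regression/Chow layer."""
    labels = np.repeat([0, 1, 2], n_per_group)
    x = rng.normal(size=labels.size)
    y = np.empty_like(x)
    for g in range(3):
        mask = labels == g
        y[mask] = intercepts[g] + slopes[g] * x[mask] + rng.normal(
            0, noise_sd, mask.sum()
        )
    return x, y, labels
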