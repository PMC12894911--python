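import numpy as np
import pytest

from pmikit import SynthConfig, generate_cohort, split_dataset
from pmikit.preprocessing import preprocess_table


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 250 x 60 cohort with planted trends."""
    return generate_cohort(SynthConfig(n_samples=250, n_features=60, seed=7))


@pytest.fixture(scope="session")
def small_standardized(small_cohort):
    table, truth = small_cohort
    std, params, _ = preprocess_table(table)
    split = split_dataset(std, seed=7)
    parts = {name: std.subset_samples(split.mask(name)) for name in ("train", "validation", "test")}
    return {"std": std, "params": params, "split": split, "truth": truth, **parts}


@pytest.fixture(scope="session")
def default_cohort():
    """The default desk-scale study cohort (1500 x 300)."""
    return generate_cohort(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_prepared(default_cohort):
    table, truth = default_cohort
    std, params, _ = preprocess_table(table)
    split = split_dataset(std, seed=11)
    parts = {name: std.subset_samples(split.mask(name)) for name in ("train", "validation", "test")}
    return {"std": std, "params": params, "split": split, "truth": truth, **parts}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
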