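import numpy as np
import pytest
from hypothesis import settings

from difnet.grm import DIFSpec, apply_uniform_dif, sample_item_bank, simulate_responses

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_dataset(seed=0, n_ref=50, n_focal=50, n_items=5, n_categories=5, dif=0.0):
    """Two-group GRM dataset under the study's generating conditions."""
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    bank = sample_item_bank(n_items, n_categories, rng)
    focal = apply_uniform_dif(bank, DIFSpec(1, dif)) if dif > 0 else bank
    return simulate_responses(bank, focal, n_ref, n_focal, rng)


@pytest.fixture(scope="session")
def null_dataset():
    """N=100, I=5, no DIF."""
    return make_dataset(seed=101)


@pytest.fixture(scope="session")
def dif_dataset():
    """N=100, I=5, uniform DIF 0.8 on item 1."""
    return make_dataset(seed=102, dif=0.8)
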