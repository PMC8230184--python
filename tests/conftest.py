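import numpy as np
import pandas as pd
import pytest

import refback as rb


@pytest.fixture(scope="session")
def small_dataset():
    """Four synthetic subjects, 256 trials each, default planted effects."""
    group = rb.default_group()
    return rb.simulate_dataset(group, n_subjects=4, n_trials=256, n_blocks=4, seed=101)


@pytest.fixture(scope="session")
def cleaned_trials(small_dataset):
    trials, _ = rb.clean(small_dataset.trials)
    return trials


@pytest.fixture(scope="session")
def hier_fit():
    """Hierarchical drift-fixed fit of 6 subjects x 256 trials (shared)."""
    group = rb.default_group(rb.build_model_spec("drift-fixed"))
    ds = rb.simulate_dataset(group, n_subjects=6, n_trials=256, n_blocks=4, seed=77)
    trials, _ = rb.clean(ds.trials)
    model = rb.HierarchicalReferenceBackDDM(trials, variant="drift-fixed")
    cfg = rb.SamplerConfig(n_chains=28, n_burn=250, n_keep=200)
    return model, model.fit(config=cfg, seed=19), ds


@pytest.fixture(scope="session")
def tiny_fit():
    """A quick drift-fixed fit of one 256-trial subject (shared across tests)."""
    group = rb.default_group(rb.build_model_spec("drift-fixed"))
    ds = rb.simulate_dataset(group, n_subjects=1, n_trials=256, n_blocks=4, seed=55)
    trials, _ = rb.clean(ds.trials)
    model = rb.ReferenceBackDDM(trials, variant="drift-fixed")
    cfg = rb.SamplerConfig(n_chains=28, n_burn=150, n_keep=150)
    return model, model.fit(config=cfg, seed=7), ds
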