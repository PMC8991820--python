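import numpy as np
import pytest

import ceamiss as cm


@pytest.fixture(scope="session")
def default_config():
    """The emulated study conditions at their defaults."""
    return cm.TrialConfig(seed=20230101)


@pytest.fixture(scope="session")
def complete_trial(default_config):
    return cm.generate_complete(default_config)


@pytest.fixture(scope="session")
def default_trial(default_config, complete_trial):
    return cm.impose_missingness(complete_trial, default_config)


@pytest.fixture(scope="session")
def small_trial():
    """Smaller trial for the cheaper unit checks."""
    cfg = cm.TrialConfig(n_patients=150, seed=99)
    return cfg, cm.make_trial(cfg)


def noiseless_config(**kw):
    """All effects and noise off: outcomes equal their period/week means."""
    defaults = dict(
        n_patients=40,
        cost_effects=np.zeros(16),
        eq5d_effects={w: 0.0 for w in (6, 26, 52, 104, 156, 208, 260)},
        covariate_effects=cm.CovariateEffects(
            cost={}, cost_site=(0.0,) * 6, eq5d={}, eq5d_site=(0.0,) * 6),
        subject_sd_cost=0.0, subject_sd_eq5d=0.0,
        resid_sd_cost=0.0, resid_sd_eq5d=0.0,
        seed=1,
    )
    defaults.update(kw)
    return cm.TrialConfig(**defaults)
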