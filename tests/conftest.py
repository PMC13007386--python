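import numpy as np
import pytest

import fusionrsa as f


@pytest.fixture(scope="session")
def small_trials():
    """6 blocks x 32 balanced trials, perfect behaviour (deterministic labels)."""
    return f.generate_trial_sequence(
        n_blocks=6,
        n_trials_per_block=32,
        behaviour_params={"accuracy_rate": 1.0, "omission_rate": 0.0},
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_trials():
    """6 blocks x 32 trials with the default (paper-level) behaviour rates."""
    return f.generate_trial_sequence(n_blocks=6, n_trials_per_block=32, seed=11)


@pytest.fixture(scope="session")
def strong_betas(small_trials):
    """One ROI with a very strong planted hemifield effect (scheme 'across')."""
    return f.simulate_fmri_betas(
        small_trials,
        [{"roi": "IPS", "n_voxels": 30}],
        [f.EffectSpec("across", 10.0, target="IPS")],
        scheme="across",
        seed=3,
    )["IPS"]


@pytest.fixture(scope="session")
def null_betas(small_trials):
    """Zero-signal betas, same geometry."""
    return f.simulate_fmri_betas(
        small_trials, [{"roi": "IPS", "n_voxels": 30}], [], scheme="across", seed=3
    )["IPS"]


@pytest.fixture(scope="session")
def across_labelling():
    return {"left-r1": 0, "left-r2": 0, "right-r1": 1, "right-r2": 1}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
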