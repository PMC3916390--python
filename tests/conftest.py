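import numpy as np
import pandas as pd
import pytest

from erpoverlap.containers import EpochSet, SimulationConfig
from erpoverlap import synthetic_data as synth


@pytest.fixture(scope="session")
def stimulus_pairs():
    return synth.generate_stimulus_list(seed=1)


@pytest.fixture(scope="session")
def speeded_trials(stimulus_pairs):
    profiles = synth.default_profiles(10, "speeded", seed=1)
    return synth.simulate_behavior(stimulus_pairs, profiles, "speeded", seed=1)


@pytest.fixture(scope="session")
def delayed_trials(stimulus_pairs):
    profiles = synth.default_profiles(10, "delayed", seed=1)
    return synth.simulate_behavior(stimulus_pairs, profiles, "delayed", seed=1,
                                   trial_id_start=8000)


def make_trial_table(n, rt, subject_id=0, as_score=10, trial_id_start=0,
                     condition="speeded"):
    """Minimal single-subject trial table for constructed simulations."""
    rt = np.broadcast_to(np.asarray(rt, dtype=float), (n,))
    return pd.DataFrame({
        "trial_id": trial_id_start + np.arange(n),
        "subject_id": subject_id,
        "pair_id": np.arange(n),
        "as_score": np.broadcast_to(np.asarray(as_score), (n,)),
        "condition": condition,
        "rt_s": rt,
        "response": 1.0,
        "missed": False,
    })


def make_bump_epochs(true_latencies, sfreq=256.0, t0=None, n_samples=410,
                     width=0.12, amplitude=1.0, noise=None, channel="Pz"):
    """Constructed single-channel epochs: one Gaussian bump per trial."""
    true_latencies = np.asarray(true_latencies, dtype=float)
    if t0 is None:
        t0 = -26 / sfreq
    times = t0 + np.arange(n_samples) / sfreq
    data = amplitude * np.exp(
        -0.5 * ((times[None, :] - true_latencies[:, None]) / width) ** 2)
    if noise is not None:
        data = data + noise
    return EpochSet(
        data=data[:, None, :], t0=t0, sfreq=sfreq, lock="target",
        channel_names=(channel,),
        metadata=pd.DataFrame({"trial_id": np.arange(len(true_latencies))}),
    )


@pytest.fixture
def bump_epochs_factory():
    return make_bump_epochs


@pytest.fixture
def trial_table_factory():
    return make_trial_table


@pytest.fixture
def quiet_config():
    """Noise- and artifact-free simulation config (components only)."""
    def _make(condition="speeded", **kw):
        kw.setdefault("pink_rms", 0.0)
        kw.setdefault("alpha_rms", 0.0)
        kw.setdefault("blink_rate", 0.0)
        return SimulationConfig(n_subjects=1, n_pairs=64, condition=condition,
                                **kw)
    return _make
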