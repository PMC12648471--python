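import numpy as np
import pytest

from insdyn.core_data import StimulusTrain, TrialRecording, TrialSet
from insdyn.synthetic_data import GeneratorConfig, gen_lfp_trialset


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(
        seed=42,
        n_trials_per_condition=6,
        energy_grid_mj=(0.5, 2.0, 4.0),
        isi_grid_ms=(5.0,),
        n_animals=1,
        n_electrodes_per_animal=2,
    )


@pytest.fixture(scope="session")
def small_trialset(small_cfg):
    return gen_lfp_trialset(small_cfg)


def make_trial(
    lfp=None,
    rate=1526.0,
    energy=2.0,
    isi=5.0,
    spikes=None,
    trial=0,
    electrode=0,
    animal=0,
    prestim=0.2,
    trial_length=1.0,
):
    stim = StimulusTrain(
        energy_mj=energy, isi_ms=isi, prestim_s=prestim, trial_length_s=trial_length
    )
    n = round(trial_length * rate)
    if lfp is None:
        lfp = np.zeros(n)
    return TrialRecording(
        lfp=lfp,
        sampling_rate=rate,
        spikes=spikes or {},
        stimulus=stim,
        animal=animal,
        electrode=electrode,
        trial=trial,
    )


@pytest.fixture
def zero_trial():
    return make_trial()


@pytest.fixture(scope="session")
def two_trial_set():
    rng = np.random.default_rng(0)
    trials = [
        make_trial(lfp=rng.standard_normal(1526), trial=i, spikes={0: np.sort(rng.uniform(0, 1, 7))})
        for i in range(2)
    ]
    return TrialSet(trials=trials, manifest={"subjects": 1})
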