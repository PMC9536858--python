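import numpy as np
import pytest

from gustnet.core import SpikeTrain, StimulusPanel, TasteTrial
from gustnet.responses import NetResponse, ResponseProfile


@pytest.fixture
def panel_a() -> StimulusPanel:
    return StimulusPanel.set_a()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trials(counts_by_trial, stimulus="SUC", light="control", prestim=10.0, stim=10.0, gap=5.0):
    """Trials laid end to end; counts_by_trial is [(stim_count, pre_count), ...]."""
    trials, spikes, t = [], [], gap
    for i, (sc, pc) in enumerate(counts_by_trial):
        trials.append(
            TasteTrial(
                trial_id=f"t{i}",
                stimulus=stimulus,
                stimulus_onset=t + prestim,
                stimulus_duration=stim,
                prestim_onset=t,
                prestim_duration=prestim,
                light_condition=light,
            )
        )
        spikes.extend(np.linspace(t, t + prestim, pc, endpoint=False))
        spikes.extend(np.linspace(t + prestim, t + prestim + stim, sc, endpoint=False))
        t += prestim + stim + gap
    return trials, np.sort(np.asarray(spikes))


def make_profile(unit_id, panel, control, light=None, n_sig=None):
    """ResponseProfile from net-response vectors in panel order."""
    prof = ResponseProfile(unit_id=unit_id, panel=panel)
    conds = {"control": control}
    if light is not None:
        conds["light_br"] = light
    for cond, vec in conds.items():
        for s, net in zip(panel.labels, vec):
            prof.responses[(s, cond)] = NetResponse(
                unit_id=unit_id,
                stimulus=s,
                light_condition=cond,
                net=float(net),
                n_trials=2,
                window_s=10.0,
                baseline_mean=10.0,
                baseline_sd=1.0,
                significant=bool(net >= 10.0),
            )
    return prof
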