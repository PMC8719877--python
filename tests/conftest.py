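import numpy as np
import pytest

from adipostat.synthetic import NightSimConfig, simulate_night


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_bout_minutes(n=600, normo=0.60, torpid=0.06, entry=120, entry_ramp=30,
                      arousal=450, arousal_ramp=20, peak=0.90, noise=0.0,
                      seed=0):
    """Hand-built minute V̇O2 bout with known boundaries and truth labels."""
    y = np.full(n, normo)
    y[entry:entry + entry_ramp] = np.linspace(normo, torpid, entry_ramp)
    y[entry + entry_ramp:arousal] = torpid
    y[arousal:arousal + arousal_ramp] = np.linspace(torpid, peak, arousal_ramp)
    y[arousal + arousal_ramp:] = peak
    labels = np.array(["normo-pre"] * n, dtype=object)
    labels[entry:entry + entry_ramp] = "entry"
    labels[entry + entry_ramp:arousal] = "torpor"
    labels[arousal:arousal + arousal_ramp] = "arousal"
    labels[arousal + arousal_ramp:] = "normo-post"
    if noise:
        y = y + np.random.default_rng(seed).normal(0.0, noise, n)
    return y, labels


@pytest.fixture()
def standard_bout():
    """The canonical synthetic bout: 2 h normothermic at 0.60, 30-min entry
    to 0.06, torpid to minute 450, 20-min arousal to 0.90, then plateau."""
    return make_bout_minutes(noise=0.01, seed=7)


@pytest.fixture()
def torpid_night():
    """A simulated adipostat night that enters torpor (full truth attached)."""
    gas, comp, truth = simulate_night(NightSimConfig(seed=11), emit_gas=False)
    assert truth["torpid"]
    return comp, truth
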