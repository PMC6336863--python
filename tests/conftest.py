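import numpy as np
import pytest

from neurodish import synthetic as syn


@pytest.fixture(scope="session")
def burst_well():
    """600 s, 8-electrode well with full-participation network bursts."""
    profile = syn.SimulationProfile(
        n_electrodes=8, duration_s=600.0, base_rate_hz=1.0,
        burst_rate_per_min=6.0, burst_participation=1.0,
        synchrony_coupling=0.9, seed=11)
    spikes, bursts = syn.simulate_spike_trains(profile)
    return profile, spikes, bursts


@pytest.fixture(scope="session")
def straight_neurite_morph():
    """Soma at origin plus a straight radial neurite of length 95 um."""
    from neurodish.morphometry import NeuronMorphology

    rows = [(1, 1, 0.0, 0.0, 0.0, 9.0, -1)]
    parent = 1
    for k, x in enumerate(np.arange(5.0, 100.0, 5.0), start=2):
        rows.append((k, 3, float(x), 0.0, 0.0, 0.5, parent))
        parent = k
    return NeuronMorphology.from_rows(rows)


@pytest.fixture(scope="session")
def y_branch_morph():
    """Straight trunk to 25 um, then two branches whose tips sit 45 um out."""
    from neurodish.morphometry import NeuronMorphology

    rows = [(1, 1, 0.0, 0.0, 0.0, 9.0, -1),
            (2, 3, 25.0, 0.0, 0.0, 0.5, 1)]
    for nid, sign in [(3, 1.0), (4, -1.0)]:
        # tip at distance 45 from the soma, branching from (25, 0)
        x, y = 40.0, sign * np.sqrt(45.0 ** 2 - 40.0 ** 2)
        rows.append((nid, 3, x, y, 0.0, 0.5, 2))
    return NeuronMorphology.from_rows(rows)
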