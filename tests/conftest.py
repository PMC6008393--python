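"""Shared fixtures: small synthetic studies cached for the whole session."""

import numpy as np
import pytest

from hypersync.config import CouplingSpec, EnvelopeCouplingSpec, SimConfig
from hypersync.synth import generate_group, simulate_study

#: engine options used by study-scale tests (validated against the exact
#: path in test_ins_fast_path_matches_exact)
FAST = dict(single=True, decimate=5)


@pytest.fixture(scope="session")
def small_cfg():
    """Four channels, short sessions: cheap but structurally complete."""
    return SimConfig(
        n_groups=3, n_channels=4, seed=11,
        couplings=[CouplingSpec(ch_a=3, ch_b=3, strength=0.8)],
        envelope_coupling=EnvelopeCouplingSpec(
            speaker_channel=4, listener_channels=(2,), strength=0.0),
    )


@pytest.fixture(scope="session")
def small_group(small_cfg):
    rec, truth = generate_group(small_cfg, 0)
    return rec, truth


@pytest.fixture(scope="session")
def coupled_study():
    """Six full-size groups with the default LA (3,3) coupling at 0.8."""
    cfg = SimConfig(n_groups=6, seed=5)
    groups, truths = simulate_study(cfg)
    return cfg, groups, truths


@pytest.fixture(scope="session")
def null_study():
    """Six full-size groups with no coupling anywhere."""
    cfg = SimConfig(n_groups=6, seed=6, couplings=[])
    groups, truths = simulate_study(cfg)
    return cfg, groups, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
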