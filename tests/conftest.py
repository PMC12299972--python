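import numpy as np
import pytest

from ecoplate import default_eco_layout, preset_study, simulate_experiment
from ecoplate.profiling import CorrectedProfile


@pytest.fixture(scope="session")
def layout():
    return default_eco_layout()


@pytest.fixture(scope="session")
def make_profile(layout):
    """Build a CorrectedProfile from a 31-vector of utilization values."""
    substrates = layout.substrates
    guilds = np.array([layout.guild_of(s) for s in substrates])

    def _make(ni, raw=None, sample_id="s", treatment="t", time=168.0):
        ni = np.asarray(ni, dtype=float)
        return CorrectedProfile(
            sample_id=sample_id,
            treatment=treatment,
            time=time,
            substrates=substrates,
            guilds=guilds,
            ni=np.maximum(ni, 0.0),
            raw_diff=np.asarray(raw if raw is not None else ni, dtype=float),
        )

    return _make


@pytest.fixture(scope="session")
def preset_exp():
    """The packaged five-treatment study preset at its packaged seed."""
    return simulate_experiment(preset_study())
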