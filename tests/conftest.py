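import numpy as np
import pytest

from drugsense import PanelConfig, generate_panel, mean_viability_auc


@pytest.fixture(scope="session")
def default_panel():
    """One default 49-line panel shared across tests (seed fixed)."""
    return generate_panel(PanelConfig(seed=1))


@pytest.fixture(scope="session")
def default_auc(default_panel):
    return mean_viability_auc(default_panel.dose_response, check_grid=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
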