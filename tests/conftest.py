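import warnings

import pytest

from yieldpath.fixtures import read_table2_fixture
from yieldpath.pipeline import compute_plot_traits
from yieldpath.synthetic import PanelConfig, simulate_panel

# the stage-one REML legitimately hits variance boundaries on some traits of
# the small test panels; those warnings are expected there
warnings.filterwarnings("ignore", message="variance component at boundary")


@pytest.fixture(scope="session")
def small_panel():
    """120-line, 3-environment synthetic study shared across tests."""
    cfg = PanelConfig(n_lines=120, n_families=12, n_snps=400)
    snps, trial = simulate_panel(cfg, seed=3)
    return cfg, snps, trial


@pytest.fixture(scope="session")
def small_traits(small_panel):
    cfg, snps, trial = small_panel
    traits, fits = compute_plot_traits(
        trial.plots_frame(), trial.cc_frame(), trial.biomass_frame(),
        trial.weather, rue_method=cfg.layout.rue_method,
    )
    return traits, fits


@pytest.fixture(scope="session")
def table2():
    return read_table2_fixture()
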