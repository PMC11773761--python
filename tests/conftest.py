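import pytest

from hhseg.io_config import default_config
from hhseg.segmentation import run_segmentation
from hhseg.synthetic_data import SyntheticConfig, generate_population


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def strong_separation_cfg():
    """Generator settings under which planted labels should be recoverable
    with sensitivity/specificity >= 0.9 (pilot-run checked)."""
    return SyntheticConfig(
        n_households=2000,
        planted_complex_fraction=0.08,
        sector_rate_multiplier_complex=6.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def strong_population(strong_separation_cfg):
    return generate_population(strong_separation_cfg)


@pytest.fixture(scope="session")
def strong_workspace(strong_population, cfg):
    persons, conditions, contacts, truth = strong_population
    ws = run_segmentation(persons, conditions, contacts, cfg)
    ws["truth"] = truth
    return ws
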