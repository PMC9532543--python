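import pytest

from cellhammer import PMMA, WATER, ProjectileSpec, preset_config


@pytest.fixture(scope="session")
def water():
    return WATER


@pytest.fixture(scope="session")
def pmma_projectile():
    """1 cm PMMA projectile matching the 3x3 mm channel bore."""
    return ProjectileSpec(material=PMMA, length=0.01, area=9.0e-6, up=1.0)


@pytest.fixture(scope="session")
def rep_config():
    return preset_config("representative")


@pytest.fixture(scope="session")
def rep_simulation(rep_config):
    from cellhammer import run_simulation

    return run_simulation(rep_config)
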