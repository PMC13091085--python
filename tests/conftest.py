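import pytest
from hypothesis import HealthCheck, settings

from spikequant import Rank, get_preset
from spikequant.examples import worked_example_profiles

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def protocol():
    """The two-species Zymo spike-in protocol (3 and 7 copies/genome,
    100,000 cells each, 10 uL of a 100x dilution)."""
    return get_preset("zymo-spikein-control-I")


@pytest.fixture
def worked_profiles():
    """Species- and phylum-rank profiles of the worked example sample."""
    return worked_example_profiles()


@pytest.fixture
def species_profile(worked_profiles):
    return worked_profiles[Rank.SPECIES]
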