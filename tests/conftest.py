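import pytest

from plasmidcad import CampaignConfig, CampaignSimConfig, generate_design


@pytest.fixture()
def config():
    return CampaignConfig()


@pytest.fixture()
def small_design():
    """2×3×4 full-factorial design with sequences (24 circular constructs)."""
    sim = CampaignSimConfig(seed=1, fragment_length_range=(400, 900))
    return generate_design(sim)


@pytest.fixture()
def small_sim_config():
    return CampaignSimConfig(seed=1, fragment_length_range=(400, 900))
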