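import pytest

from tundraflux.synthetic import CampaignConfig, generate_site_campaign


@pytest.fixture(scope="session")
def default_campaign():
    """One default (quiet-noise) site campaign with truth."""
    return generate_site_campaign(CampaignConfig(seed=42))


@pytest.fixture(scope="session")
def field_campaign():
    """One field-realistic-noise site campaign with truth."""
    return generate_site_campaign(CampaignConfig.field_realistic(seed=42))


@pytest.fixture(scope="session")
def noiseless_campaign():
    return generate_site_campaign(CampaignConfig(seed=42, noise_sd_er=0.0, noise_sd_gpp=0.0))
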