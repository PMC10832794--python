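import numpy as np
import pytest

from canopygpp import PipelineConfig, run_pipeline
from canopygpp.synth import CampaignTruth


@pytest.fixture(scope="session")
def truth():
    return CampaignTruth(seed=1)


@pytest.fixture(scope="session")
def campaign_run(tmp_path_factory):
    """One full synthetic-campaign pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("campaign")
    cfg = PipelineConfig(seed=1, out_dir=str(out))
    manifest = run_pipeline(cfg)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
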