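import dataclasses

import pytest

from diinpx.synthetic import TINY, SyntheticConfig, emit_bundle, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    return dataclasses.replace(TINY, rng_seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    """(composition, records, reference, npx, truth) at unit-test scale."""
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config, tmp_path_factory):
    """The tiny cohort written out as the full pipeline input bundle."""
    outdir = tmp_path_factory.mktemp("bundle")
    return emit_bundle(tiny_config, outdir)
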