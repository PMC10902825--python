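import pytest

import echoclean as ec
from echoclean.pipeline import PipelineConfig, run


@pytest.fixture(scope="session")
def rulesets():
    return ec.default_rulesets()


@pytest.fixture(scope="session")
def clean_roundtrip():
    """Zero-corruption synthetic export run through the full pipeline."""
    cfg = ec.GeneratorConfig.clean(n_studies=150, seed=7)
    chunks, gt = ec.generate_export(cfg)
    result = run(PipelineConfig(dedupe_mode="keep_all"), chunks=chunks)
    return chunks, gt, result


@pytest.fixture(scope="session")
def corrupted_run():
    """Default-rate corrupted export run through the full pipeline."""
    cfg = ec.GeneratorConfig(n_studies=400, seed=11)
    chunks, gt = ec.generate_export(cfg)
    result = run(PipelineConfig(dedupe_mode="keep_all"), chunks=chunks)
    return chunks, gt, result
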