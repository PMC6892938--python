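import pytest

from sibcnv import CohortConfig, RunConfig, generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic cohort, generated once per session."""
    root = tmp_path_factory.mktemp("cohort")
    return generate_cohort(CohortConfig(), root / "bundle", seed=1)


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    """Full pipeline run over the default bundle."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig.from_bundle(bundle, out)
    return run_pipeline(cfg)
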