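import pytest

from chic2drug.pipeline import RunConfig, run_pipeline
from chic2drug.simulate import FixtureConfig, generate_fixture

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The default synthetic dataset (66 loci, all archetypes), seed-pinned."""
    outdir = tmp_path_factory.mktemp("fixture")
    generate_fixture(FixtureConfig(seed=FIXTURE_SEED), outdir)
    return outdir


@pytest.fixture(scope="session")
def ground_truth(fixture_dir):
    from chic2drug.simulate import GroundTruth

    return GroundTruth.from_json(fixture_dir / "ground_truth.json")


@pytest.fixture(scope="session")
def run_config(fixture_dir):
    return RunConfig.from_yaml(fixture_dir / "config.yaml")


@pytest.fixture(scope="session")
def pipeline_results(run_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(run_config, outdir)
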