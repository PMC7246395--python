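import pytest
from hypothesis import HealthCheck, settings

from ddradsex.pipeline import RunConfig, run_pipeline
from ddradsex.samples import Sample
from ddradsex.simdata import SimulationParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_params():
    """A fast study design: small background, error-free, 2 planted fragments."""
    return SimulationParams(
        background_length=30_000,
        n_chromosomes=2,
        n_male_specific_fragments=2,
        mean_depth=25.0,
        error_rate=0.0,
        seed=7,
    )


@pytest.fixture
def small_samples():
    barcodes = ["AACGT", "CCATG", "GGTAC", "TTGCA", "ACACA", "CTCTC", "GAGAG", "TGTGT"]
    samples = [Sample(f"M{i+1}", "M", barcodes[i]) for i in range(4)]
    samples += [Sample(f"F{i+1}", "F", barcodes[4 + i]) for i in range(4)]
    return samples


@pytest.fixture(scope="session")
def eucommia_run(tmp_path_factory):
    """One full pipeline run of the packaged 20M+20F scenario, shared read-only."""
    out = tmp_path_factory.mktemp("eucommia") / "run"
    config = RunConfig(out_dir=str(out), seed=1, scenario="eucommia")
    manifest = run_pipeline(config)
    return out, manifest
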