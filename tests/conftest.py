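import pytest

from ecsubtype.cn import train_cluster4_model
from ecsubtype.pipeline import classify_cohort
from ecsubtype.simulate import (
    CohortSpec, default_fixture_spec, generate_cn_training, generate_cohort,
    write_bundle,
)

FIXTURE_SEED = 11
TRAIN_SEED = 17


def subset_spec(n: int, seed: int = FIXTURE_SEED) -> CohortSpec:
    """First n samples of the packaged fixture plan (keeps flag variety)."""
    full = default_fixture_spec(seed=seed)
    return CohortSpec(samples=full.samples[:n], survival=full.survival, seed=seed)


@pytest.fixture(scope="session")
def cn_model():
    segments, labels = generate_cn_training(seed=TRAIN_SEED)
    return train_cluster4_model(segments, labels)


@pytest.fixture(scope="session")
def fixture_bundle():
    return generate_cohort(default_fixture_spec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def fixture_dir(fixture_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture_cohort")
    write_bundle(fixture_bundle, d)
    return d


@pytest.fixture(scope="session")
def fixture_run(fixture_dir, cn_model):
    """(calls, per-sample table, summary) for the packaged 108-sample fixture."""
    return classify_cohort(fixture_dir, cn_model)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohort(subset_spec(12))


@pytest.fixture(scope="session")
def small_dir(small_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("small_cohort")
    write_bundle(small_bundle, d)
    return d
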