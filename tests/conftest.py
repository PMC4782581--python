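import numpy as np
import pytest

from stepscreen import SubjectRecord, generate, reconstruct_fixture, study_preset


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 125-subject reconstructed validation cohort."""
    return reconstruct_fixture()


@pytest.fixture(scope="session")
def calibrated_cohort_10k():
    """One seeded 10,000-subject cohort under the study preset."""
    return generate(study_preset(n=10_000), seed=20260929)


@pytest.fixture(scope="session")
def calibrated_cohort_100k():
    """Large seeded cohort for rank properties whose population gaps (~0.02)
    need more resolving power than n=10,000 provides."""
    return generate(study_preset(n=100_000), seed=20260929)


def random_records(rng: np.random.Generator, n: int) -> list[SubjectRecord]:
    """Unstructured random cohort for property tests (no study calibration)."""
    items = rng.integers(0, 4, size=(n, 9))
    heart_mind = rng.integers(0, 2, size=n)
    impairment = rng.integers(0, 2, size=n) & heart_mind
    return [
        SubjectRecord(
            id=f"R{i:04d}",
            items=tuple(int(v) for v in items[i]),
            total=int(items[i].sum()),
            heart_mind=int(heart_mind[i]),
            brain_mind=int(rng.integers(0, 2)),
            impairment=int(impairment[i]),
            reference=int(rng.integers(0, 2)),
        )
        for i in range(n)
    ]


@pytest.fixture
def record_factory():
    return random_records
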