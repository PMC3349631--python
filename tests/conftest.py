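import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cutcalib import (
    AlignedSample,
    SimConfig,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size simulated cohort (28 participants, six activities)."""
    samples, ground_truth, report = generate_cohort(SimConfig(seed=20260929))
    return samples, ground_truth, report


@pytest.fixture(scope="session")
def small_cohort():
    """A three-participant cohort for cheap pipeline tests."""
    samples, ground_truth, report = generate_cohort(
        SimConfig(n_participants=3, seed=7)
    )
    return samples, ground_truth, report


def make_samples(cpm_codes, role="cross_validation"):
    """Build aligned samples from (cpm, code) pairs on a 10-s grid."""
    return [
        AlignedSample(
            participant_id="P01",
            activity="free_choice",
            role=role,
            interval_start=10.0 * i,
            count_10s=cpm / 6.0,
            cpm=float(cpm),
            code=int(code),
        )
        for i, (cpm, code) in enumerate(cpm_codes)
    ]


@pytest.fixture
def six_sample_fixture():
    """The hand-checkable 6-interval cross-validation fixture.

    Against the moderate rule (codes 4-5 positive, cpm > 2160):
    tp=2 (2500, 5000), fn=1 (2000), fp=0, tn=3 (100, 300, 800).
    """
    return make_samples(
        [(100, 1), (300, 2), (800, 3), (2500, 4), (5000, 5), (2000, 4)]
    )


def random_two_class(rng, n_max=30):
    """Random small two-class instance with ties likely (integer values)."""
    n = int(rng.integers(2, n_max + 1))
    n_pos = int(rng.integers(1, n))
    values = rng.integers(0, 12, size=n).astype(float)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1
    return values, labels
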