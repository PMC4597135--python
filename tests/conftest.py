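import numpy as np
import pytest

from selfprior import SubjectParams, simulate_subject


def make_params(**overrides) -> SubjectParams:
    base = dict(
        subject_id="S01",
        group="patient",
        sigma_performance=30.0,
        mu_performance=-10.0,
        sigma_prior=15.0,
        sigma_evidence=25.0,
        shift_evidence=-20.0,
        skip_prob=0.0,
        est_time_median=1.0,
        est_time_sigma_log=0.25,
    )
    base.update(overrides)
    return SubjectParams(**base)


def error_pairs(params: SubjectParams, n: int, seed: int):
    """Target-centred (performance_error, estimation_error) arrays."""
    recs = simulate_subject(params, n, seed, trials_per_block=max(n, 1))
    perf = np.array([r.performance_error for r in recs if not r.skipped])
    est = np.array([r.estimation_error for r in recs if not r.skipped])
    return perf, est


@pytest.fixture
def default_params() -> SubjectParams:
    return make_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
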