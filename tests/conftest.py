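import pytest
from hypothesis import HealthCheck, settings

from fmtrack import SimParams, SubjectRecord, simulate_cohort

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _dfmt_subject(i: int, grades: dict) -> SubjectRecord:
    return SubjectRecord(
        subject_id=f"d{i:02d}",
        arm="DFMT",
        donor_id="DA" if i <= 4 else "DB",
        grade_by_visit=grades,
    )


def _pfmt_subject(i: int, grades: dict) -> SubjectRecord:
    return SubjectRecord(subject_id=f"p{i:02d}", arm="PFMT", grade_by_visit=grades)


@pytest.fixture(scope="session")
def trial_subjects():
    """Cohort whose per-visit grades reproduce the trial's printed counts.

    D-FMT: resolution 10/9/7/3 and <=G1 10/10/10/8 at wk1/2/4/8;
    P-FMT: resolution 3/0/0/0 and <=G1 3/2/2/1.
    """
    subjects = []
    for i in range(1, 11):
        grades = {
            "baseline": 3 if i == 1 else 2,
            "wk1": 0,
            "wk2": 0 if i <= 9 else 1,
            "wk4": 0 if i <= 7 else 1,
            "wk8": 0 if i <= 3 else (1 if i <= 8 else 2),
        }
        subjects.append(_dfmt_subject(i, grades))
    for i in range(1, 11):
        grades = {
            "baseline": 2,
            "wk1": 0 if i <= 3 else 2,
            "wk2": 1 if i <= 2 else 2,
            "wk4": 1 if i <= 2 else 2,
            "wk8": 1 if i <= 1 else 2,
        }
        subjects.append(_pfmt_subject(i, grades))
    return subjects


@pytest.fixture(scope="session")
def small_cohort():
    """Fully strain-profiled 30-species cohort for exact-recovery checks."""
    return simulate_cohort(
        SimParams(n_species=30, seed=11, strain_profiling_prob=1.0)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter cohort (incomplete strain profiling)."""
    return simulate_cohort(SimParams(seed=7))
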