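"""Trial endpoint derivation and exact tests for CTC-graded diarrhoea.

The trial design this module serves is a two-arm randomised comparison of
donor faecal microbiota transplantation (D-FMT) against placebo FMT (P-FMT)
in patients with tyrosine-kinase-inhibitor-induced diarrhoea.  Severity is
recorded on the NCI Common Terminology Criteria (CTC) v4.0 ordinal scale
(grade 0-4), eligibility requires grade 2-3 at baseline, and efficacy is
summarised per follow-up visit as two binary endpoints:

* ``resolution`` - diarrhoea grade 0 at the visit;
* ``le_G1``      - diarrhoea grade 1 or lower at the visit.

Each endpoint at each visit yields a 2x2 success/failure table by arm,
tested with the two-sided Fisher exact test; secondary endpoints are
Bonferroni-adjusted.  Missing follow-up grades count as failures
(intention-to-treat convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _sps

VISITS = ("baseline", "wk1", "wk2", "wk4", "wk8")
FOLLOWUP_VISITS = ("wk1", "wk2", "wk4", "wk8")
ARMS = ("DFMT", "PFMT")
ENDPOINTS = ("resolution", "le_G1")

#: Default Bonferroni multiplicity: the seven secondary outcomes
#: (resolution at wk1/wk2/wk8 plus <=G1 at all four follow-up visits);
#: the primary outcome (resolution at wk4) is reported unadjusted.
DEFAULT_BONFERRONI_M = 7


@dataclass
class SubjectRecord:
    """One trial participant with per-visit CTC diarrhoea grades.

    ``grade_by_visit`` maps visit labels (:data:`VISITS`) to grades 0-4;
    ``None`` marks an explicitly missing follow-up assessment.  Baseline
    grade must be 2 or 3 (trial eligibility).  ``donor_id`` is required
    for the DFMT arm and must be absent for PFMT.
    """

    subject_id: str
    arm: str
    grade_by_visit: dict
    donor_id: Optional[str] = None
    sex: Optional[str] = None
    age: Optional[int] = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.arm == "DFMT" and not self.donor_id:
            raise ValueError(f"subject {self.subject_id}: DFMT arm requires donor_id")
        if self.arm == "PFMT" and self.donor_id:
            raise ValueError(f"subject {self.subject_id}: PFMT arm must not carry donor_id")
        for visit, grade in self.grade_by_visit.items():
            if visit not in VISITS:
                raise ValueError(f"unknown visit label {visit!r}")
            if grade is not None and grade not in (0, 1, 2, 3, 4):
                raise ValueError(f"invalid CTC grade {grade!r} at {visit}")
        baseline = self.grade_by_visit.get("baseline")
        if baseline is not None and baseline not in (2, 3):
            raise ValueError(
                f"subject {self.subject_id}: baseline grade {baseline} outside "
                "eligibility range {2, 3}"
            )
        if self.age is not None and self.age < 18:
            raise ValueError(f"subject {self.subject_id}: age {self.age} below 18")

    def grade_at(self, visit: str) -> Optional[int]:
        if visit not in VISITS:
            raise ValueError(f"unknown visit label {visit!r}")
        return self.grade_by_visit.get(visit)


@dataclass
class EndpointTable:
    """2x2 success/failure counts for one endpoint at one visit.

    ``counts`` is ``[[dfmt_success, dfmt_failure], [pfmt_success,
    pfmt_failure]]``; row sums equal arm sizes.
    """

    visit: str
    endpoint: str
    counts: list

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise ValueError("counts must be a non-negative 2x2 table")
        self.counts = arr.astype(int).tolist()

    @property
    def arm_sizes(self) -> tuple:
        return tuple(int(sum(row)) for row in self.counts)


@dataclass
class TestResult:
    """A raw p-value with its multiplicity adjustment."""

    p_raw: float
    p_adjusted: float
    m: int
    method: str = "fisher_exact_two_sided"


def grade_from_symptoms(
    stool_increase_per_day: int,
    nocturnal_stools: bool = False,
    incontinence_or_parenteral: bool = False,
    intensive_care: bool = False,
) -> int:
    """CTC v4.0 diarrhoea grade from symptom counts and clinical flags.

    Grades (evaluated from most to least severe; first criterion met wins):
    4 = physiologic consequences requiring intensive care; 3 = increase of
    >=7 stools/day over pre-treatment, or incontinence, or need for
    parenteral support; 2 = increase of 4-6 stools/day, or nocturnal
    stools; 1 = increase of <4 stools/day (but at least one); 0 = none.
    """
    if stool_increase_per_day < 0:
        raise ValueError("stool increase must be non-negative")
    if intensive_care:
        return 4
    if stool_increase_per_day >= 7 or incontinence_or_parenteral:
        return 3
    if 4 <= stool_increase_per_day <= 6 or nocturnal_stools:
        return 2
    if stool_increase_per_day >= 1:
        return 1
    return 0


def _endpoint_success(grade: Optional[int], endpoint: str) -> bool:
    # missing grade counts as failure (intention-to-treat)
    if grade is None:
        return False
    if endpoint == "resolution":
        return grade == 0
    if endpoint == "le_G1":
        return grade <= 1
    raise ValueError(f"unknown endpoint {endpoint!r}")


def derive_endpoint_tables(
    subjects: Sequence[SubjectRecord], visit: str
) -> tuple:
    """Build (resolution, le_G1) :class:`EndpointTable` pairs for a visit.

    Successes partition each arm; a missing grade is a failure.
    """
    if not subjects:
        raise ValueError("empty cohort")
    if visit not in FOLLOWUP_VISITS:
        raise ValueError(f"unknown follow-up visit {visit!r}")
    tables = []
    for endpoint in ENDPOINTS:
        counts = []
        for arm in ARMS:
            in_arm = [s for s in subjects if s.arm == arm]
            success = sum(
                _endpoint_success(s.grade_at(visit), endpoint) for s in in_arm
            )
            counts.append([success, len(in_arm) - success])
        tables.append(EndpointTable(visit=visit, endpoint=endpoint, counts=counts))
    return tuple(tables)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (minimum-likelihood rule).

    The p-value sums the hypergeometric point probabilities of every table
    with the observed margins whose point probability does not exceed that
    of the observed table.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    return float(_sps.fisher_exact(arr, alternative="two-sided")[1])


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni adjustment: ``min(1, m * p_raw)``."""
    if not (0 < p_raw <= 1):
        raise ValueError("p_raw must be in (0, 1]")
    if m < 1:
        raise ValueError("multiplicity m must be >= 1")
    return min(1.0, m * p_raw)


def sample_size_two_proportions(
    p1: float, p2: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Per-group n for a two-sided two-proportion comparison.

    Normal-approximation formula with pooled variance under H0::

        n = ((z_{a/2} sqrt(2 pbar qbar) + z_pow sqrt(p1 q1 + p2 q2)) / (p1 - p2))^2

    rounded up to the next integer.  Requires ``0 < p2 < p1 < 1``.
    """
    if not (0 < p2 < p1 < 1):
        raise ValueError("require 0 < p2 < p1 < 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = _sps.norm.isf(alpha / 2.0)
    z_pow = _sps.norm.ppf(power)
    pbar = (p1 + p2) / 2.0
    num = z_a * math.sqrt(2.0 * pbar * (1.0 - pbar)) + z_pow * math.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    return int(math.ceil((num / (p1 - p2)) ** 2))


def format_p_value(p: float) -> str:
    """Printed-style p rounding: one significant figure below 0.01,
    two decimals otherwise, bare "1" at the top."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if p < 0.01:
        return f"{p:.1g}"
    if p > 0.995:
        return "1"
    return f"{p:.2f}"


@dataclass
class EndpointResult:
    """One row of the endpoint report."""

    visit: str
    endpoint: str
    table: EndpointTable
    test: TestResult
    is_primary: bool = False


def endpoint_analysis(
    subjects: Sequence[SubjectRecord],
    m: int = DEFAULT_BONFERRONI_M,
    primary: tuple = ("wk4", "resolution"),
    visits: Iterable[str] = FOLLOWUP_VISITS,
) -> list:
    """Full endpoint analysis over follow-up visits.

    Fisher two-sided p per endpoint table; the primary (visit, endpoint)
    is reported unadjusted (m = 1), all others Bonferroni-adjusted by
    ``m``.  ``m`` is exposed because the trial report does not state the
    multiplicity it used; 7 (the number of secondary outcomes) is the
    default and 6 is the other defensible reading.
    """
    results = []
    for visit in visits:
        for table in derive_endpoint_tables(subjects, visit):
            p_raw = fisher_exact_two_sided(table.counts)
            is_primary = (visit, table.endpoint) == tuple(primary)
            mult = 1 if is_primary else m
            test = TestResult(
                p_raw=p_raw, p_adjusted=bonferroni(p_raw, mult), m=mult
            )
            results.append(
                EndpointResult(
                    visit=visit,
                    endpoint=table.endpoint,
                    table=table,
                    test=test,
                    is_primary=is_primary,
                )
            )
    return results
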