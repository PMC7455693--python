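"""Community-level donor-recipient convergence metrics.

Two pairwise metrics quantify how much a recipient's gut community moved
toward the donor's after FMT:

* Bray-Curtis dissimilarity on species-level relative abundances,
  ``1 - 2 * sum_s min(a_s, b_s) / (sum_s a_s + sum_s b_s)`` - 0 for
  identical communities, 1 for disjoint ones.  Bray-Curtis is a
  semimetric: bounded, symmetric, zero exactly on identical profiles,
  but the triangle inequality is not guaranteed.
* Shared-species fraction: Jaccard overlap of the detected species sets,
  ``|A & B| / |A | B|`` (a ``min-set`` denominator is available for
  sensitivity analysis).

Pairs of samples are grouped into labelled comparison categories (donor
vs its recipients at each visit, within-patient pre-vs-post, donor vs
untreated controls, control vs control) defined as configuration data so
the panel layout can be changed without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import braycurtis as _braycurtis

from .metadata import CohortMetadata

ABUNDANCE_SUM_TARGET = 100.0
ABUNDANCE_SUM_TOL = 0.5


@dataclass
class AbundanceProfile:
    """Species -> relative abundance (percent) for one sample."""

    sample_id: str
    abundances: Dict[str, float]
    subject_id: Optional[str] = None
    time_point: Optional[str] = None

    def __post_init__(self) -> None:
        for sp, v in self.abundances.items():
            if v < 0:
                raise ValueError(
                    f"negative abundance {v} for {sp} in {self.sample_id}"
                )

    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def sum_in_tolerance(self) -> bool:
        return abs(self.total() - ABUNDANCE_SUM_TARGET) <= ABUNDANCE_SUM_TOL

    def detected(self, detection_min: float = 0.0) -> set:
        return {s for s, v in self.abundances.items() if v > detection_min}


def _union_vectors(a: AbundanceProfile, b: AbundanceProfile):
    species = sorted(set(a.abundances) | set(b.abundances))
    va = np.array([a.abundances.get(s, 0.0) for s in species])
    vb = np.array([b.abundances.get(s, 0.0) for s in species])
    return va, vb


def bray_curtis(a: AbundanceProfile, b: AbundanceProfile) -> float:
    """Bray-Curtis dissimilarity over the union of species.

    Species absent from one profile are imputed as zero; profiles are not
    renormalised after taking the union.
    """
    va, vb = _union_vectors(a, b)
    if va.sum() == 0 and vb.sum() == 0:
        raise ValueError("both profiles are all-zero")
    return float(_braycurtis(va, vb))


def shared_species_fraction(
    a: AbundanceProfile,
    b: AbundanceProfile,
    detection_min: float = 0.0,
    denominator: str = "union",
) -> float:
    """Fraction of species shared between two samples.

    A species is detected when its abundance strictly exceeds
    ``detection_min`` (default 0: any positive abundance).  The default
    denominator is the union of the detected sets (Jaccard, symmetric);
    ``min-set`` divides by the smaller detected set instead.
    """
    if detection_min < 0:
        raise ValueError("detection_min must be >= 0")
    da, db = a.detected(detection_min), b.detected(detection_min)
    if not da and not db:
        raise ValueError("no species detected in either sample")
    inter = len(da & db)
    if denominator == "union":
        return inter / len(da | db)
    if denominator == "min-set":
        smaller = min(len(da), len(db))
        if smaller == 0:
            return 0.0
        return inter / smaller
    raise ValueError(f"unknown denominator rule {denominator!r}")


@dataclass(frozen=True)
class CategorySpec:
    """One comparison category: which sample pairs it collects.

    ``role_a``/``role_b`` are time-point labels (or tuples of them);
    ``constraint`` is one of:

    * ``cross`` - every unordered cross pair;
    * ``same_donor_link`` - pairs a donor sample with samples of patients
      assigned to that donor;
    * ``same_patient`` - pairs samples of the same subject.
    """

    label: str
    role_a: Union[str, Tuple[str, ...]]
    role_b: Union[str, Tuple[str, ...]]
    constraint: str = "cross"


#: Default seven-category panel: donor distance to untreated controls and
#: to its recipients before and after FMT, within-patient shift, and the
#: control-control background.
DEFAULT_CATEGORY_SCHEME = (
    CategorySpec("donor_vs_control_pre", "donor", "control_pre", "cross"),
    CategorySpec("donor_vs_pre", "donor", "pre", "same_donor_link"),
    CategorySpec("donor_vs_wk1", "donor", "wk1", "same_donor_link"),
    CategorySpec("donor_vs_wk2", "donor", "wk2", "same_donor_link"),
    CategorySpec("donor_vs_wk4", "donor", "wk4", "same_donor_link"),
    CategorySpec("pre_vs_post", "pre", ("wk1", "wk2", "wk4"), "same_patient"),
    CategorySpec("control_vs_control", "control_pre", "control_pre", "cross"),
)


@dataclass
class PairDistanceRecord:
    """Metrics for one sample pair in one comparison category."""

    sample_a: str
    sample_b: str
    category: str
    bray_curtis: float
    shared_species_fraction: float


def category_pairs(
    metadata: CohortMetadata, scheme: Sequence[CategorySpec] = DEFAULT_CATEGORY_SCHEME
) -> List[Tuple[str, str, str]]:
    """Enumerate (sample_a, sample_b, category) triples for a scheme.

    Each unordered pair is assigned to at most one category, the first in
    scheme order that matches (the default scheme is disjoint).
    """
    seen = set()
    out: List[Tuple[str, str, str]] = []
    for spec in scheme:
        set_a = metadata.samples_at(spec.role_a)
        set_b = metadata.samples_at(spec.role_b)
        if spec.constraint == "cross":
            if set(set_a) == set(set_b):
                candidates = combinations(sorted(set_a), 2)
            else:
                candidates = product(set_a, set_b)
            pairs = [
                (a, b)
                for a, b in candidates
                if a != b
            ]
        elif spec.constraint == "same_donor_link":
            pairs = [
                (a, b)
                for a, b in product(set_a, set_b)
                if a != b and metadata.donor_of(b) == metadata.subject_of(a)
            ]
        elif spec.constraint == "same_patient":
            pairs = [
                (a, b)
                for a, b in product(set_a, set_b)
                if a != b and metadata.subject_of(a) == metadata.subject_of(b)
            ]
        else:
            raise ValueError(f"unknown constraint {spec.constraint!r}")
        for a, b in pairs:
            key = frozenset((a, b))
            if key in seen:
                continue
            seen.add(key)
            out.append((a, b, spec.label))
    return out


def build_comparison_pairs(
    profiles: Iterable[AbundanceProfile],
    metadata: CohortMetadata,
    scheme: Sequence[CategorySpec] = DEFAULT_CATEGORY_SCHEME,
    detection_min: float = 0.0,
    denominator: str = "union",
) -> List[PairDistanceRecord]:
    """Compute both pair metrics for every categorised sample pair.

    Pairs whose samples lack an abundance profile are skipped silently
    (strain-only samples); a D-FMT sample without a donor link raises at
    metadata construction time.
    """
    by_id = {p.sample_id: p for p in profiles}
    records = []
    for a, b, label in category_pairs(metadata, scheme):
        if a not in by_id or b not in by_id:
            continue
        pa, pb = by_id[a], by_id[b]
        records.append(
            PairDistanceRecord(
                sample_a=a,
                sample_b=b,
                category=label,
                bray_curtis=bray_curtis(pa, pb),
                shared_species_fraction=shared_species_fraction(
                    pa, pb, detection_min, denominator
                ),
            )
        )
    return records


def values_by_category(
    records: Sequence[PairDistanceRecord], metric: str
) -> Dict[str, List[float]]:
    """Group one metric's values by comparison category."""
    out: Dict[str, List[float]] = {}
    for r in records:
        out.setdefault(r.category, []).append(getattr(r, metric))
    return out
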