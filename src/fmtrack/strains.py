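"""Strain-identity calling and donor-strain engraftment classification.

StrainPhlAn-style strain profiling yields, per species, either a
phylogeny whose leaves are sample identifiers or (equivalently) a matrix
of pairwise normalised genetic distances (nGD).  nGD between two samples
is the patristic distance (sum of branch lengths on the leaf-to-leaf
path) divided by the total branch length of that species' tree, making
the quantity invariant to overall tree scaling.  Two samples carry the
*same strain* of a species when nGD <= 0.01 (inclusive cutoff,
configurable).

From same-strain calls this module derives:

* per-pair shared-strain fractions (the strain-level analogue of the
  shared-species fraction),
* per (patient, species, post-FMT visit) transmission events -
  donor_acquired / retained_pre / replaced / coincident_shared /
  not_callable,
* a partition of all multi-sample strains into relationship classes
  (within-patient over time, patient-vs-donor, patients sharing a donor,
  other),
* species rankings by number of patients showing a given event.

Species/sample combinations that were not strain-profiled are excluded
from every denominator; strain-level transmission estimates are
therefore lower bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .metadata import POST_TIME_POINTS, CohortMetadata

DEFAULT_NGD_THRESHOLD = 0.01

EVENT_LABELS = (
    "donor_acquired",
    "retained_pre",
    "replaced",
    "coincident_shared",
    "not_callable",
)

SHARING_CLASSES = (
    "within_patient_timepoints",
    "patient_vs_donor",
    "same_donor_patients",
    "other",
)


class StrainDistanceSet:
    """Complete pairwise nGD among the samples strain-profiled for one species."""

    def __init__(self, species_name: str, distances: Mapping[Tuple[str, str], float]):
        self.species_name = species_name
        self._d: Dict[Tuple[str, str], float] = {}
        samples = set()
        for (a, b), v in distances.items():
            if v < 0:
                raise ValueError(f"negative nGD {v} for ({a}, {b})")
            if a == b:
                if v != 0:
                    raise ValueError(f"nonzero self-distance for {a}")
                samples.add(a)
                continue
            samples.update((a, b))
            key = (a, b) if a < b else (b, a)
            prev = self._d.get(key)
            if prev is not None and prev != v:
                raise ValueError(f"asymmetric distances for pair {key}")
            self._d[key] = float(v)
        self.samples = frozenset(samples)
        n = len(self.samples)
        if len(self._d) != n * (n - 1) // 2:
            raise ValueError(
                f"{species_name}: incomplete distance set over {n} samples"
            )

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.samples

    def distance(self, a: str, b: str) -> float:
        if a not in self.samples or b not in self.samples:
            raise KeyError(f"sample pair ({a}, {b}) not profiled for {self.species_name}")
        if a == b:
            return 0.0
        return self._d[(a, b) if a < b else (b, a)]

    def pairs(self):
        """Iterate ((a, b), nGD) over distinct unordered pairs."""
        return self._d.items()

    def to_matrix(self) -> pd.DataFrame:
        ids = sorted(self.samples)
        mat = pd.DataFrame(0.0, index=ids, columns=ids)
        for (a, b), v in self._d.items():
            mat.loc[a, b] = v
            mat.loc[b, a] = v
        return mat

    @classmethod
    def from_matrix(cls, species_name: str, frame: pd.DataFrame) -> "StrainDistanceSet":
        if list(frame.index) != list(frame.columns):
            raise ValueError(f"{species_name}: matrix row/column ids differ")
        d = {}
        ids = list(frame.index)
        arr = frame.to_numpy(dtype=float)
        for i, a in enumerate(ids):
            d[(a, a)] = 0.0
            for j in range(i + 1, len(ids)):
                d[(a, ids[j])] = arr[i, j]
        return cls(species_name, d)


def total_tree_length(tree: dendropy.Tree) -> float:
    return float(sum(e.length or 0.0 for e in tree.edges()))


def _normaliser(tree: dendropy.Tree, normalisation: str) -> float:
    """Branch-length scale for nGD: total tree length (default) or the
    maximum pairwise patristic distance."""
    if normalisation == "total_length":
        return total_tree_length(tree)
    if normalisation == "max_pairwise":
        pdm = tree.phylogenetic_distance_matrix()
        return max(
            (pdm.patristic_distance(a, b)
             for a, b in combinations(tree.taxon_namespace, 2)),
            default=0.0,
        )
    raise ValueError(f"unknown normalisation {normalisation!r}")


def ngd_from_tree(
    tree: dendropy.Tree,
    leaf_a: str,
    leaf_b: str,
    normalisation: str = "total_length",
) -> float:
    """Normalised genetic distance between two leaves of a strain tree.

    Patristic distance divided by the tree's branch-length scale (total
    branch length by default); invariant to rescaling all branch lengths.
    """
    total = _normaliser(tree, normalisation)
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    taxa = {t.label: t for t in tree.taxon_namespace}
    for leaf in (leaf_a, leaf_b):
        if leaf not in taxa:
            raise KeyError(f"leaf {leaf!r} not in tree")
    if leaf_a == leaf_b:
        return 0.0
    pdm = tree.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(taxa[leaf_a], taxa[leaf_b])) / total


def tree_to_distance_set(
    tree: dendropy.Tree,
    species_name: str,
    normalisation: str = "total_length",
) -> StrainDistanceSet:
    """All-pairs nGD from one species tree."""
    total = _normaliser(tree, normalisation)
    if total <= 0:
        raise ValueError(f"{species_name}: tree has zero total branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    d: Dict[Tuple[str, str], float] = {}
    for i, ta in enumerate(taxa):
        d[(ta.label, ta.label)] = 0.0
        for tb in taxa[i + 1:]:
            d[(ta.label, tb.label)] = float(pdm.patristic_distance(ta, tb)) / total
    return StrainDistanceSet(species_name, d)


def call_same_strain(
    ngd: float, threshold: float = DEFAULT_NGD_THRESHOLD, inclusive: bool = True
) -> bool:
    """Same-strain call at the nGD cutoff (inclusive boundary by default)."""
    if ngd < 0:
        raise ValueError("nGD must be non-negative")
    return ngd <= threshold if inclusive else ngd < threshold


def shared_strain_fraction(
    sample_a: str,
    sample_b: str,
    distance_sets: Iterable[StrainDistanceSet],
    threshold: float = DEFAULT_NGD_THRESHOLD,
) -> Optional[float]:
    """Fraction of co-profiled species whose strains match between two samples.

    Returns ``None`` (not callable) when no species is strain-profiled in
    both samples; such pairs are excluded from downstream distributions.
    """
    shared = 0
    co_profiled = 0
    for ds in distance_sets:
        if sample_a in ds and sample_b in ds:
            co_profiled += 1
            if call_same_strain(ds.distance(sample_a, sample_b), threshold):
                shared += 1
    if co_profiled == 0:
        return None
    return shared / co_profiled


@dataclass
class StrainEvent:
    """One classified transmission outcome per (patient, species, visit)."""

    patient_id: str
    species_name: str
    time_point: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")


def classify_strain_event(
    patient_id: str,
    species_name: str,
    time_point: str,
    donor_post: Optional[bool],
    pre_post: Optional[bool],
    donor_pre: Optional[bool],
) -> StrainEvent:
    """Classify one post-FMT strain observation.

    Inputs are same-strain calls for the donor-vs-post, pre-vs-post and
    donor-vs-pre comparisons (``None`` = not callable because one side
    was not strain-profiled).  Rules, evaluated in order:

    1. all three callable and true -> ``coincident_shared`` (the donor
       and the patient already carried indistinguishable strains);
    2. pre-vs-post true -> ``retained_pre``;
    3. donor-vs-post true with the pre sample profiled (so a pre strain
       existed and differs from the post strain) -> ``replaced``;
    4. donor-vs-post true with no pre profile -> ``donor_acquired``;
    5. otherwise -> ``not_callable``.
    """
    if donor_post and pre_post and donor_pre:
        label = "coincident_shared"
    elif pre_post:
        label = "retained_pre"
    elif donor_post and pre_post is not None:
        label = "replaced"
    elif donor_post:
        label = "donor_acquired"
    else:
        label = "not_callable"
    return StrainEvent(patient_id, species_name, time_point, label)


def classify_events(
    distance_sets: Iterable[StrainDistanceSet],
    metadata: CohortMetadata,
    threshold: float = DEFAULT_NGD_THRESHOLD,
    post_time_points: Sequence[str] = POST_TIME_POINTS,
) -> List[StrainEvent]:
    """Classify every (patient, species, visit) with a profiled post sample."""
    layout = _patient_sample_layout(metadata, post_time_points)
    events: List[StrainEvent] = []
    for ds in distance_sets:
        for patient, (donor_sample, pre_sample, post_samples) in layout.items():
            for tp, post_sample in post_samples.items():
                if post_sample is None or post_sample not in ds:
                    continue

                def _call(x: Optional[str], y: Optional[str]) -> Optional[bool]:
                    if x is None or y is None or x not in ds or y not in ds:
                        return None
                    return call_same_strain(ds.distance(x, y), threshold)

                events.append(
                    classify_strain_event(
                        patient,
                        ds.species_name,
                        tp,
                        donor_post=_call(donor_sample, post_sample),
                        pre_post=_call(pre_sample, post_sample),
                        donor_pre=_call(donor_sample, pre_sample),
                    )
                )
    return events


def _patient_sample_layout(
    metadata: CohortMetadata, post_time_points: Sequence[str]
) -> Dict[str, tuple]:
    """Per D-FMT patient: (donor sample, pre sample, {visit: post sample})."""
    layout: Dict[str, tuple] = {}
    for patient in metadata.dfmt_patients():
        donor_sample = metadata.donor_sample_of(metadata.donor_of_patient(patient))
        pre_sample = metadata.sample_of(patient, "pre")
        posts = {tp: metadata.sample_of(patient, tp) for tp in post_time_points}
        layout[patient] = (donor_sample, pre_sample, posts)
    return layout


def strain_clusters(
    ds: StrainDistanceSet, threshold: float = DEFAULT_NGD_THRESHOLD
) -> List[frozenset]:
    """Connected components of the thresholded same-strain graph.

    Same-strain calls at a fixed cutoff need not be transitive, so strain
    identity over more than two samples is *imposed* by taking connected
    components rather than assumed.
    """
    g = nx.Graph()
    g.add_nodes_from(ds.samples)
    for (a, b), v in ds.pairs():
        if call_same_strain(v, threshold):
            g.add_edge(a, b)
    return [frozenset(c) for c in nx.connected_components(g)]


@dataclass
class SharingPartition:
    """Multi-sample strains partitioned into relationship classes."""

    counts: Dict[str, int]
    total: int

    @property
    def percentages(self) -> Dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.total for k, v in self.counts.items()}


def _applicable_classes(cluster: frozenset, metadata: CohortMetadata) -> set:
    rows = [metadata.row(s) for s in cluster]
    classes = set()
    # within one D-FMT patient across different time points
    by_subject: Dict[str, set] = {}
    for r in rows:
        if r["role"] == "dfmt":
            by_subject.setdefault(str(r["subject_id"]), set()).add(str(r["time_point"]))
    if any(len(tps) > 1 for tps in by_subject.values()):
        classes.add("within_patient_timepoints")
    # patient sample together with its own donor's sample
    donor_subjects = {str(r["subject_id"]) for r in rows if r["role"] == "donor"}
    if any(
        r["role"] == "dfmt" and str(r["donor_id"]) in donor_subjects for r in rows
    ):
        classes.add("patient_vs_donor")
    # distinct patients sharing the same donor
    donors_of_patients: Dict[str, set] = {}
    for r in rows:
        if r["role"] == "dfmt":
            donors_of_patients.setdefault(str(r["donor_id"]), set()).add(
                str(r["subject_id"])
            )
    if any(len(pats) > 1 for pats in donors_of_patients.values()):
        classes.add("same_donor_patients")
    return classes


def _classify_cluster(
    cluster: frozenset,
    metadata: CohortMetadata,
    precedence: Sequence[str] = SHARING_CLASSES,
) -> str:
    classes = _applicable_classes(cluster, metadata)
    for label in precedence:
        if label in classes:
            return label
    return "other"


def sharing_partition(
    distance_sets: Iterable[StrainDistanceSet],
    metadata: CohortMetadata,
    threshold: float = DEFAULT_NGD_THRESHOLD,
    precedence: Sequence[str] = SHARING_CLASSES,
) -> SharingPartition:
    """Partition multi-sample strains by relationship class.

    A strain is a connected component of a species' same-strain graph;
    only components spanning more than one sample enter the partition.
    A cluster matching several classes takes the first in ``precedence``
    (default: within-patient over time > patient-vs-donor > patients
    sharing a donor > other), so classes are mutually exclusive.
    """
    counts = {k: 0 for k in SHARING_CLASSES}
    total = 0
    for ds in distance_sets:
        for cluster in strain_clusters(ds, threshold):
            if len(cluster) < 2:
                continue
            total += 1
            counts[_classify_cluster(cluster, metadata, precedence)] += 1
    return SharingPartition(counts=counts, total=total)


def top_event_species(
    events: Sequence[StrainEvent], label: str
) -> List[Tuple[str, int]]:
    """Species ranked by number of distinct patients with the given event.

    A patient with events at several visits for one species counts once.
    Ties break lexicographically by species name.
    """
    if label not in EVENT_LABELS:
        raise ValueError(f"unknown event label {label!r}")
    patients_by_species: Dict[str, set] = {}
    for e in events:
        if e.label == label:
            patients_by_species.setdefault(e.species_name, set()).add(e.patient_id)
    ranked = sorted(
        ((sp, len(pats)) for sp, pats in patients_by_species.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked


def estimate_engraftment_rates(
    events: Sequence[StrainEvent],
    distance_sets: Iterable[StrainDistanceSet],
    metadata: CohortMetadata,
    post_time_points: Sequence[str] = POST_TIME_POINTS,
) -> Dict[str, float]:
    """Estimate per-opportunity engraftment and retention rates.

    Engraftment rate: among (patient, species, visit) triples whose donor
    sample is strain-profiled for the species, the fraction where the
    post sample carries the donor's strain (donor_acquired, replaced or
    coincident_shared).  Retention rate: among triples whose pre sample
    is profiled and whose post strain is not donor-derived, the fraction
    retaining the pre strain.  Unbiased when strain profiling is
    complete; with incomplete profiling both are conservative estimates,
    mirroring the underestimation inherent to strain-level profiling.
    """
    ev_by_key = {
        (e.patient_id, e.species_name, e.time_point): e.label for e in events
    }
    layout = _patient_sample_layout(metadata, post_time_points)
    n_e = k_e = n_r = k_r = 0
    for ds in distance_sets:
        for patient, (donor_sample, pre_sample, _posts) in layout.items():
            for tp in post_time_points:
                label = ev_by_key.get((patient, ds.species_name, tp))
                donor_derived = label in ("donor_acquired", "replaced", "coincident_shared")
                if donor_sample in ds:
                    n_e += 1
                    k_e += donor_derived
                if pre_sample is not None and pre_sample in ds and not donor_derived:
                    n_r += 1
                    k_r += label == "retained_pre"
    return {
        "engraftment_rate": k_e / n_e if n_e else float("nan"),
        "retention_rate": k_r / n_r if n_r else float("nan"),
        "n_engraftment_opportunities": n_e,
        "n_retention_opportunities": n_r,
    }
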