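"""Synthetic FMT-trial cohorts with planted engraftment structure.

The generator emulates the structure of a two-donor, 10+10-patient
randomised FMT trial: donor stool communities, patient baseline
communities, post-FMT communities at weeks 1/2/4 that are convex
mixtures of donor and pre-FMT profiles, and per-species strain lineages
with controllable engraftment and retention probabilities.  Every
quantity the pipeline later estimates is planted explicitly and returned
as ground truth, so classifier output can be compared against known
answers.

Communities are log-normal relative-abundance vectors over a shared
species pool with partial occupancy, renormalised to 100%.  Strain
lineages are abstract labels (one per donor and one per patient
baseline, always distinct); pairwise normalised genetic distances are
drawn below the same-strain band for samples carrying the same lineage
and above the different-strain band otherwise, so thresholded strain
clusters recover lineages exactly.  Strain profiling of each
species/sample combination is Bernoulli-thinned to emulate incomplete
StrainPhlAn coverage.

The generator does not attempt read-level realism, phylogenetic models
of marker evolution, or ecological dynamics; see the package methods
note for what that implies about test conclusions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clinical import SubjectRecord
from .community import AbundanceProfile
from .metadata import METADATA_COLUMNS, CohortMetadata
from .strains import StrainDistanceSet

PLANTED_LABELS = ("donor_acquired", "retained_pre", "replaced", "absent")

_WEEK_OF = {"wk1": 1, "wk2": 2, "wk4": 4}


@dataclass
class SimParams:
    """Study-condition parameters for one simulated cohort.

    Defaults mirror the emulated trial design (2 donors, 10 treated and
    10 control patients, four treated-patient time points) and a
    moderately engrafting FMT: per-species donor-strain take-over
    probability 0.6 at week 1 with no decay, baseline-strain retention
    0.4 in the absence of take-over, and 70% strain-profiling coverage.
    """

    n_dfmt: int = 10
    n_pfmt: int = 10
    n_donors: int = 2
    n_species: int = 200
    time_points: Tuple[str, ...] = ("pre", "wk1", "wk2", "wk4")
    engraftment_prob: float = 0.6
    retention_prob: float = 0.4
    decay_per_week: float = 1.0
    abundance_log_mean: float = 0.0
    abundance_log_sd: float = 2.0
    species_prevalence: float = 0.6
    mixture_weight_range: Tuple[float, float] = (0.4, 0.8)
    strain_profiling_prob: float = 0.7
    same_strain_ngd_max: float = 0.005
    diff_strain_ngd_min: float = 0.05
    diff_strain_ngd_max: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "engraftment_prob",
            "retention_prob",
            "species_prevalence",
            "strain_profiling_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.decay_per_week <= 1.0):
            raise ValueError("decay_per_week must be in (0, 1]")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if min(self.n_dfmt, self.n_pfmt, self.n_donors) < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not (self.same_strain_ngd_max < 0.01 < self.diff_strain_ngd_min):
            raise ValueError(
                "nGD bands must straddle the 0.01 same-strain cutoff"
            )
        lo, hi = self.mixture_weight_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mixture_weight_range must be ordered within [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["time_points"] = list(self.time_points)
        d["mixture_weight_range"] = list(self.mixture_weight_range)
        return d


@dataclass
class SimulatedCohort:
    """In-memory simulation output plus planted ground truth."""

    params: SimParams
    profiles: List[AbundanceProfile]
    distance_sets: List[StrainDistanceSet]
    metadata: CohortMetadata
    ground_truth: pd.DataFrame  # patient_id, species, time_point, label
    mixture_weights: Dict[str, float]  # post sample id -> weight on donor
    subjects: List[SubjectRecord]


def _species_names(n: int) -> List[str]:
    return [f"sp{i:04d}" for i in range(1, n + 1)]


def _community(rng: np.random.Generator, species: Sequence[str], params: SimParams):
    """Partial-occupancy log-normal community, renormalised to 100%."""
    n = len(species)
    present = rng.random(n) < params.species_prevalence
    if not present.any():
        present[rng.integers(n)] = True
    ab = np.where(
        present,
        rng.lognormal(params.abundance_log_mean, params.abundance_log_sd, n),
        0.0,
    )
    ab = 100.0 * ab / ab.sum()
    return dict(zip(species, ab))


def _grades(rng: np.random.Generator, arm: str) -> dict:
    # plumbing for end-to-end runs: D-FMT mostly resolves, P-FMT persists
    if arm == "DFMT":
        probs = {0: 0.7, 1: 0.2, 2: 0.1}
    else:
        probs = {0: 0.05, 1: 0.15, 2: 0.6, 3: 0.2}
    grades = {"baseline": 2}
    for visit in ("wk1", "wk2", "wk4", "wk8"):
        grades[visit] = int(
            rng.choice(list(probs.keys()), p=list(probs.values()))
        )
    return grades


def simulate_cohort(params: Optional[SimParams] = None, **kwargs) -> SimulatedCohort:
    """Generate one fully reproducible synthetic cohort.

    Independent RNG streams (spawned from the master seed) drive
    abundances, ground-truth labels, strain distances, profiling dropout
    and clinical grades, so rerunning one stage cannot perturb another.
    """
    if params is None:
        params = SimParams(**kwargs)
    ss = np.random.SeedSequence(params.seed)
    r_ab, r_truth, r_dist, r_prof, r_mix, r_clin = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    species = _species_names(params.n_species)
    donors = [f"D{i:02d}" for i in range(1, params.n_donors + 1)]
    dfmt = [f"P{i:02d}" for i in range(1, params.n_dfmt + 1)]
    pfmt = [f"C{i:02d}" for i in range(1, params.n_pfmt + 1)]
    donor_of = {p: donors[i % params.n_donors] for i, p in enumerate(dfmt)}

    meta_rows = []
    profiles: List[AbundanceProfile] = []
    communities: Dict[str, dict] = {}

    for d in donors:
        sid = f"{d}_donor"
        communities[sid] = _community(r_ab, species, params)
        meta_rows.append([sid, d, "donor", "donor", d])
        profiles.append(
            AbundanceProfile(sid, communities[sid], subject_id=d, time_point="donor")
        )
    for p in dfmt:
        sid = f"{p}_pre"
        communities[sid] = _community(r_ab, species, params)
        meta_rows.append([sid, p, "dfmt", "pre", donor_of[p]])
        profiles.append(
            AbundanceProfile(sid, communities[sid], subject_id=p, time_point="pre")
        )
    for c in pfmt:
        sid = f"{c}_pre"
        communities[sid] = _community(r_ab, species, params)
        meta_rows.append([sid, c, "pfmt", "control_pre", None])
        profiles.append(
            AbundanceProfile(sid, communities[sid], subject_id=c, time_point="control_pre")
        )

    # post-FMT communities: convex donor/pre mixtures, one weight per patient
    lo, hi = params.mixture_weight_range
    mixture_weights: Dict[str, float] = {}
    post_tps = [t for t in params.time_points if t != "pre"]
    patient_weight = {p: float(r_mix.uniform(lo, hi)) for p in dfmt}
    for p in dfmt:
        donor_sid = f"{donor_of[p]}_donor"
        pre_sid = f"{p}_pre"
        w = patient_weight[p]
        for tp in post_tps:
            sid = f"{p}_{tp}"
            mix = {
                s: w * communities[donor_sid].get(s, 0.0)
                + (1.0 - w) * communities[pre_sid].get(s, 0.0)
                for s in species
            }
            communities[sid] = mix
            mixture_weights[sid] = w
            meta_rows.append([sid, p, "dfmt", tp, donor_of[p]])
            profiles.append(
                AbundanceProfile(sid, mix, subject_id=p, time_point=tp)
            )

    metadata = CohortMetadata(
        pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    )

    # planted strain structure ------------------------------------------------
    truth_rows = []
    lineage_of: Dict[str, Dict[str, Optional[str]]] = {s: {} for s in species}
    for si, s in enumerate(species):
        for d in donors:
            if communities[f"{d}_donor"][s] > 0:
                lineage_of[s][f"{d}_donor"] = f"donor:{d}"
        for subj in dfmt + pfmt:
            if communities[f"{subj}_pre"][s] > 0:
                lineage_of[s][f"{subj}_pre"] = f"pre:{subj}"
        for p in dfmt:
            donor_has = f"{donor_of[p]}_donor" in lineage_of[s]
            pre_has = f"{p}_pre" in lineage_of[s]
            for tp in post_tps:
                week = _WEEK_OF.get(tp, 1)
                p_e = params.engraftment_prob * params.decay_per_week ** (week - 1)
                engrafted = donor_has and (r_truth.random() < p_e)
                retained = pre_has and (r_truth.random() < params.retention_prob)
                if engrafted:
                    label = "replaced" if pre_has else "donor_acquired"
                    lineage_of[s][f"{p}_{tp}"] = f"donor:{donor_of[p]}"
                elif retained:
                    label = "retained_pre"
                    lineage_of[s][f"{p}_{tp}"] = f"pre:{p}"
                else:
                    label = "absent"
                truth_rows.append([p, s, tp, label])

    ground_truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "species", "time_point", "label"]
    )

    # strain profiling dropout + planted pairwise nGD -------------------------
    distance_sets: List[StrainDistanceSet] = []
    for s in species:
        carriers = sorted(lineage_of[s])
        kept = [
            sid
            for sid in carriers
            if r_prof.random() < params.strain_profiling_prob
        ]
        if not kept:
            continue
        k = len(kept)
        n_pairs = k * (k - 1) // 2
        same_draws = r_dist.uniform(0.0, params.same_strain_ngd_max, n_pairs)
        diff_draws = r_dist.uniform(
            params.diff_strain_ngd_min, params.diff_strain_ngd_max, n_pairs
        )
        d: Dict[Tuple[str, str], float] = {}
        idx = 0
        for i, a in enumerate(kept):
            d[(a, a)] = 0.0
            lin_a = lineage_of[s][a]
            for b in kept[i + 1:]:
                same = lin_a == lineage_of[s][b]
                d[(a, b)] = float(same_draws[idx] if same else diff_draws[idx])
                idx += 1
        distance_sets.append(StrainDistanceSet(s, d))

    subjects = [
        SubjectRecord(
            subject_id=p,
            arm="DFMT",
            donor_id=donor_of[p],
            grade_by_visit=_grades(r_clin, "DFMT"),
        )
        for p in dfmt
    ] + [
        SubjectRecord(
            subject_id=c, arm="PFMT", grade_by_visit=_grades(r_clin, "PFMT")
        )
        for c in pfmt
    ]

    return SimulatedCohort(
        params=params,
        profiles=profiles,
        distance_sets=distance_sets,
        metadata=metadata,
        ground_truth=ground_truth,
        mixture_weights=mixture_weights,
        subjects=subjects,
    )


def planted_sharing_counts(cohort: SimulatedCohort) -> Dict[str, int]:
    """Relationship-class counts computed from planted lineages directly.

    Independent of distances and thresholds: for every (species, lineage)
    carried by more than one *profiled* sample, the class is assigned
    from metadata with the same precedence the pipeline uses.  Serves as
    the ground-truth oracle for :func:`fmtrack.strains.sharing_partition`.
    """
    from .strains import SHARING_CLASSES, _classify_cluster

    counts = {k: 0 for k in SHARING_CLASSES}
    for ds in cohort.distance_sets:
        groups: Dict[str, set] = {}
        # reconstruct lineages from planted distances: profiled samples with
        # identical lineage labels were generated with nGD below the band
        for sid in ds.samples:
            lineage = _planted_lineage(cohort, ds.species_name, sid)
            groups.setdefault(lineage, set()).add(sid)
        for members in groups.values():
            if len(members) > 1:
                counts[_classify_cluster(frozenset(members), cohort.metadata)] += 1
    return counts


def _planted_lineage(cohort: SimulatedCohort, species: str, sample_id: str) -> str:
    meta = cohort.metadata.row(sample_id)
    subj, tp, role = str(meta["subject_id"]), str(meta["time_point"]), str(meta["role"])
    if role == "donor":
        return f"donor:{subj}"
    if tp in ("pre", "control_pre"):
        return f"pre:{subj}"
    gt = cohort.ground_truth
    row = gt[
        (gt["patient_id"] == subj)
        & (gt["species"] == species)
        & (gt["time_point"] == tp)
    ]
    label = row["label"].iloc[0]
    if label in ("donor_acquired", "replaced"):
        return f"donor:{cohort.metadata.donor_of(sample_id)}"
    if label == "retained_pre":
        return f"pre:{subj}"
    raise ValueError(f"sample {sample_id} profiled for {species} without a lineage")


# fixture serialisation -------------------------------------------------------

def write_fixture_set(cohort: SimulatedCohort, directory) -> dict:
    """Write the cohort in the exact external formats the pipeline reads.

    Emits ``abundance.tsv`` (merged MetaPhlAn-dialect table),
    ``metadata.tsv``, ``subjects.tsv``, ``ground_truth.tsv``, one
    ``strains/<species>.tsv`` square distance matrix per profiled
    species, and ``manifest.json`` recording the seed and every
    parameter.  Output is byte-deterministic for a fixed seed.
    """
    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "strains").mkdir(exist_ok=True)

    abundance_path = directory / "abundance.tsv"
    _io.write_abundance_table(cohort.profiles, abundance_path)

    metadata_path = directory / "metadata.tsv"
    _io.write_metadata(cohort.metadata, metadata_path)

    subjects_path = directory / "subjects.tsv"
    _io.write_subjects(cohort.subjects, subjects_path)

    gt_path = directory / "ground_truth.tsv"
    cohort.ground_truth.to_csv(gt_path, sep="\t", index=False)

    strain_files = []
    for ds in sorted(cohort.distance_sets, key=lambda d: d.species_name):
        path = directory / "strains" / f"{ds.species_name}.tsv"
        _io.write_distance_matrix(ds, path)
        strain_files.append(str(path.relative_to(directory)))

    manifest = {
        "params": cohort.params.to_dict(),
        "seed": cohort.params.seed,
        "files": {
            "abundance": abundance_path.name,
            "metadata": metadata_path.name,
            "subjects": subjects_path.name,
            "ground_truth": gt_path.name,
            "strains": strain_files,
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
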