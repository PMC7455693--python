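"""Readers and writers for the pipeline's external formats.

All tabular formats are plain TSV (tab-separated, UTF-8, no quoting);
abundance tables follow the merged-MetaPhlAn dialect (``#`` comment
lines, first column a species name or a ``|``-separated taxonomy path
whose ``s__`` leaf segment is used); strain inputs are either square
per-species distance-matrix TSVs or newick trees whose leaves are sample
identifiers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd
import yaml

from .clinical import (
    FOLLOWUP_VISITS,
    VISITS,
    EndpointResult,
    SubjectRecord,
    format_p_value,
)
from .community import ABUNDANCE_SUM_TARGET, ABUNDANCE_SUM_TOL, AbundanceProfile, PairDistanceRecord
from .metadata import METADATA_COLUMNS, CohortMetadata
from .stats import CategoryTest, PermanovaResult
from .strains import SharingPartition, StrainDistanceSet, StrainEvent, tree_to_distance_set

logger = logging.getLogger("fmtrack")

FLOAT_FMT = "%.6f"
MATRIX_ASYMMETRY_TOL = 1e-9


# --- abundance tables --------------------------------------------------------

_RANK_PREFIXES = tuple(f"{r}__" for r in "kpcofgst")


def _species_from_clade(name: str) -> Optional[str]:
    """Reduce a taxonomy path to its species name; None = not species-level."""
    leaf = name.split("|")[-1]
    if leaf.startswith("s__"):
        return leaf[3:]
    if leaf.startswith(_RANK_PREFIXES):
        return None  # kingdom..genus / strain rows of a full merged table
    return None if "|" in name else name


def read_abundance_table(path, metadata: Optional[CohortMetadata] = None) -> List[AbundanceProfile]:
    """Parse a merged species-abundance TSV into per-sample profiles.

    ``#`` header lines are skipped; taxonomy-path rows other than species
    level are dropped; duplicate sample columns are rejected.  Samples
    whose abundances do not sum to 100 +/- 0.5 are kept with a logged
    warning (profiler rounding can overshoot that on real tables).
    """
    path = Path(path)
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
    if header is None:
        raise ValueError(f"{path}: no header line found")
    sample_ids = header[1:]
    if not sample_ids:
        raise ValueError(f"{path}: no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups}")

    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric abundance value ({exc})") from None

    rows = {}
    for clade in frame.index:
        sp = _species_from_clade(str(clade))
        if sp is None:
            continue
        if sp in rows:
            raise ValueError(f"{path}: duplicate species {sp!r}")
        rows[sp] = frame.loc[clade]

    profiles = []
    for sid in sample_ids:
        abundances = {sp: float(row[sid]) for sp, row in rows.items() if row[sid] > 0}
        profile = AbundanceProfile(sample_id=sid, abundances=abundances)
        if metadata is not None and sid in metadata:
            profile.subject_id = metadata.subject_of(sid)
            profile.time_point = metadata.time_point_of(sid)
        total = profile.total()
        if abs(total - ABUNDANCE_SUM_TARGET) > ABUNDANCE_SUM_TOL:
            logger.warning(
                "sample %s abundances sum to %.3f (outside %g +/- %g)",
                sid, total, ABUNDANCE_SUM_TARGET, ABUNDANCE_SUM_TOL,
            )
        profiles.append(profile)
    return profiles


def write_abundance_table(profiles: Sequence[AbundanceProfile], path) -> None:
    """Write profiles as a merged-dialect abundance TSV (6 decimals)."""
    species = sorted({s for p in profiles for s in p.abundances})
    ids = [p.sample_id for p in profiles]
    with open(path, "w") as fh:
        fh.write("#mpa_synthetic merged abundance table\n")
        fh.write("clade_name\t" + "\t".join(ids) + "\n")
        for sp in species:
            vals = "\t".join(
                FLOAT_FMT % p.abundances.get(sp, 0.0) for p in profiles
            )
            fh.write(f"{sp}\t{vals}\n")


# --- metadata and subjects ---------------------------------------------------

def read_metadata(path) -> CohortMetadata:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame["donor_id"] = frame["donor_id"].replace("", None)
    return CohortMetadata(frame)


def write_metadata(metadata: CohortMetadata, path) -> None:
    frame = metadata.frame.copy()
    frame["donor_id"] = frame["donor_id"].fillna("")
    frame.to_csv(path, sep="\t", index=False)


_SUBJECT_GRADE_COLS = {f"grade_{v}": v for v in VISITS}


def read_subjects(path) -> List[SubjectRecord]:
    """Read the subjects TSV; empty grade cells mark missing visits."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    subjects = []
    for _, row in frame.iterrows():
        grades = {}
        for col, visit in _SUBJECT_GRADE_COLS.items():
            raw = row.get(col, "")
            grades[visit] = int(raw) if raw != "" else None
        subjects.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                arm=row["arm"],
                donor_id=row.get("donor_id") or None,
                sex=row.get("sex") or None,
                age=int(row["age"]) if row.get("age") else None,
                grade_by_visit=grades,
            )
        )
    return subjects


def write_subjects(subjects: Sequence[SubjectRecord], path) -> None:
    cols = ["subject_id", "arm", "donor_id", "sex", "age"] + list(
        _SUBJECT_GRADE_COLS
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in subjects:
            row = [
                s.subject_id,
                s.arm,
                s.donor_id or "",
                s.sex or "",
                "" if s.age is None else str(s.age),
            ]
            for visit in VISITS:
                g = s.grade_by_visit.get(visit)
                row.append("" if g is None else str(g))
            fh.write("\t".join(row) + "\n")


# --- strain inputs -----------------------------------------------------------

def read_distance_matrix(path, species_name: Optional[str] = None) -> StrainDistanceSet:
    """Read one square symmetric nGD matrix TSV.

    Asymmetries up to 1e-9 are symmetrised away; larger ones are
    rejected.  The diagonal must be (numerically) zero.
    """
    path = Path(path)
    if species_name is None:
        species_name = path.stem
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    arr = frame.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: matrix must be square with matching ids")
    asym = np.abs(arr - arr.T).max() if arr.size else 0.0
    if asym > MATRIX_ASYMMETRY_TOL:
        raise ValueError(f"{path}: asymmetry {asym:g} exceeds tolerance")
    if arr.size and np.abs(np.diag(arr)).max() > MATRIX_ASYMMETRY_TOL:
        raise ValueError(f"{path}: nonzero diagonal")
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 0.0)
    return StrainDistanceSet.from_matrix(
        species_name, pd.DataFrame(arr, index=frame.index, columns=frame.columns)
    )


def write_distance_matrix(ds: StrainDistanceSet, path) -> None:
    """Write one nGD matrix TSV at full float precision (round-trip safe)."""
    mat = ds.to_matrix()
    ids = list(mat.index)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for a in ids:
            fh.write(a + "\t" + "\t".join(repr(float(v)) for v in mat.loc[a]) + "\n")


def read_newick_tree(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"{path}: malformed newick ({exc})") from None


TREE_SUFFIXES = (".tre", ".nwk", ".newick")


def read_strain_inputs(path_spec) -> List[StrainDistanceSet]:
    """Load per-species strain distances from a directory (or one file).

    Newick files (``.tre``/``.nwk``/``.newick``) are converted to nGD via
    the tree's total branch length; ``.tsv`` files are validated distance
    matrices.  File stems name the species.
    """
    path = Path(path_spec)
    files = sorted(path.iterdir()) if path.is_dir() else [path]
    sets: List[StrainDistanceSet] = []
    for f in files:
        if f.suffix == ".tsv":
            sets.append(read_distance_matrix(f))
        elif f.suffix in TREE_SUFFIXES:
            sets.append(tree_to_distance_set(read_newick_tree(f), f.stem))
    if not sets:
        raise ValueError(f"{path}: no strain input files found")
    return sets


# --- result writers ----------------------------------------------------------

def write_pair_metrics(records: Sequence[PairDistanceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_a\tsample_b\tcategory\tbray_curtis\tshared_species_fraction\n")
        for r in records:
            fh.write(
                f"{r.sample_a}\t{r.sample_b}\t{r.category}\t"
                + (FLOAT_FMT % r.bray_curtis)
                + "\t"
                + (FLOAT_FMT % r.shared_species_fraction)
                + "\n"
            )


def read_pair_metrics(path) -> List[PairDistanceRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        PairDistanceRecord(
            sample_a=str(r.sample_a),
            sample_b=str(r.sample_b),
            category=str(r.category),
            bray_curtis=float(r.bray_curtis),
            shared_species_fraction=float(r.shared_species_fraction),
        )
        for r in frame.itertuples()
    ]


def write_shared_strains(rows: Sequence[dict], path) -> None:
    """Per-pair shared-strain TSV; not-callable pairs carry empty cells."""
    with open(path, "w") as fh:
        fh.write("sample_a\tsample_b\tcategory\tshared_strain_fraction\tn_co_profiled\n")
        for r in rows:
            frac = r["shared_strain_fraction"]
            fh.write(
                f"{r['sample_a']}\t{r['sample_b']}\t{r['category']}\t"
                + ("" if frac is None else FLOAT_FMT % frac)
                + f"\t{r['n_co_profiled']}\n"
            )


def write_events(events: Sequence[StrainEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tspecies\ttime_point\tlabel\n")
        for e in events:
            fh.write(f"{e.patient_id}\t{e.species_name}\t{e.time_point}\t{e.label}\n")


def read_events(path) -> List[StrainEvent]:
    frame = pd.read_csv(path, sep="\t")
    return [
        StrainEvent(str(r.patient_id), str(r.species), str(r.time_point), str(r.label))
        for r in frame.itertuples()
    ]


def write_partition_json(partition: SharingPartition, path) -> None:
    payload = {
        "total_multi_sample_strains": partition.total,
        "counts": partition.counts,
        "percentages": {k: round(v, 4) for k, v in partition.percentages.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_endpoint_report(results: Sequence[EndpointResult], path) -> None:
    """Endpoint report TSV: counts, raw and adjusted p, printed-style p."""
    with open(path, "w") as fh:
        fh.write(
            "visit\tendpoint\tprimary\tdfmt_success\tdfmt_failure\t"
            "pfmt_success\tpfmt_failure\tm\tp_raw\tp_adjusted\tp_printed\n"
        )
        for r in results:
            (ds, dfail), (ps, pfail) = r.table.counts
            fh.write(
                f"{r.visit}\t{r.endpoint}\t{int(r.is_primary)}\t{ds}\t{dfail}\t"
                f"{ps}\t{pfail}\t{r.test.m}\t{r.test.p_raw!r}\t"
                f"{r.test.p_adjusted!r}\t{format_p_value(r.test.p_adjusted)}\n"
            )


def endpoint_summary_dict(results: Sequence[EndpointResult]) -> dict:
    out = []
    for r in results:
        out.append(
            {
                "visit": r.visit,
                "endpoint": r.endpoint,
                "primary": r.is_primary,
                "counts": r.table.counts,
                "m": r.test.m,
                "p_raw": r.test.p_raw,
                "p_adjusted": r.test.p_adjusted,
                "p_printed": format_p_value(r.test.p_adjusted),
            }
        )
    return {"endpoints": out}


def stats_payload(
    panels: Dict[str, List[CategoryTest]],
    baseline: Optional[PermanovaResult] = None,
) -> dict:
    payload: dict = {"panels": {}}
    for panel, tests in panels.items():
        payload["panels"][panel] = [
            {
                "category_a": t.category_a,
                "category_b": t.category_b,
                "n_a": t.n_a,
                "n_b": t.n_b,
                "p": t.p,
            }
            for t in tests
        ]
    if baseline is not None:
        payload["baseline_permanova"] = {
            "pseudo_F": baseline.pseudo_F,
            "p": baseline.p,
            "n_perm": baseline.n_perm,
            "seed": baseline.seed,
        }
    return payload


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end run configuration (mirrors the flat config file)."""

    out_dir: str
    subjects: Optional[str] = None
    abundance: Optional[str] = None
    strains: Optional[str] = None
    metadata: Optional[str] = None
    ngd_threshold: float = 0.01
    bonferroni_m: int = 7
    detection_min: float = 0.0
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ngd_threshold <= 0:
            raise ValueError("ngd_threshold must be positive")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)
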