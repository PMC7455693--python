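"""End-to-end orchestration: clinical and microbiome analyses in one run.

``run_full_analysis`` ties the stages together: endpoint statistics from
the subjects table; pair metrics and category construction from the
abundance table; strain events, sharing partition and shared-strain
fractions from the strain inputs; rank-sum panel tests and the baseline
PERMANOVA; plus a human-readable summary.  Every output is a plain TSV
or JSON file in the configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import io as _io
from .clinical import endpoint_analysis, format_p_value
from .community import (
    DEFAULT_CATEGORY_SCHEME,
    bray_curtis,
    build_comparison_pairs,
    category_pairs,
    values_by_category,
)
from .stats import DEFAULT_PANEL_TESTS, compare_categories, permanova
from .strains import (
    classify_events,
    estimate_engraftment_rates,
    sharing_partition,
    shared_strain_fraction,
    top_event_species,
)

logger = logging.getLogger("fmtrack")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: "_io.RunConfig") -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def baseline_permanova(profiles, metadata, n_perm: int, seed: int):
    """ADONIS on Bray-Curtis over baseline samples, grouped by arm.

    Compares treated patients' pre-FMT communities with the untreated
    controls' baseline communities.
    """
    by_id = {p.sample_id: p for p in profiles}
    ids, labels = [], []
    for sid in metadata.samples_at(("pre", "control_pre")):
        if sid in by_id:
            ids.append(sid)
            labels.append(metadata.role_of(sid))
    ids_sorted = sorted(ids)
    n = len(ids_sorted)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = bray_curtis(by_id[ids_sorted[i]], by_id[ids_sorted[j]])
            dm[i, j] = dm[j, i] = d
    labels_sorted = [labels[ids.index(s)] for s in ids_sorted]
    return permanova(dm, labels_sorted, n_perm=n_perm, seed=seed, sample_ids=ids_sorted)


def run_full_analysis(config: "_io.RunConfig") -> Dict[str, str]:
    """Run every stage the configured inputs allow; return output paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run config %s hash=%s seed=%d", config.to_dict(), _config_hash(config), config.seed)

    outputs: Dict[str, str] = {}
    summary_lines: List[str] = []

    # --- clinical stage ------------------------------------------------------
    if config.subjects:
        try:
            subjects = _io.read_subjects(config.subjects)
            results = endpoint_analysis(subjects, m=config.bonferroni_m)
            path = out_dir / "endpoints.tsv"
            _io.write_endpoint_report(results, path)
            _io.write_json(
                _io.endpoint_summary_dict(results), out_dir / "endpoints.json"
            )
            outputs["endpoints"] = str(path)
            outputs["endpoints_json"] = str(out_dir / "endpoints.json")
            for r in results:
                if r.is_primary:
                    summary_lines.append(
                        f"primary outcome ({r.visit} {r.endpoint}): "
                        f"{r.table.counts[0][0]}/{sum(r.table.counts[0])} vs "
                        f"{r.table.counts[1][0]}/{sum(r.table.counts[1])}, "
                        f"raw Fisher p = {format_p_value(r.test.p_raw)}"
                    )
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError("clinical", exc) from exc

    profiles = metadata = None
    if config.abundance and config.metadata:
        try:
            metadata = _io.read_metadata(config.metadata)
            profiles = _io.read_abundance_table(config.abundance, metadata)
            records = build_comparison_pairs(
                profiles, metadata, detection_min=config.detection_min
            )
            path = out_dir / "pair_metrics.tsv"
            _io.write_pair_metrics(records, path)
            outputs["pair_metrics"] = str(path)
            summary_lines.append(
                f"community: {len(records)} categorised sample pairs over "
                f"{len(profiles)} profiles"
            )
        except Exception as exc:
            raise StageError("community", exc) from exc
    else:
        records = None

    distance_sets = None
    if config.strains and metadata is not None:
        try:
            distance_sets = _io.read_strain_inputs(config.strains)
            events = classify_events(
                distance_sets, metadata, threshold=config.ngd_threshold
            )
            _io.write_events(events, out_dir / "events.tsv")
            outputs["events"] = str(out_dir / "events.tsv")

            partition = sharing_partition(
                distance_sets, metadata, threshold=config.ngd_threshold
            )
            _io.write_partition_json(partition, out_dir / "sharing_partition.json")
            outputs["sharing_partition"] = str(out_dir / "sharing_partition.json")

            shared_rows = []
            for a, b, label in category_pairs(metadata):
                frac = shared_strain_fraction(
                    a, b, distance_sets, threshold=config.ngd_threshold
                )
                n_co = sum(1 for ds in distance_sets if a in ds and b in ds)
                shared_rows.append(
                    {
                        "sample_a": a,
                        "sample_b": b,
                        "category": label,
                        "shared_strain_fraction": frac,
                        "n_co_profiled": n_co,
                    }
                )
            _io.write_shared_strains(shared_rows, out_dir / "shared_strains.tsv")
            outputs["shared_strains"] = str(out_dir / "shared_strains.tsv")

            rates = estimate_engraftment_rates(events, distance_sets, metadata)
            acquired = top_event_species(events, "donor_acquired")[:10]
            retained = top_event_species(events, "retained_pre")[:10]
            _io.write_json(
                {
                    "rates": rates,
                    "top_donor_acquired": acquired,
                    "top_retained_pre": retained,
                },
                out_dir / "engraftment.json",
            )
            outputs["engraftment"] = str(out_dir / "engraftment.json")
            summary_lines.append(
                f"strains: {partition.total} multi-sample strains; "
                f"engraftment rate {rates['engraftment_rate']:.3f}, "
                f"retention rate {rates['retention_rate']:.3f}"
            )
        except Exception as exc:
            raise StageError("strains", exc) from exc

    if records is not None:
        try:
            panels = {}
            for metric in ("bray_curtis", "shared_species_fraction"):
                values = values_by_category(records, metric)
                panels[metric] = compare_categories(values)
            if distance_sets is not None:
                shared_values: Dict[str, List[float]] = {}
                for row in shared_rows:
                    if row["shared_strain_fraction"] is not None:
                        shared_values.setdefault(row["category"], []).append(
                            row["shared_strain_fraction"]
                        )
                panels["shared_strain_fraction"] = compare_categories(shared_values)
            baseline = baseline_permanova(
                profiles, metadata, n_perm=config.n_perm, seed=config.seed
            )
            payload = _io.stats_payload(panels, baseline)
            _io.write_json(payload, out_dir / "stats.json")
            outputs["stats"] = str(out_dir / "stats.json")
            summary_lines.append(
                f"baseline PERMANOVA: pseudo-F = {baseline.pseudo_F:.3f}, "
                f"p = {baseline.p:.3f} ({baseline.n_perm} permutations)"
            )
        except Exception as exc:
            raise StageError("stats", exc) from exc

    summary = out_dir / "summary.txt"
    with open(summary, "w") as fh:
        fh.write("fmtrack run summary\n")
        fh.write(f"config hash: {_config_hash(config)}  seed: {config.seed}\n")
        for line in summary_lines:
            fh.write(line + "\n")
    outputs["summary"] = str(summary)
    return outputs
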