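import dendropy
import numpy as np
import pandas as pd
import pytest

from fmtrack import (
    CohortMetadata,
    SimParams,
    StrainDistanceSet,
    call_same_strain,
    classify_events,
    classify_strain_event,
    estimate_engraftment_rates,
    ngd_from_tree,
    shared_strain_fraction,
    sharing_partition,
    simulate_cohort,
    top_event_species,
    tree_to_distance_set,
)
from fmtrack.simulate import planted_sharing_counts
from fmtrack.strains import StrainEvent, strain_clusters

from oracles import ngd_path_oracle, random_strain_tree


def tree_from_newick(s):
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


class TestNgdFromTree:
    def test_star_tree_hand_value(self):
        tree = tree_from_newick("(A:1,B:2,C:3);")
        assert ngd_from_tree(tree, "A", "B") == pytest.approx(0.5)

    def test_same_leaf_is_zero(self):
        tree = tree_from_newick("(A:1,B:2,C:3);")
        assert ngd_from_tree(tree, "A", "A") == 0.0

    def test_branch_scaling_invariance(self):
        t1 = tree_from_newick("((A:1,B:2):0.5,(C:3,D:1):0.25);")
        t2 = tree_from_newick("((A:10,B:20):5,(C:30,D:10):2.5);")
        assert ngd_from_tree(t1, "A", "C") == pytest.approx(
            ngd_from_tree(t2, "A", "C")
        )

    def test_unknown_leaf_and_zero_length_rejected(self):
        tree = tree_from_newick("(A:1,B:2);")
        with pytest.raises(KeyError):
            ngd_from_tree(tree, "A", "Z")
        with pytest.raises(ValueError):
            ngd_from_tree(tree_from_newick("(A:0,B:0);"), "A", "B")

    def test_max_pairwise_normalisation(self):
        # widest leaf pair (B, C) spans 5 of the star's 6 length units
        tree = tree_from_newick("(A:1,B:2,C:3);")
        assert ngd_from_tree(tree, "A", "B", normalisation="max_pairwise") == (
            pytest.approx(3 / 5)
        )
        assert ngd_from_tree(tree, "B", "C", normalisation="max_pairwise") == (
            pytest.approx(1.0)
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_path_enumeration_oracle(self, seed):
        n_leaves = 3 + seed
        tree = random_strain_tree(seed, n_leaves)
        ds = tree_to_distance_set(tree, "sp")
        labels = sorted(t.label for t in tree.taxon_namespace)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert ds.distance(a, b) == pytest.approx(
                    ngd_path_oracle(tree, a, b), rel=1e-9
                )


class TestSameStrainCall:
    @pytest.mark.parametrize(
        "ngd,expected",
        [(0.0, True), (0.009, True), (0.01, True), (0.011, False), (0.5, False)],
    )
    def test_inclusive_cutoff(self, ngd, expected):
        assert call_same_strain(ngd) is expected

    def test_exclusive_variant(self):
        assert call_same_strain(0.01, inclusive=False) is False
        assert call_same_strain(0.009, inclusive=False) is True

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            call_same_strain(-0.001)


def simple_distance_sets():
    """Four species over samples X and Y; one same-strain call (sp1)."""
    sets = []
    for name, d in [
        ("sp1", 0.002),
        ("sp2", 0.3),
        ("sp3", 0.2),
        ("sp4", 0.4),
    ]:
        sets.append(StrainDistanceSet(name, {("X", "Y"): d}))
    return sets


class TestSharedStrainFraction:
    def test_hand_counted_fraction(self):
        assert shared_strain_fraction("X", "Y", simple_distance_sets()) == 0.25

    def test_self_comparison_is_one(self):
        assert shared_strain_fraction("X", "X", simple_distance_sets()) == 1.0

    def test_no_co_profiled_species_not_callable(self):
        sets = [StrainDistanceSet("sp1", {("X", "Z"): 0.2})]
        assert shared_strain_fraction("X", "Y", sets) is None

    def test_donor_inheritance_fraction_recovered(self):
        """donor-vs-post shared fraction converges to the inherited fraction."""
        rng = np.random.default_rng(3)
        n_species, f = 400, 0.3
        sets = []
        inherited = rng.random(n_species) < f
        for i in range(n_species):
            d = rng.uniform(0, 0.005) if inherited[i] else rng.uniform(0.05, 0.5)
            sets.append(StrainDistanceSet(f"sp{i}", {("donor", "post"): d}))
        got = shared_strain_fraction("donor", "post", sets)
        assert got == pytest.approx(inherited.mean())
        assert got == pytest.approx(f, abs=3 * np.sqrt(f * (1 - f) / n_species))


class TestEventClassification:
    @pytest.mark.parametrize(
        "donor_post,pre_post,donor_pre,expected",
        [
            (True, None, None, "donor_acquired"),
            (True, False, False, "replaced"),
            (True, False, None, "replaced"),
            (False, True, None, "retained_pre"),
            (True, True, True, "coincident_shared"),
            (True, True, False, "retained_pre"),
            (True, True, None, "retained_pre"),
            (False, False, None, "not_callable"),
            (None, None, None, "not_callable"),
            (None, True, None, "retained_pre"),
            (None, False, None, "not_callable"),
        ],
    )
    def test_rule_table(self, donor_post, pre_post, donor_pre, expected):
        event = classify_strain_event(
            "P01", "sp1", "wk1", donor_post, pre_post, donor_pre
        )
        assert event.label == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            StrainEvent("P01", "sp1", "wk1", "engrafted")

    def test_every_profiled_post_gets_exactly_one_label(self, small_cohort):
        events = classify_events(small_cohort.distance_sets, small_cohort.metadata)
        keys = [(e.patient_id, e.species_name, e.time_point) for e in events]
        assert len(keys) == len(set(keys))
        profiled = 0
        meta = small_cohort.metadata
        for ds in small_cohort.distance_sets:
            for p in meta.dfmt_patients():
                for tp in ("wk1", "wk2", "wk4"):
                    sid = meta.sample_of(p, tp)
                    profiled += sid is not None and sid in ds
        assert len(events) == profiled


def partition_metadata():
    rows = [
        ["DA_donor", "DA", "donor", "donor", "DA"],
        ["DB_donor", "DB", "donor", "donor", "DB"],
        ["P01_pre", "P01", "dfmt", "pre", "DA"],
        ["P01_wk1", "P01", "dfmt", "wk1", "DA"],
        ["P02_wk1", "P02", "dfmt", "wk1", "DA"],
        ["C01_pre", "C01", "pfmt", "control_pre", ""],
    ]
    return CohortMetadata(
        pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "role", "time_point", "donor_id"]
        )
    )


class TestSharingPartition:
    def test_within_patient_only(self):
        sets = [StrainDistanceSet("sp1", {("P01_pre", "P01_wk1"): 0.001})]
        part = sharing_partition(sets, partition_metadata())
        assert part.total == 1
        assert part.counts["within_patient_timepoints"] == 1
        assert part.percentages["within_patient_timepoints"] == 100.0

    def test_patient_vs_donor(self):
        sets = [StrainDistanceSet("sp1", {("DA_donor", "P01_wk1"): 0.001})]
        part = sharing_partition(sets, partition_metadata())
        assert part.counts["patient_vs_donor"] == 1

    def test_same_donor_patients(self):
        sets = [StrainDistanceSet("sp1", {("P01_wk1", "P02_wk1"): 0.001})]
        part = sharing_partition(sets, partition_metadata())
        assert part.counts["same_donor_patients"] == 1

    def test_precedence_within_patient_over_donor(self):
        d = {
            ("P01_pre", "P01_wk1"): 0.001,
            ("P01_pre", "DA_donor"): 0.001,
            ("P01_wk1", "DA_donor"): 0.001,
        }
        part = sharing_partition([StrainDistanceSet("sp1", d)], partition_metadata())
        assert part.counts["within_patient_timepoints"] == 1
        assert part.total == 1

    def test_precedence_is_configurable(self):
        d = {
            ("P01_pre", "P01_wk1"): 0.001,
            ("P01_pre", "DA_donor"): 0.001,
            ("P01_wk1", "DA_donor"): 0.001,
        }
        part = sharing_partition(
            [StrainDistanceSet("sp1", d)],
            partition_metadata(),
            precedence=("patient_vs_donor", "within_patient_timepoints"),
        )
        assert part.counts["patient_vs_donor"] == 1

    def test_empty_input_all_zero(self):
        part = sharing_partition([], partition_metadata())
        assert part.total == 0
        assert all(v == 0 for v in part.counts.values())

    def test_singleton_strains_excluded(self):
        sets = [StrainDistanceSet("sp1", {("P01_pre", "C01_pre"): 0.4})]
        part = sharing_partition(sets, partition_metadata())
        assert part.total == 0

    def test_clusters_are_connected_components(self):
        # chain A-B-C with A-C above threshold: one imposed 3-sample strain
        d = {
            ("P01_pre", "P01_wk1"): 0.009,
            ("P01_wk1", "P02_wk1"): 0.009,
            ("P01_pre", "P02_wk1"): 0.02,
        }
        clusters = strain_clusters(StrainDistanceSet("sp1", d))
        assert sorted(len(c) for c in clusters) == [3]

    def test_planted_partition_recovered_exactly(self, small_cohort):
        """With complete profiling the thresholded partition equals the
        partition computed from planted lineages directly."""
        part = sharing_partition(small_cohort.distance_sets, small_cohort.metadata)
        assert part.counts == planted_sharing_counts(small_cohort)


class TestTopEventSpecies:
    def events(self):
        return [
            StrainEvent("P01", "spX", "wk1", "donor_acquired"),
            StrainEvent("P02", "spX", "wk1", "donor_acquired"),
            StrainEvent("P03", "spX", "wk4", "donor_acquired"),
            StrainEvent("P01", "spY", "wk1", "donor_acquired"),
            StrainEvent("P01", "spY", "wk4", "donor_acquired"),
        ]

    def test_ranked_by_distinct_patients(self):
        assert top_event_species(self.events(), "donor_acquired") == [
            ("spX", 3),
            ("spY", 1),
        ]

    def test_patient_counted_once_across_visits(self):
        ranked = dict(top_event_species(self.events(), "donor_acquired"))
        assert ranked["spY"] == 1

    def test_ties_break_lexicographically(self):
        events = [
            StrainEvent("P01", "spB", "wk1", "retained_pre"),
            StrainEvent("P01", "spA", "wk1", "retained_pre"),
        ]
        assert top_event_species(events, "retained_pre") == [("spA", 1), ("spB", 1)]

    def test_no_events_and_unknown_label(self):
        assert top_event_species([], "replaced") == []
        with pytest.raises(ValueError):
            top_event_species([], "bogus")


class TestDistanceSetValidation:
    def test_incomplete_set_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            StrainDistanceSet("sp", {("A", "B"): 0.1, ("B", "C"): 0.1})

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            StrainDistanceSet("sp", {("A", "B"): -0.1})

    def test_matrix_round_trip(self):
        ds = StrainDistanceSet("sp", {("A", "B"): 0.1, ("B", "C"): 0.2, ("A", "C"): 0.3})
        back = StrainDistanceSet.from_matrix("sp", ds.to_matrix())
        assert back.distance("A", "C") == 0.3
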