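"""Strain-level engraftment tracking on a synthetic cohort.

Simulates a cohort with planted engraftment probability 0.6 and
retention probability 0.4 at complete strain profiling, classifies every
(patient, species, visit) strain observation, partitions multi-sample
strains by relationship class, and recovers the planted rates.
"""

from collections import Counter

from fmtrack import (
    SimParams,
    classify_events,
    estimate_engraftment_rates,
    sharing_partition,
    simulate_cohort,
    top_event_species,
)


def main():
    cohort = simulate_cohort(SimParams(seed=7, strain_profiling_prob=1.0))
    events = classify_events(cohort.distance_sets, cohort.metadata)

    print("event labels over", len(events), "classified (patient, species, visit):")
    for label, n in Counter(e.label for e in events).most_common():
        print(f"  {label:<18} {n}")

    part = sharing_partition(cohort.distance_sets, cohort.metadata)
    print(f"\n{part.total} strains present in more than one sample:")
    for cls, pct in part.percentages.items():
        print(f"  {cls:<26} {part.counts[cls]:>4}  ({pct:.1f}%)")

    rates = estimate_engraftment_rates(events, cohort.distance_sets, cohort.metadata)
    print(f"\nestimated engraftment rate: {rates['engraftment_rate']:.3f} "
          f"(planted 0.6, n={rates['n_engraftment_opportunities']})")
    print(f"estimated retention rate:   {rates['retention_rate']:.3f} "
          f"(planted 0.4, n={rates['n_retention_opportunities']})")

    print("\ntop species by patients acquiring the donor strain:")
    for sp, n in top_event_species(events, "donor_acquired")[:5]:
        print(f"  {sp:<10} {n} patients")
    print()
    print("donor_acquired/replaced events carry the donor's lineage into the")
    print("patient; retained_pre means the baseline strain persisted.  The")
    print("estimates recover the planted simulation rates.")


if __name__ == "__main__":
    main()
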