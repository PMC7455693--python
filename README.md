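# fmtrack

Clinical endpoint statistics and donor-strain engraftment tracking for
randomised faecal microbiota transplantation (FMT) trials.

`fmtrack` re-implements, as a tested and reusable pipeline, the complete
analysis of a two-arm trial of donor FMT (D-FMT) versus placebo FMT
(P-FMT) for tyrosine-kinase-inhibitor-induced diarrhoea: the exact
endpoint statistics computed from CTC diarrhoea grades, and the
quantification of donor-microbiome engraftment from species abundance
profiles and per-species strain phylogenies. It is aimed at microbiome
researchers who have MetaPhlAn-style species profiles and
StrainPhlAn-style strain trees (or distance matrices) for an FMT cohort
and want the full donor-engraftment readout without re-deriving the
statistics.

## What it computes

**Clinical endpoints.** Per follow-up visit, two binary endpoints from
CTC grades — *resolution* (grade 0) and *≤G1* (grade ≤ 1) — as 2×2
success/failure tables by arm, tested with the two-sided Fisher exact
test (minimum-likelihood rule: p = Σ point probabilities ≤ that of the
observed table) and Bonferroni-adjusted for the secondary outcomes
(`p_adj = min(1, m·p)`). A pooled-variance normal-approximation
sample-size routine for two proportions is included.

**Community convergence.** Pairwise Bray–Curtis dissimilarity
`1 − 2Σ min(a_s, b_s) / (Σa_s + Σb_s)` on species-level abundances, and
the shared-species fraction `|A∩B| / |A∪B|` on detected-species sets,
grouped into configurable donor/recipient/control comparison categories.

**Strain engraftment.** Normalised genetic distance (nGD) between two
samples on a species' strain phylogeny — patristic distance divided by
the tree's total branch length — with a same-strain call at nGD ≤ 0.01.
From these calls: per-pair shared-strain fractions, per
(patient, species, visit) transmission events (donor-acquired /
retained-pre / replaced / coincident-shared / not-callable), a partition
of multi-sample strains by relationship class, and species rankings by
engraftment evidence.

**Tests.** Two-sided Wilcoxon rank-sum per scheduled category pair
(exact by enumeration for small tie-free samples) and one-way PERMANOVA
(Anderson's pseudo-F, seeded permutation null) for the baseline group
comparison.

**Synthetic cohorts.** A generator that emulates the trial design
(2 donors, 10 treated patients at four time points, 10 controls at
baseline) with planted engraftment/retention probabilities and full
ground truth, so every stage can be validated against known answers.

## Worked example

`python examples/clinical_endpoints.py` builds the 20-subject cohort
from the trial's published per-visit outcome counts and prints:

```
visit endpoint    D-FMT  P-FMT     p_raw   p_adj  note
wk1   resolution   10/10    3/10   0.00310    0.02  m=7
wk1   le_G1        10/10    3/10   0.00310    0.02  m=7
wk2   resolution    9/10    0/10   0.00012  0.0008  m=7
wk2   le_G1        10/10    2/10   0.00071   0.005  m=7
wk4   resolution    7/10    0/10   0.00310   0.003  primary (unadjusted)
wk4   le_G1        10/10    2/10   0.00071   0.005  m=7
wk8   resolution    3/10    0/10   0.21053       1  m=7
wk8   le_G1         8/10    1/10   0.00548    0.04  m=7
```

Each row is one endpoint: successes out of 10 per arm, the raw
two-sided Fisher p, and the Bonferroni-adjusted value (the primary
outcome, week-4 resolution, is reported unadjusted). The primary p of
0.003 says 7/10 vs 0/10 cures would be very surprising if outcome were
independent of arm; week-8 resolution (3 vs 0) is compatible with
chance after adjustment.

The other examples cover the microbiome side on synthetic cohorts:
`donor_convergence.py` (Bray-Curtis/shared-species panels, rank-sum
tests, baseline PERMANOVA), `strain_engraftment.py` (event
classification, sharing partition, recovery of planted engraftment
0.6 / retention 0.4), and `simulate_fixtures.py` (fixture files for the
CLI).

## Command line

```
fmtrack simulate --out fixture/ --seed 1          # synthetic cohort fixture set
fmtrack run-all --fixture fixture/ --out bundle/  # full clinical + microbiome run
fmtrack report --bundle bundle/                   # human-readable summary
```

Single-stage subcommands (`clinical`, `community`, `strains`, `stats`)
run each analysis on its own inputs; `run-all --clinical-only` skips the
microbiome stages.

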