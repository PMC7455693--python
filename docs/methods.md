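# Methods

This note documents the statistical procedures, the modelling choices
behind the synthetic-cohort generator, and the numerical conventions
used throughout `fmtrack`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Clinical endpoint analysis

Diarrhoea severity is the NCI CTC v4.0 ordinal grade, derived from the
stool-frequency increase over pre-treatment and clinical flags
(`grade_from_symptoms` evaluates the criteria from most to least severe
and returns the first grade satisfied: intensive-care consequences → 4;
increase ≥ 7/day, incontinence or parenteral support → 3; increase
4–6/day or nocturnal stools → 2; any smaller increase → 1; none → 0).

Two endpoints are derived per follow-up visit (weeks 1, 2, 4, 8):
*resolution* (grade 0) and *≤G1* (grade ≤ 1). Each yields a 2×2
success/failure table by arm. A missing follow-up grade counts as
failure, the intention-to-treat convention (the emulated trial had no
dropouts, so the choice is inert there but matters for reuse).

Arm differences use the two-sided Fisher exact test under the
minimum-likelihood rule: with margins fixed, the p-value sums the
hypergeometric point probabilities of all tables whose point probability
does not exceed the observed one. This is the rule mainstream
implementations use; the computation is delegated to
`scipy.stats.fisher_exact` and validated in the test suite against an
exact rational-arithmetic enumeration oracle on every table with total
count ≤ 12.

The primary outcome (week-4 resolution) is reported unadjusted.
Secondary outcomes are Bonferroni-adjusted, `p_adj = min(1, m·p)`. The
multiplicity is exposed as a parameter with default **m = 7** (the seven
secondary outcomes: resolution at weeks 1/2/8 and ≤G1 at all four
visits). This default reproduces the adjusted values 0.02, 0.005, 0.04
and 1 from the trial's printed counts. The printed week-2 resolution
value 0.0007 is instead consistent with m = 6 (7 × 0.000119 = 0.00083
rounds to 0.0008, 6 × gives 0.00071): the original multiplicity is not
stated, so both readings are supported and the m = 6 variant is reported
alongside by the acceptance script.

The sample-size routine is the pooled-variance normal-approximation
formula for two proportions,

    n = ((z_{α/2}·√(2·p̄·q̄) + z_{power}·√(p₁q₁ + p₂q₂)) / (p₁ − p₂))²,

rounded up; at (0.80 vs 0.20, α = 0.05, power 0.80) it gives 10 per
group, the emulated design.

Printed-style p rounding (one significant figure below 0.01, two
decimals otherwise, bare "1" at the top) is applied only to report
columns; raw values are always retained alongside.

## Community metrics

Bray–Curtis dissimilarity is computed on the union of the two species
sets with absent species imputed as zero and **no renormalisation after
the union**; it is treated as a semimetric (bounds, symmetry and
coincidence are asserted; the triangle inequality is not). The
shared-species fraction defaults to Jaccard overlap of detected species
(union denominator) because it is symmetric like the distance panels it
accompanies; a `min-set` denominator is available for sensitivity
analysis. The detection threshold defaults to 0 (any positive abundance
counts) since upstream profilers already truncate trace abundances.

Comparison categories are configuration data, not code: each category
names two time-point roles and a pairing constraint (`cross`,
`same_donor_link`, `same_patient`). The default seven-category scheme —
donor vs control baseline, donor vs its recipients' pre/wk1/wk2/wk4,
within-patient pre-vs-post, control-vs-control — is one documented
reading of a panel layout whose exact labels the original figure text
does not state. Donor-vs-recipient pairs always use the recipient's
assigned donor.

## Strain engraftment

Normalised genetic distance (nGD) between two samples on a species'
strain tree is the patristic distance divided by the tree's **total
branch length** (default). Total-length normalisation is scale-free and
the standard reading in strain-sharing work; a `max_pairwise`
normalisation (divide by the tree diameter) is available. Trees and
square distance-matrix TSVs are interchangeable inputs.

The same-strain call is nGD ≤ 0.01 with an **inclusive** boundary
(configurable): "cutoff" language is ambiguous and inclusivity is the
convention adopted here. Strains across more than two samples are
connected components of the thresholded same-strain graph — pairwise
calls at a fixed cutoff need not be transitive, so transitivity is
imposed, not assumed.

Each (patient, species, post-FMT visit) with a strain-profiled post
sample receives exactly one event label, by ordered rules on the three
same-strain calls donor↔post, pre↔post, donor↔pre (each possibly
not-callable when a side is unprofiled):

1. all three callable and true → `coincident_shared` (donor and patient
   already carried indistinguishable strains; kept as its own class so
   the partition classes stay mutually exclusive);
2. pre↔post true → `retained_pre`;
3. donor↔post true and the pre sample profiled → `replaced`;
4. donor↔post true, no pre profile → `donor_acquired`;
5. otherwise → `not_callable`.

Species/sample combinations not profiled at the strain level are
excluded from every denominator, so transmission estimates are lower
bounds — strain-level profiling systematically underestimates sharing.

Multi-sample strains are partitioned by relationship class with
configurable precedence, default: within one treated patient across
time points > patient-with-its-own-donor > distinct patients sharing a
donor > other. The "same donor" class is read as patient-to-patient
sharing through a common donor (not donor-sample replicates).

`estimate_engraftment_rates` estimates the per-opportunity engraftment
rate (donor strain present in post sample, given the donor was profiled
for the species) and retention rate (pre strain persisting, given a
profiled pre sample and no donor take-over). Both are unbiased under
complete strain profiling and conservative otherwise.

## Distribution-level tests

The rank-sum test is two-sided Wilcoxon/Mann-Whitney: exact by full
enumeration of the U null when the combined sample size is ≤ 12 with no
ties, otherwise the normal approximation with tie and continuity
correction. The switch point balances enumeration cost against accuracy;
at 6+6 the corrected approximation tracks the exact p to within ~0.016.
Pairwise-distance observations are treated as independent in these
tests even though pairs sharing a sample are dependent — this replicates
the analysis convention of the trial being emulated and is a known
caveat, not corrected here (dependency-aware models are out of scope).

PERMANOVA uses Anderson's pseudo-F from the within/among decomposition
of squared distances,

    F = (SS_A / (a − 1)) / (SS_W / (n − a)),   SS_T = Σ_{i<j} d²_ij / n,
    SS_W = Σ_g Σ_{i<j∈g} d²_ij / n_g,

with p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm) over a seeded
permutation stream (default n_perm = 999; the seed is mandatory in the
pipeline). Samples are put in canonical sorted-id order before
permuting, so results are invariant to input ordering at a fixed seed.
Perfect within-group coincidence yields F = ∞; permutations recreating
the same partition tie with it and are counted, as in any standard
implementation. The baseline comparison runs on Bray–Curtis over
species abundances of treated-arm pre-FMT vs control baseline samples.

## Synthetic cohorts

The generator plants every quantity the pipeline later estimates:

* **Communities**: independent log-normal abundance vectors (log-mean 0,
  log-sd 2 — heavy-tailed, as real species-abundance distributions are)
  over a shared species pool with per-community occupancy 0.6, then
  renormalised to 100%. Partial occupancy keeps the shared-species
  metric informative.
* **Post-FMT communities**: convex mixtures w·donor + (1−w)·pre with one
  weight per patient, w ~ U(0.4, 0.8) by default — substantial but
  incomplete convergence. Sweeping fixed weights {0, 0.25, …, 1} drives
  the monotonicity check on mean donor-recipient Bray–Curtis.
* **Strain lineages**: one abstract lineage per donor and per patient
  baseline, all pairwise distinct (donor-donor lineages always differ, so
  the two-donor design stays distinguishable). Per (patient, species,
  visit): the donor lineage takes over with probability
  p_e·decay^(week−1) (defaults p_e = 0.6, decay = 1 — engraftment that
  persists through week 4); otherwise the baseline strain is retained
  with probability p_r = 0.4. Take-over with a pre-existing strain is
  planted as `replaced`, without one as `donor_acquired`. p_e > p_r
  mirrors a cohort where more post-FMT strains trace to the donor than
  to the baseline.
* **Distances**: same-lineage pairs draw nGD ~ U(0, 0.005), cross-lineage
  pairs ~ U(0.05, 0.5). The bands straddle the 0.01 cutoff with margin,
  so thresholded clusters recover lineages exactly and the planted
  partition is recovered bit-exactly at full profiling.
* **Profiling dropout**: each species/sample combination is profiled
  with probability 0.7, emulating incomplete StrainPhlAn coverage.
* **Clinical grades**: simple plausible trajectories (treated arm mostly
  resolving, control arm mostly persisting) so end-to-end runs exercise
  the clinical stage; they are plumbing, not calibrated to any trial.

One RNG stream per stage is spawned from the master seed, so rerunning a
stage cannot perturb the others and fixture sets are byte-identical
across runs at a fixed seed.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: read-level noise and profiler error,
phylogenetic models of marker evolution (distances are drawn, not
evolved, and need not be tree-metric), ecological dynamics between
species, compositional correlation structure, or multi-strain mixtures
within one sample (each sample carries at most one lineage per species,
the dominant-strain abstraction). Results on synthetic cohorts validate
the *pipeline logic*, not profiler accuracy.

## Problem sizes and numerical conventions

Default analyses run at 200 species × 52 samples; parameter-recovery
checks average 20 independent cohorts at complete profiling, and
PERMANOVA calibration uses 1000 null data sets (20 samples, 199
permutations each) — sizes chosen so the whole suite validates the
estimators' behaviour while remaining quick to run on a laptop.
Distance matrices are written at full float precision (round-trip
exact); abundances and metric columns at 6 decimals. Matrix asymmetries
up to 1e-9 are symmetrised on read, larger ones rejected. Degenerate
inputs (all-zero tables or profiles, empty cohorts, zero-length trees,
pairs with no co-profiled species) raise or return a documented
not-callable sentinel rather than silently producing numbers.

## Known limitations

* The rank-sum panel ignores dependence between pairs sharing a sample
  (faithful-replication caveat above).
* Strain identity is a hard threshold on a single distance; borderline
  nGD values flip calls, and connected-component clustering can chain
  borderline pairs.
* The event classifier cannot distinguish `coincident_shared` from
  acquisition or retention when donor and patient strains were already
  indistinguishable at baseline; it is reported as its own class.
* Deposited-cohort quantities (total comparison counts, the published
  sharing percentages) depend on the original sequencing data and
  profiler runs and are not reproduced by the synthetic cohorts.
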