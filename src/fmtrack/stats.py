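"""Distribution-level hypothesis tests for pairwise-metric panels.

Two tests cover every comparison in the analysis:

* two-sided Wilcoxon rank-sum (Mann-Whitney) between the metric
  distributions of two comparison categories - exact by enumeration for
  small tie-free samples, normal approximation with tie and continuity
  correction otherwise;
* PERMANOVA (ADONIS) on a distance matrix for the baseline group
  comparison, using Anderson's pseudo-F and a seeded label-permutation
  null.

Pairwise distance observations are treated as independent in the
rank-sum tests even though pairs sharing a sample are dependent; this
replicates the original analysis convention and is documented as a
caveat rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

#: Largest combined sample size for which the exact rank-sum null is used.
EXACT_MAX_N = 12


def wilcoxon_rank_sum_two_sided(x, y, exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration of the U null distribution when the combined sample
    size is at most ``exact_max_n`` and there are no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = _sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


@dataclass
class PermanovaResult:
    """Pseudo-F with its permutation p-value and reproducibility settings."""

    pseudo_F: float
    p: float
    n_perm: int
    seed: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    ss_among = ss_total - ss_within
    if ss_within == 0.0:
        return float("inf")  # perfect within-group coincidence
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dmatrix,
    labels: Sequence,
    n_perm: int = 999,
    seed: int = 0,
    sample_ids: Optional[Sequence[str]] = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a square distance matrix (Anderson's method).

    Pseudo-F is computed from the within/among sum-of-squares
    decomposition of squared distances; the p-value is
    ``(1 + #{permuted F >= observed F}) / (1 + n_perm)`` over a seeded
    permutation stream.  When ``sample_ids`` are supplied (or ``dmatrix``
    is a labelled DataFrame) samples are first put in canonical sorted-id
    order, so the result is invariant to input ordering at a fixed seed.
    """
    if isinstance(dmatrix, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(dmatrix.index)
        dmatrix = dmatrix.to_numpy(dtype=float)
    d = np.asarray(dmatrix, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have zero diagonal")
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError("one group label per sample required")
    if sample_ids is not None:
        order = np.argsort(np.asarray(sample_ids))
        d = d[np.ix_(order, order)]
        labels = labels[order]
    groups, codes = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if np.bincount(codes).min() < 2:
        raise ValueError("every group needs at least two samples")

    d2 = d ** 2
    f_obs = _pseudo_f(d2, codes, len(groups))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(d2, codes[perm], len(groups)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_F=float(f_obs), p=float(p), n_perm=n_perm, seed=seed)


#: Default panel test schedule (seven rank-sum tests per metric panel):
#: each donor-recipient visit category against the donor-vs-control
#: reference, the post-FMT visits against the pre-FMT donor distance, and
#: the within-patient shift against the control-control background.
DEFAULT_PANEL_TESTS = (
    ("donor_vs_pre", "donor_vs_control_pre"),
    ("donor_vs_wk1", "donor_vs_control_pre"),
    ("donor_vs_wk2", "donor_vs_control_pre"),
    ("donor_vs_wk4", "donor_vs_control_pre"),
    ("donor_vs_wk1", "donor_vs_pre"),
    ("donor_vs_wk4", "donor_vs_pre"),
    ("pre_vs_post", "control_vs_control"),
)


@dataclass
class CategoryTest:
    """One scheduled category-vs-category rank-sum test."""

    category_a: str
    category_b: str
    n_a: int
    n_b: int
    p: float


def compare_categories(
    values: Mapping[str, Sequence[float]],
    scheme: Sequence[Tuple[str, str]] = DEFAULT_PANEL_TESTS,
) -> List[CategoryTest]:
    """Run the scheduled two-sided rank-sum tests on grouped metric values.

    Output order matches scheme order.  A category absent from ``values``
    (or empty) raises.
    """
    out = []
    for cat_a, cat_b in scheme:
        for cat in (cat_a, cat_b):
            if cat not in values or len(values[cat]) == 0:
                raise KeyError(f"category {cat!r} missing or empty")
        x, y = values[cat_a], values[cat_b]
        out.append(
            CategoryTest(
                category_a=cat_a,
                category_b=cat_b,
                n_a=len(x),
                n_b=len(y),
                p=wilcoxon_rank_sum_two_sided(x, y),
            )
        )
    return out
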