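"""Independent brute-force oracles used to validate the fast paths.

Everything here is deliberately naive: exact rational arithmetic and
full enumeration, kept free of the implementation code it checks.
"""

from __future__ import annotations

import random as _pyrandom
from fractions import Fraction
from itertools import combinations
from math import comb

import dendropy
import networkx as nx
import numpy as np
from dendropy.simulate import treesim


def fisher_two_sided_oracle(table) -> Fraction:
    """Minimum-likelihood two-sided Fisher p by full table enumeration.

    Sums the exact hypergeometric point probabilities of every table
    sharing the observed margins whose point probability is <= that of
    the observed table.  Exact rational arithmetic throughout.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = comb(n, c1)

    def point(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs)


def wilcoxon_exact_distribution(n: int, m: int):
    """Exact null distribution of U_x over all C(n+m, n) rank splits.

    Returns a sorted numpy array of U values (one per split).
    """
    ranks = range(1, n + m + 1)
    offset = n * (n + 1) // 2
    return np.sort([sum(s) - offset for s in combinations(ranks, n)])


def wilcoxon_two_sided_oracle(x, y) -> Fraction:
    """Two-sided exact rank-sum p: 2 * min(tail probabilities), capped at 1."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - len(x) * (len(x) + 1) // 2
    dist = wilcoxon_exact_distribution(len(x), len(y))
    total = len(dist)
    lo = int((dist <= u_obs).sum())
    hi = int((dist >= u_obs).sum())
    p = 2 * Fraction(min(lo, hi), total)
    return min(p, Fraction(1))


def wilcoxon_p_of_u(u: int, n: int, m: int) -> Fraction:
    """Two-sided exact p as a function of the U statistic alone."""
    dist = wilcoxon_exact_distribution(n, m)
    total = len(dist)
    lo = int((dist <= u).sum())
    hi = int((dist >= u).sum())
    return min(2 * Fraction(min(lo, hi), total), Fraction(1))


def random_strain_tree(seed: int, n_leaves: int) -> dendropy.Tree:
    """Random birth-death topology with uniform random branch lengths."""
    rng = np.random.default_rng(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        rng=_pyrandom.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"L{i}"
    for edge in tree.edges():
        edge.length = float(rng.uniform(0.05, 2.0)) if edge.tail_node is not None else 0.0
    return tree


def ngd_path_oracle(tree: dendropy.Tree, leaf_a: str, leaf_b: str) -> float:
    """nGD by explicit shortest-path traversal of the tree graph."""
    g = nx.Graph()
    total = 0.0
    for edge in tree.edges():
        if edge.tail_node is None:
            continue
        w = edge.length or 0.0
        total += w
        g.add_edge(id(edge.tail_node), id(edge.head_node), weight=w)
    leaves = {
        leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()
    }
    path_len = nx.shortest_path_length(
        g, leaves[leaf_a], leaves[leaf_b], weight="weight"
    )
    return path_len / total
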