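"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by brute force (enumeration, closed
form, or rational arithmetic) without touching the implementation path it
is used to check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, inf

import numpy as np

GAP = "-"


# --- pruning likelihood ---------------------------------------------------

def enumerate_loglik(tree, traits, Q, root_prior=None):
    """Likelihood by explicit summation over all internal-node states.

    Walks the dendropy tree; every node (internal and tip) gets a state
    assignment, tips restricted to the states their (possibly missing)
    trait pair allows; probabilities multiply along edges via expm(Q t).
    """
    from scipy.linalg import expm

    dtree = tree.dendropy_tree
    nodes = list(dtree.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    P = {}
    for n in nodes[1:]:
        P[id(n)] = expm(Q * float(n.edge.length))
    allowed = []
    for n in nodes:
        if n.is_leaf():
            x, y = traits[n.taxon.label]
            allowed.append([s for s in range(4)
                            if (x is None or (s >> 1) == x)
                            and (y is None or (s & 1) == y)])
        else:
            allowed.append(list(range(4)))
    prior = np.full(4, 0.25) if root_prior is None else np.asarray(root_prior)
    total = 0.0
    for assign in itertools.product(*allowed):
        p = prior[assign[0]]
        for n in nodes[1:]:
            p *= P[id(n)][assign[idx[id(n.parent_node)]], assign[idx[id(n)]]]
        total += p
    return np.log(total)


# --- semi-global alignment ------------------------------------------------

def brute_force_semiglobal_score(a, b, matrix, gap_open, gap_extend):
    """Best end-gap-free global alignment score by enumerating all
    monotone alignments (gap length k costs open + (k-1)*extend when
    internal, 0 when terminal in its own sequence)."""
    la, lb = len(a), len(b)
    best = -inf

    def score_moves(moves):
        # strip the leading and trailing gap runs: they are terminal in
        # their own sequence and therefore free
        start = 0
        if moves and moves[0] != "M":
            while start < len(moves) and moves[start] == moves[0]:
                start += 1
        end = len(moves)
        if end > start and moves[-1] != "M":
            while end > start and moves[end - 1] == moves[-1]:
                end -= 1
        s = 0.0
        i = j = 0
        # advance through the stripped leading run
        for m in moves[:start]:
            if m == "A":
                j += 1
            else:
                i += 1
        prev = None
        for m in moves[start:end]:
            if m == "M":
                s += matrix[a[i], b[j]]
                i += 1
                j += 1
            elif m == "A":  # gap in a, consumes b
                s += gap_extend if prev == "A" else gap_open
                j += 1
            else:  # gap in b, consumes a
                s += gap_extend if prev == "B" else gap_open
                i += 1
            prev = m
        return s

    def rec(i, j, moves):
        nonlocal best
        if i == la and j == lb:
            best = max(best, score_moves(moves))
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, moves + ["M"])
        if j < lb:
            rec(i, j + 1, moves + ["A"])
        if i < la:
            rec(i + 1, j, moves + ["B"])

    rec(0, 0, [])
    return best


# --- Fisher exact ---------------------------------------------------------

def fisher_two_sided_exact(a, b, c, d) -> float:
    """Two-sided Fisher p by rational hypergeometric enumeration
    (point-probability method: sum pmf(x) <= pmf(observed))."""
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def pmf(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p0 = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum((px for x in range(lo, hi + 1) if (px := pmf(x)) <= p0),
                Fraction(0))
    return float(total)


# --- rank-sum -------------------------------------------------------------

def ranksum_two_sided_exact(g1, g2) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments
    (tie-free inputs only)."""
    pooled = sorted(list(g1) + list(g2))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(g1)
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    r_obs = sum(ranks[v] for v in g1)
    dist = [sum(combo) for combo in itertools.combinations(range(1, len(pooled) + 1), n1)]
    n_tot = len(dist)
    p_le = sum(r <= r_obs for r in dist) / n_tot
    p_ge = sum(r >= r_obs for r in dist) / n_tot
    return min(1.0, 2.0 * min(p_le, p_ge))


# --- trees ----------------------------------------------------------------

def tip_path_distances(tree) -> dict[frozenset, float]:
    """All tip-to-tip path lengths of a Phylogeny, keyed by label pair."""
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in pdm.taxon_iter():
        for t2 in pdm.taxon_iter():
            if t1.label < t2.label:
                out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


def grid_search_rate(f, lo, hi, n_coarse=200, n_fine=2000):
    """Two-stage 1-D grid maximization of f over [lo, hi] (log grid)."""
    grid = np.geomspace(lo, hi, n_coarse)
    vals = [f(q) for q in grid]
    k = int(np.argmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_coarse - 1)]
    fine = np.linspace(a, b, n_fine)
    fvals = [f(q) for q in fine]
    j = int(np.argmax(fvals))
    return float(fine[j]), float(fvals[j])
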