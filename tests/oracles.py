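"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (double loops, exhaustive
enumeration, direct formulas) and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from teconet.network import _matrix_form


def naive_correlations(expr, genes, tes, samples):
    """Double-loop Pearson r via scipy.stats.pearsonr."""
    out = {}
    sub = expr[list(samples)]
    for g in genes:
        for t in tes:
            out[(g, t)] = stats.pearsonr(
                sub.loc[g].to_numpy(), sub.loc[t].to_numpy()
            ).statistic
    return out


def bh_step_up(p):
    """Hand application of the Benjamini-Hochberg step-up rule."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(1.0, p[idx] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted


def exhaustive_barber_best(net) -> float:
    """Maximum Barber modularity over every set partition of the nodes
    (restricted-growth-string enumeration; feasible to ~10 nodes)."""
    genes, tes, A = _matrix_form(net)
    m = A.sum()
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    ng = len(genes)
    n = ng + len(tes)
    best = [-np.inf]
    labels = [0] * n

    def q_of() -> float:
        q = 0.0
        for c in set(labels):
            sel = [i for i, lab in enumerate(labels) if lab == c]
            gs = [i for i in sel if i < ng]
            ts = [i - ng for i in sel if i >= ng]
            if gs and ts:
                q += A[np.ix_(gs, ts)].sum() - k[gs].sum() * d[ts].sum() / m
        return q / m

    def rec(i: int, max_label: int) -> None:
        if i == n:
            best[0] = max(best[0], q_of())
            return
        for lab in range(max_label + 1):
            labels[i] = lab
            rec(i + 1, max(max_label, lab + 1))

    rec(0, 0)
    return best[0]


def exact_two_by_k_chi2_p(table: np.ndarray) -> float:
    """Exact p-value of the chi-squared statistic for a 2 x k table
    under fixed margins, by full enumeration of the first row
    (multivariate hypergeometric null)."""
    from itertools import product
    from math import comb

    table = np.asarray(table, dtype=int)
    row1 = int(table[0].sum())
    cols = table.sum(axis=0)
    total = int(table.sum())
    expected = np.outer(table.sum(axis=1), cols) / total
    obs_chi2 = float(((table - expected) ** 2 / expected).sum())

    denom = comb(total, row1)
    p = 0.0
    ranges = [range(0, min(row1, c) + 1) for c in cols]
    for cells in product(*ranges):
        if sum(cells) != row1:
            continue
        prob = 1.0
        for a, c in zip(cells, cols):
            prob *= comb(int(c), a)
        prob /= denom
        cand = np.vstack([cells, cols - np.asarray(cells)])
        chi2 = float(((cand - expected) ** 2 / expected).sum())
        if chi2 >= obs_chi2 - 1e-12:
            p += prob
    return p


def random_bipartite_network(rng, max_nodes: int = 10):
    """A random small weighted bipartite network for oracle tests."""
    from teconet.network import BipartiteNetwork

    ng = int(rng.integers(2, 6))
    nt = int(rng.integers(2, min(max_nodes - ng, 6) + 1))
    genes = [f"g{i}" for i in range(ng)]
    tes = [f"t{i}" for i in range(nt)]
    edges = []
    for g in genes:
        for t in tes:
            if rng.random() < 0.45:
                sign = 1 if rng.random() < 0.7 else -1
                edges.append(
                    (g, t, {"r": float(sign * rng.uniform(0.4, 1.0))})
                )
    if not edges:
        edges.append((genes[0], tes[0], {"r": 0.5}))
    return BipartiteNetwork(set(genes), set(tes), edges)
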