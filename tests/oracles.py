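"""Independent reference implementations used to check the package.

These deliberately use brute force (grid search, exhaustive enumeration,
graph shortest paths) and share no code with the implementations they test.
"""

from __future__ import annotations

import numpy as np


def grid_em_mle(counts: np.ndarray, step: float = 1e-3) -> tuple[np.ndarray, float]:
    """Grid-search ML two-locus haplotype frequencies.

    Marginal allele frequencies are fixed at their sample values (the MLE
    preserves them); the single free parameter f_AB is scanned over its
    feasible interval at ``step`` resolution.
    """
    counts = np.asarray(counts, dtype=float)
    two_n = 2 * counts.sum()
    pA = (2 * counts[2].sum() + counts[1].sum()) / two_n
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / two_n
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    grid = np.unique(np.concatenate([np.arange(lo, hi, step), [lo, hi]]))

    best_f, best_ll = None, -np.inf
    for fAB in grid:
        f = np.array([fAB, pA - fAB, pB - fAB, 1 - pA - pB + fAB])
        if (f < -1e-12).any():
            continue
        f = np.clip(f, 0, None)
        probs = np.array(
            [
                [f[3] ** 2, 2 * f[2] * f[3], f[2] ** 2],
                [2 * f[1] * f[3], 2 * (f[0] * f[3] + f[1] * f[2]), 2 * f[0] * f[2]],
                [f[1] ** 2, 2 * f[0] * f[1], f[0] ** 2],
            ]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts * np.log(probs)
        ll = terms[counts > 0].sum()
        if ll > best_ll:
            best_ll, best_f = ll, f
    return best_f, float(best_ll)


def random_genotype_table(rng: np.random.Generator, max_total: int = 40) -> np.ndarray:
    """Random polymorphic 3×3 genotype table from random haplotype frequencies."""
    while True:
        f = rng.dirichlet(np.full(4, 0.8))
        n = int(rng.integers(4, max_total + 1))
        probs = np.array(
            [
                [f[3] ** 2, 2 * f[2] * f[3], f[2] ** 2],
                [2 * f[1] * f[3], 2 * (f[0] * f[3] + f[1] * f[2]), 2 * f[0] * f[2]],
                [f[1] ** 2, 2 * f[0] * f[1], f[0] ** 2],
            ]
        ).ravel()
        counts = rng.multinomial(n, probs).reshape(3, 3)
        two_n = 2 * n
        alt_a = 2 * counts[2].sum() + counts[1].sum()
        alt_b = 2 * counts[:, 2].sum() + counts[:, 1].sum()
        if 0 < alt_a < two_n and 0 < alt_b < two_n:
            return counts


def brute_force_spine(dp: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Greedy maximal solid-spine intervals via exhaustive validity checks."""

    def valid(i: int, j: int) -> bool:
        for k in range(i + 1, j + 1):
            if not dp[i, k] >= threshold:  # NaN-safe: comparison is False
                return False
        for k in range(i, j):
            if not dp[k, j] >= threshold:
                return False
        return True

    m = dp.shape[0]
    out = []
    i = 0
    while i < m - 1:
        ends = [j for j in range(i + 1, m) if valid(i, j)]
        if ends:
            out.append((i, max(ends)))
            i = max(ends) + 1
        else:
            i += 1
    return out


def random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """Distance matrix of a random weighted binary tree (leaf path lengths).

    Built by random agglomeration; distances computed by graph shortest
    paths, fully independent of any NJ code.
    """
    import networkx as nx

    g = nx.Graph()
    labels = [f"t{i}" for i in range(n_taxa)]
    active = list(labels)
    nxt = 0
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        node = f"i{nxt}"
        nxt += 1
        g.add_edge(a, node, weight=float(rng.uniform(0.1, 2.0)))
        g.add_edge(b, node, weight=float(rng.uniform(0.1, 2.0)))
        active = [x for x in active if x not in (a, b)] + [node]
    dist = np.zeros((n_taxa, n_taxa))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            dist[i, j] = paths[a][b]
    dist = 0.5 * (dist + dist.T)  # remove float summation-order asymmetry
    np.fill_diagonal(dist, 0.0)
    return labels, dist


def tree_leaf_distances(tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of an skbio TreeNode."""
    n = len(labels)
    out = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = tips[a].distance(tips[b])
                out[i, j] = out[j, i] = d
    return out
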