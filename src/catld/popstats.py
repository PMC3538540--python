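"""Population-genetic summaries: heterozygosity, Tajima's D, F_st, NJ tree.

All statistics work directly on unphased genotype codes.

* Ho/He/F_is per population × region, with He carrying the small-sample
  correction 2n/(2n−1) and F_is = 1 − Ho/He.
* Tajima's D per region from allele frequencies (π is phase-free) with the
  canonical 1989 normalising constants; monomorphic regions are undefined.
* Pairwise F_st by the Hudson ratio-of-averages moment estimator — a
  deliberate, documented substitute for model-based differentiation
  estimates; it feeds a distance matrix, not absolute F_st claims.
* Neighbor-joining (Saitou–Nei) on the F_st matrix, with deterministic
  label-order tie-breaking and negative branch lengths clamped to zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import TreeNode

from .genotype_io import MISSING, GenotypeDataset, _per_snp_stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity_fis(ds: GenotypeDataset) -> tuple[float, float, float]:
    """(Ho, He, F_is) for one population's dataset (typically one region).

    Per SNP: ho = fraction heterozygous among called individuals;
    he = 2p(1−p) · 2n_c/(2n_c−1).  Ho and He are means over SNPs with at
    least one call (monomorphic SNPs contribute zero to both, which leaves
    F_is = 1 − Ho/He unchanged).  F_is is NaN when He = 0.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    called = ds.calls != MISSING
    n_c = called.sum(axis=0)
    use = n_c > 0
    if not use.any():
        raise ValueError("no called genotypes")
    het = ((ds.calls == 1) & called).sum(axis=0)
    _, p, _ = _per_snp_stats(ds.calls)
    ho = het[use] / n_c[use]
    pp = p[use]
    nn = n_c[use]
    he = 2 * pp * (1 - pp) * (2 * nn / (2 * nn - 1))
    Ho = float(ho.mean())
    He = float(he.mean())
    Fis = 1.0 - Ho / He if He > 0 else float("nan")
    return Ho, He, Fis


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajimas_d(ds: GenotypeDataset) -> float:
    """Tajima's D over the dataset's SNPs; NaN when no site segregates.

    Sequences are the 2n chromosomes of n diploid individuals.  π is the
    frequency-based unbiased pairwise diversity Σ 2p(1−p)·m/(m−1) with
    m = 2n sequences, θ_W = S/a₁, and the variance uses the canonical
    constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂.  Per-site allele frequencies
    come from called genotypes; the constants use the full sample size.
    """
    m = 2 * ds.n_samples  # sequences
    if m < 4:
        raise ValueError("Tajima's D needs at least 4 sequences (2 diploids)")
    _, p, n_called = _per_snp_stats(ds.calls)
    seg = (~np.isnan(p)) & (p > 0) & (p < 1)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi = float(np.sum(2 * p[seg] * (1 - p[seg])) * m / (m - 1))

    a1 = np.sum(1.0 / np.arange(1, m))
    a2 = np.sum(1.0 / np.arange(1, m) ** 2)
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - theta_w) / np.sqrt(var))


def population_region_summary(ds: GenotypeDataset) -> pd.DataFrame:
    """Ho/He/F_is and Tajima's D for every population × region."""
    rows = []
    for pop in ds.populations:
        sub = ds.for_population(pop)
        for (chrom, region), grp in sub.snps.groupby(["chrom", "region"], sort=False):
            reg = sub.take_snps(grp.index.to_numpy())
            try:
                Ho, He, Fis = heterozygosity_fis(reg)
            except ValueError:
                Ho = He = Fis = float("nan")
            try:
                D = tajimas_d(reg)
            except ValueError:
                D = float("nan")
            rows.append(
                {"population": pop, "region": region, "chrom": chrom,
                 "Ho": Ho, "He": He, "Fis": Fis, "TajD": D}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# F_st
# ---------------------------------------------------------------------------

def _freqs_and_counts(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    _, p, n_called = _per_snp_stats(ds.calls)
    return p, n_called


def pairwise_fst(dsA: GenotypeDataset, dsB: GenotypeDataset) -> float:
    """Hudson-type ratio-of-averages F_st between two populations.

    Per SNP: num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) and
    den = p₁(1−p₂) + p₂(1−p₁), with nᵢ the called diploid individuals;
    F_st = Σnum / Σden.  SNPs monomorphic in both populations, or with
    fewer than two called individuals in either, are skipped.
    """
    if not (dsA.snps.snp_id.to_numpy() == dsB.snps.snp_id.to_numpy()).all():
        raise ValueError("populations must share the same SNP panel")
    p1, n1 = _freqs_and_counts(dsA)
    p2, n2 = _freqs_and_counts(dsB)
    ok = (~np.isnan(p1)) & (~np.isnan(p2)) & (n1 >= 2) & (n2 >= 2)
    both_mono = ((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1))
    use = ok & ~both_mono
    if not use.any():
        raise ValueError("no usable SNPs for F_st")
    p1, p2, n1, n2 = p1[use], p2[use], n1[use], n2[use]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def fst_matrix(ds: GenotypeDataset) -> pd.DataFrame:
    """Symmetric pairwise F_st matrix over all populations (diagonal 0).

    Values are clipped to [0, 1]; out-of-range raw values are logged.
    """
    pops = ds.populations
    subs = {p: ds.for_population(p) for p in pops}
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            v = pairwise_fst(subs[a], subs[b])
            if not 0.0 <= v <= 1.0:
                logger.info("F_st(%s, %s) = %.4g clipped into [0, 1]", a, b, v)
            v = min(max(v, 0.0), 1.0)
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Canonical Saitou–Nei neighbor joining on a symmetric distance matrix.

    Q-matrix minimisation with deterministic tie-breaking by sorted label
    pair; branch lengths from the standard formulas, negatives clamped to 0
    (logged).  Returns an unrooted ``skbio.TreeNode`` (trifurcating root).
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    D = dist.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")

    def clamp(x: float, a: str, b: str) -> float:
        if x < 0:
            logger.info("negative branch length %.4g on (%s, %s) clamped to 0", x, a, b)
            return 0.0
        return x

    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    active = list(labels)
    Dw = pd.DataFrame(D, index=labels, columns=labels)

    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {i: sum(Dw.loc[i, k] for k in active if k != i) for i in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                q = (n - 2) * Dw.loc[a, b] - r[a] - r[b]
                key = (q, *sorted((str(a), str(b))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        la = 0.5 * Dw.loc[a, b] + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = Dw.loc[a, b] - la
        la, lb = clamp(la, a, b), clamp(lb, b, a)
        new = f"__nj{counter}"
        counter += 1
        parent = TreeNode(name=None)
        nodes[a].length = la
        nodes[b].length = lb
        parent.extend([nodes[a], nodes[b]])
        nodes[new] = parent
        for k in active:
            if k in (a, b):
                continue
            Dw.loc[new, k] = Dw.loc[k, new] = 0.5 * (
                Dw.loc[a, k] + Dw.loc[b, k] - Dw.loc[a, b]
            )
        Dw.loc[new, new] = 0.0
        active = [k for k in active if k not in (a, b)] + [new]

    a, b, c = active
    la = 0.5 * (Dw.loc[a, b] + Dw.loc[a, c] - Dw.loc[b, c])
    lb = 0.5 * (Dw.loc[a, b] + Dw.loc[b, c] - Dw.loc[a, c])
    lc = 0.5 * (Dw.loc[a, c] + Dw.loc[b, c] - Dw.loc[a, b])
    root = TreeNode(name=None)
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lab].length = clamp(ln, lab, "root")
        root.append(nodes[lab])
    return root


def tree_to_newick(tree: TreeNode) -> str:
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Feature correlation
# ---------------------------------------------------------------------------

def feature_correlation(extents, features) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) of LD extent vs a genomic feature."""
    x = np.asarray(extents, dtype=float)
    y = np.asarray(features, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
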