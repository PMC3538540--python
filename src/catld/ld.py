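"""Two-locus haplotype frequency estimation (EM) and pairwise LD statistics.

Genotypes are unphased, so the joint 3×3 table of genotype counts at two
biallelic loci determines haplotype counts exactly for every cell except the
double heterozygote, whose two resolutions (coupling AB/ab vs repulsion Ab/aB)
are split by expectation–maximisation under random mating.  This composite
direct-counting + EM estimator is the standard unphased two-locus MLE.

From the fitted haplotype frequencies we report the classical measures

    D   = f_AB − p_A·p_B
    r²  = D² / (p_A(1−p_A) p_B(1−p_B))
    D′  = D / D_max  with the usual sign-dependent D_max

per unordered SNP pair, on the pairwise-complete individuals.  Inter-
chromosomal ("background") LD — the empirical null for unlinked loci — is the
plain mean of r² over all cross-chromosome pairs.

The EM is vectorised across pairs (the per-pair state is just four
frequencies), which keeps region-scale all-pairs scans fast without changing
the per-pair algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

EM_TOL = 1e-10
EM_MAX_ITER = 10_000
#: double-heterozygote coupling fractions used as EM starting points; the
#: balanced start plus two biased restarts to escape the symmetric ridge
EM_STARTS = (0.5, 0.9, 0.1)


class MonomorphicError(ValueError):
    """LD is undefined when either locus is monomorphic in the usable data."""


@dataclass
class HaplotypeFreqs2:
    """ML haplotype frequencies for two biallelic loci (A/a × B/b)."""

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    loglik: float
    n_iter: int
    converged: bool
    note: str = ""

    @property
    def p_A(self) -> float:
        return self.f_AB + self.f_Ab

    @property
    def p_B(self) -> float:
        return self.f_AB + self.f_aB


# ---------------------------------------------------------------------------
# Batch EM over many 3×3 tables
# ---------------------------------------------------------------------------

def _loglik(counts: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of genotype tables under random mating.

    ``counts``: (..., 3, 3) with axis order (genotype at A, genotype at B),
    genotype = alt-allele count.  ``f``: (..., 4) = (f_AB, f_Ab, f_aB, f_ab).
    """
    fAB, fAb, faB, fab = f[..., 0], f[..., 1], f[..., 2], f[..., 3]
    probs = np.empty(counts.shape, dtype=float)
    probs[..., 2, 2] = fAB**2
    probs[..., 2, 1] = 2 * fAB * fAb
    probs[..., 2, 0] = fAb**2
    probs[..., 1, 2] = 2 * fAB * faB
    probs[..., 1, 1] = 2 * (fAB * fab + fAb * faB)
    probs[..., 1, 0] = 2 * fAb * fab
    probs[..., 0, 2] = faB**2
    probs[..., 0, 1] = 2 * faB * fab
    probs[..., 0, 0] = fab**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(probs)
    terms = np.where(counts > 0, terms, 0.0)  # 0·log0 := 0
    return terms.sum(axis=(-2, -1))


def _em_batch(counts: np.ndarray, start_pc: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run EM on a stack of 3×3 tables from one coupling-fraction start.

    Returns (freqs (..., 4), n_iter, converged).
    """
    counts = np.asarray(counts, dtype=float)
    two_n = 2.0 * counts.sum(axis=(-2, -1))
    n11 = counts[..., 1, 1]
    # phase-known haplotype counts
    k_AB = 2 * counts[..., 2, 2] + counts[..., 2, 1] + counts[..., 1, 2]
    k_Ab = 2 * counts[..., 2, 0] + counts[..., 2, 1] + counts[..., 1, 0]
    k_aB = 2 * counts[..., 0, 2] + counts[..., 0, 1] + counts[..., 1, 2]
    k_ab = 2 * counts[..., 0, 0] + counts[..., 0, 1] + counts[..., 1, 0]

    shape = n11.shape
    n11f, two_nf = n11.ravel(), two_n.ravel()
    kAB, kAb, kaB, kab = (k.ravel() for k in (k_AB, k_Ab, k_aB, k_ab))

    def m_step(pc, idx):
        return np.stack(
            [
                (kAB[idx] + n11f[idx] * pc) / two_nf[idx],
                (kAb[idx] + n11f[idx] * (1 - pc)) / two_nf[idx],
                (kaB[idx] + n11f[idx] * (1 - pc)) / two_nf[idx],
                (kab[idx] + n11f[idx] * pc) / two_nf[idx],
            ],
            axis=-1,
        )

    all_idx = np.arange(n11f.size)
    f = m_step(np.full(n11f.size, start_pc), all_idx)
    # tables without double heterozygotes are exact at iteration 0
    active = np.flatnonzero(n11f > 0)
    n_iter = np.zeros(n11f.size, dtype=int)
    for _ in range(EM_MAX_ITER):
        if active.size == 0:
            break
        fa = f[active]
        coup = fa[:, 0] * fa[:, 3]
        rep = fa[:, 1] * fa[:, 2]
        with np.errstate(invalid="ignore", divide="ignore"):
            pc_new = np.where(coup + rep > 0, coup / (coup + rep), 0.5)
        f_new = m_step(pc_new, active)
        delta = np.abs(f_new - fa).max(axis=-1)
        f[active] = f_new
        n_iter[active] += 1
        active = active[delta >= EM_TOL]
    converged = np.ones(n11f.size, dtype=bool)
    converged[active] = False
    return f.reshape(*shape, 4), n_iter.reshape(shape), converged.reshape(shape)


def em_haplotype_freqs_batch(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best-of-three-starts EM over a stack of 3×3 genotype tables.

    Returns (freqs (...,4), loglik, n_iter, converged); per table the start
    with the highest final log-likelihood wins.
    """
    best_f = best_ll = best_it = best_conv = None
    for pc0 in EM_STARTS:
        f, it, conv = _em_batch(counts, pc0)
        ll = _loglik(np.asarray(counts, dtype=float), f)
        if best_f is None:
            best_f, best_ll, best_it, best_conv = f, ll, it, conv
        else:
            better = ll > best_ll + 1e-12
            best_f = np.where(better[..., None], f, best_f)
            best_it = np.where(better, it, best_it)
            best_conv = np.where(better, conv, best_conv)
            best_ll = np.maximum(ll, best_ll)
    return best_f, best_ll, best_it, best_conv


def em_loglik_trace(counts: np.ndarray, start_pc: float = 0.5) -> np.ndarray:
    """Log-likelihood after every EM iteration from one start (monotone by
    the EM property; exposed for diagnostics)."""
    counts = np.asarray(counts, dtype=float)
    two_n = 2.0 * counts.sum()
    n11 = counts[1, 1]
    k_AB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    k_Ab = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    k_aB = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    k_ab = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]

    def m_step(pc):
        return np.array(
            [
                (k_AB + n11 * pc) / two_n,
                (k_Ab + n11 * (1 - pc)) / two_n,
                (k_aB + n11 * (1 - pc)) / two_n,
                (k_ab + n11 * pc) / two_n,
            ]
        )

    f = m_step(start_pc)
    trace = [float(_loglik(counts, f))]
    for _ in range(EM_MAX_ITER):
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        pc = coup / (coup + rep) if coup + rep > 0 else 0.5
        f_new = m_step(pc)
        trace.append(float(_loglik(counts, f_new)))
        if np.abs(f_new - f).max() < EM_TOL:
            break
        f = f_new
    return np.asarray(trace)


def two_locus_em(counts: np.ndarray) -> HaplotypeFreqs2:
    """ML two-locus haplotype frequencies from a 3×3 joint genotype table.

    Rows index the alt-allele count at locus A, columns at locus B.  Raises
    :class:`MonomorphicError` if either locus is monomorphic in the table.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError(f"expected a 3×3 table, got shape {counts.shape}")
    if counts.sum() < 1:
        raise ValueError("empty genotype table")
    alt_a = 2 * counts[2].sum() + counts[1].sum()
    alt_b = 2 * counts[:, 2].sum() + counts[:, 1].sum()
    two_n = 2 * counts.sum()
    if alt_a in (0, two_n) or alt_b in (0, two_n):
        raise MonomorphicError("undefined LD: a locus is monomorphic in the table")

    f, ll, it, conv = em_haplotype_freqs_batch(counts[None])
    f, ll, it, conv = f[0], float(ll[0]), int(it[0]), bool(conv[0])
    note = ""
    # flat ridge: only double heterozygotes → likelihood constant in phase
    known = counts.sum() - counts[1, 1]
    if counts[1, 1] > 0 and known == 0:
        note = "degenerate: double-heterozygotes only (flat likelihood ridge)"
    return HaplotypeFreqs2(
        f_AB=float(f[0]),
        f_Ab=float(f[1]),
        f_aB=float(f[2]),
        f_ab=float(f[3]),
        loglik=ll,
        n_iter=it,
        converged=conv,
        note=note,
    )


# ---------------------------------------------------------------------------
# LD measures
# ---------------------------------------------------------------------------

def _ld_from_freqs(fAB: np.ndarray, fAb: np.ndarray, faB: np.ndarray, fab: np.ndarray):
    pA = fAB + fAb
    pB = fAB + faB
    D = fAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, D**2 / denom, np.nan)
    dmax_pos = np.minimum(pA * (1 - pB), (1 - pA) * pB)
    dmax_neg = np.minimum(pA * pB, (1 - pA) * (1 - pB))
    dmax = np.where(D > 0, dmax_pos, dmax_neg)
    with np.errstate(invalid="ignore", divide="ignore"):
        dprime = np.where(D == 0, 0.0, np.abs(D) / dmax)
    # guard against eps-level overshoot of the theoretical [0, 1] bounds
    return D, np.clip(np.abs(dprime), 0.0, 1.0), np.clip(r2, 0.0, 1.0)


def ld_measures(h: HaplotypeFreqs2) -> tuple[float, float, float]:
    """(D, |D′|, r²) from fitted two-locus haplotype frequencies."""
    pA, pB = h.p_A, h.p_B
    if not (0 < pA < 1) or not (0 < pB < 1):
        raise MonomorphicError("LD measures undefined: monomorphic marginal")
    D, adp, r2 = _ld_from_freqs(
        np.float64(h.f_AB), np.float64(h.f_Ab), np.float64(h.f_aB), np.float64(h.f_ab)
    )
    return float(D), float(adp), float(r2)


# ---------------------------------------------------------------------------
# All-pairs LD over a dataset
# ---------------------------------------------------------------------------

def _joint_tables(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """3×3 joint genotype count tables for all (column of a) × (column of b).

    Pairwise-complete: an individual contributes to a pair only when both
    calls are non-missing.  Returns shape (n_a, n_b, 3, 3).
    """
    n_a, n_b = calls_a.shape[1], calls_b.shape[1]
    tables = np.empty((n_a, n_b, 3, 3), dtype=np.int32)
    ind_a = [(calls_a == g) for g in range(3)]
    ind_b = [(calls_b == g) for g in range(3)]
    for ga in range(3):
        a = ind_a[ga].astype(np.float32)
        for gb in range(3):
            tables[:, :, ga, gb] = a.T @ ind_b[gb].astype(np.float32)
    return tables


def _pairs_ld_frame(
    ds: GenotypeDataset, idx_a: np.ndarray, idx_b: np.ndarray, chunk: int = 200_000
) -> pd.DataFrame:
    """LD statistics for explicit SNP index pairs (idx_a[k], idx_b[k])."""
    snp_id = ds.snps.snp_id.to_numpy()
    chrom = ds.snps.chrom.to_numpy()
    pos = ds.snps.pos.to_numpy()
    out = []
    for lo in range(0, len(idx_a), chunk):
        ia = idx_a[lo : lo + chunk]
        ib = idx_b[lo : lo + chunk]
        ca = ds.calls[:, ia]
        cb = ds.calls[:, ib]
        ok = (ca != MISSING) & (cb != MISSING)
        counts = np.zeros((len(ia), 3, 3), dtype=float)
        for ga in range(3):
            for gb in range(3):
                counts[:, ga, gb] = ((ca == ga) & (cb == gb) & ok).sum(axis=0)
        n_used = counts.sum(axis=(1, 2))
        two_n = 2 * n_used
        alt_a = 2 * counts[:, 2, :].sum(axis=1) + counts[:, 1, :].sum(axis=1)
        alt_b = 2 * counts[:, :, 2].sum(axis=1) + counts[:, :, 1].sum(axis=1)
        poly = (
            (n_used > 0)
            & (alt_a > 0) & (alt_a < two_n)
            & (alt_b > 0) & (alt_b < two_n)
        )
        f, _, _, conv = em_haplotype_freqs_batch(counts[poly])
        _, adp, r2 = _ld_from_freqs(f[:, 0], f[:, 1], f[:, 2], f[:, 3])
        sel = np.flatnonzero(poly)
        out.append(
            pd.DataFrame(
                {
                    "snp_a": snp_id[ia[sel]],
                    "snp_b": snp_id[ib[sel]],
                    "chrom_a": chrom[ia[sel]],
                    "chrom_b": chrom[ib[sel]],
                    "distance_bp": np.abs(pos[ia[sel]] - pos[ib[sel]]),
                    "n_used": n_used[sel].astype(int),
                    "r2": r2,
                    "abs_dprime": adp,
                    "converged": conv,
                    "n_dropped_monomorphic": (~poly).sum(),
                }
            )
        )
    if not out:
        return _empty_ld_table()
    df = pd.concat(out, ignore_index=True)
    df["inter_chromosome"] = df.chrom_a != df.chrom_b
    return df


def _empty_ld_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "snp_a", "snp_b", "chrom_a", "chrom_b", "distance_bp", "n_used",
            "r2", "abs_dprime", "converged", "n_dropped_monomorphic",
            "inter_chromosome",
        ]
    )


def pairwise_ld_region(ds: GenotypeDataset) -> pd.DataFrame:
    """All intra-chromosome pairwise LD for one post-QC population dataset.

    One row per unordered same-chromosome SNP pair; pairs whose pairwise-
    complete subset leaves a locus monomorphic are dropped (the drop count is
    carried in ``n_dropped_monomorphic``).
    """
    if len(set(ds.samples.population)) > 1:
        raise ValueError("pairwise_ld_region expects a single-population dataset")
    chroms = ds.snps.chrom.to_numpy()
    idx_a, idx_b = [], []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        ia, ib = np.triu_indices(len(idx), k=1)
        idx_a.append(idx[ia])
        idx_b.append(idx[ib])
    if not idx_a:
        import warnings

        warnings.warn("fewer than 2 SNPs on every chromosome; empty LD table", stacklevel=2)
        return _empty_ld_table()
    return _pairs_ld_frame(ds, np.concatenate(idx_a), np.concatenate(idx_b))


def background_ld(
    ds: GenotypeDataset, maf_min: float = 0.1, call_rate_min: float = 0.80
) -> tuple[float, int]:
    """Mean r² over all inter-chromosome SNP pairs — the unlinked-locus null.

    QC (call rate, monomorphic, MAF ≥ ``maf_min``) is applied within the
    population first.  Returns (mean r², number of pairs used).
    """
    from .genotype_io import apply_qc

    pops = set(ds.samples.population)
    if len(pops) != 1:
        raise ValueError("background_ld expects a single-population dataset")
    sub, _ = apply_qc(ds, next(iter(pops)), maf_min=maf_min, call_rate_min=call_rate_min)
    chroms = sub.snps.chrom.to_numpy()
    uniq = list(dict.fromkeys(chroms))
    if len(uniq) < 2:
        raise ValueError("background LD needs SNPs on at least two chromosomes")
    idx_a, idx_b = [], []
    for i, ca in enumerate(uniq):
        for cb in uniq[i + 1 :]:
            ia = np.flatnonzero(chroms == ca)
            ib = np.flatnonzero(chroms == cb)
            grid_a, grid_b = np.meshgrid(ia, ib, indexing="ij")
            idx_a.append(grid_a.ravel())
            idx_b.append(grid_b.ravel())
    df = _pairs_ld_frame(sub, np.concatenate(idx_a), np.concatenate(idx_b))
    if df.empty:
        raise ValueError("no usable inter-chromosome pairs")
    return float(df.r2.mean()), int(len(df))


def write_ld_table(df: pd.DataFrame, path) -> None:
    cols = ["snp_a", "snp_b", "chrom_a", "chrom_b", "distance_bp", "n_used", "r2", "abs_dprime"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
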