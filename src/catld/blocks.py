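"""Solid-spine haplotype blocks and within-block haplotype frequencies.

A block under the solid-spine-of-LD rule is a maximal marker interval
[i..j] whose first and last markers are each in strong LD (|D′| at or above
a threshold, default 0.8) with *every* marker between them:

    |D′|(i, k) ≥ t  for all k in (i..j]   and   |D′|(k, j) ≥ t  for all k in [i..j)

Intermediate-vs-intermediate pairs are unconstrained.  Blocks are found by
left-to-right greedy extension to the farthest valid end marker and never
overlap; single markers form no block.

Within a block, haplotype frequencies are estimated from the unphased
genotypes by a multi-locus EM over phase configurations (partition–ligation
for long blocks).  Haplotypes are reported down to frequency 0.01 and
classified as the single major haplotype, intermediate (> 0.1), or pooled
rare (< 0.1) — the classes used for block-diagram displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset, apply_qc
from .ld import em_haplotype_freqs_batch, _joint_tables, _ld_from_freqs

DPRIME_THRESHOLD = 0.8
DISPLAY_FREQ_MIN = 0.01
INTERMEDIATE_FREQ = 0.1
# partition–ligation parameters: direct EM up to this many markers, then
# split, keep the top haplotypes per side, and ligate
PL_MAX_DIRECT = 8
PL_TOP = 20
# individuals with more ambiguity than this (ordered phase configurations)
# are excluded from the block EM
_MAX_AMBIGUITY = 4096


@dataclass
class HaplotypeBlock:
    population: str
    region: str
    chrom: str
    first: int            # marker indices within the region's marker list
    last: int
    start_bp: int
    end_bp: int
    n_markers: int
    haplotypes: list = field(default_factory=list)  # (allele_string, freq, class)
    rare_pooled_freq: float = 0.0

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def major_freq(self) -> float:
        return self.haplotypes[0][1] if self.haplotypes else float("nan")


# ---------------------------------------------------------------------------
# Spine detection
# ---------------------------------------------------------------------------

def dprime_matrix(ds: GenotypeDataset) -> np.ndarray:
    """Symmetric |D′| matrix over the dataset's SNPs (NaN where undefined).

    Pairs are computed on pairwise-complete individuals; pairs whose usable
    subset is monomorphic at either locus are NaN.
    """
    m = ds.n_snps
    tables = _joint_tables(ds.calls, ds.calls).astype(float)
    iu, ju = np.triu_indices(m, k=1)
    counts = tables[iu, ju]
    two_n = 2 * counts.sum(axis=(1, 2))
    alt_a = 2 * counts[:, 2, :].sum(axis=1) + counts[:, 1, :].sum(axis=1)
    alt_b = 2 * counts[:, :, 2].sum(axis=1) + counts[:, :, 1].sum(axis=1)
    poly = (two_n > 0) & (alt_a > 0) & (alt_a < two_n) & (alt_b > 0) & (alt_b < two_n)
    dp = np.full(m * (m - 1) // 2, np.nan)
    if poly.any():
        f, _, _, _ = em_haplotype_freqs_batch(counts[poly])
        _, adp, _ = _ld_from_freqs(f[:, 0], f[:, 1], f[:, 2], f[:, 3])
        dp[poly] = adp
    out = np.full((m, m), np.nan)
    out[iu, ju] = dp
    out[ju, iu] = dp
    np.fill_diagonal(out, 1.0)
    return out


def _interval_valid(dp: np.ndarray, i: int, j: int, t: float) -> bool:
    """Two-sided spine condition on [i..j] (j > i)."""
    left = dp[i, i + 1 : j + 1]
    right = dp[i:j, j]
    if np.isnan(left).any() or np.isnan(right).any():
        return False
    return bool((left >= t).all() and (right >= t).all())


def spine_intervals(dp: np.ndarray, threshold: float = DPRIME_THRESHOLD) -> list[tuple[int, int]]:
    """Greedy left-to-right maximal solid-spine intervals over a |D′| matrix."""
    m = dp.shape[0]
    out: list[tuple[int, int]] = []
    i = 0
    while i < m - 1:
        best_j = -1
        for j in range(i + 1, m):
            if _interval_valid(dp, i, j, threshold):
                best_j = j
        if best_j > i:
            out.append((i, best_j))
            i = best_j + 1
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Multi-locus EM
# ---------------------------------------------------------------------------

def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All ordered haplotype pairs consistent with one genotype vector.

    Heterozygous sites contribute a 2-way phase choice, missing sites a
    4-way ordered allele choice; homozygous sites are fixed.
    """
    options = []
    for g in geno:
        if g == 0:
            options.append(((0, 0),))
        elif g == 2:
            options.append(((1, 1),))
        elif g == 1:
            options.append(((0, 1), (1, 0)))
        else:  # missing
            options.append(((0, 0), (0, 1), (1, 0), (1, 1)))
    pairs = []
    for combo in product(*options):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        pairs.append((h1, h2))
    return pairs


def _em_haplotypes(pair_lists: list[list[tuple]], tol: float = 1e-9, max_iter: int = 2000) -> dict:
    """EM over haplotype frequencies given each individual's compatible pairs."""
    haps = sorted({h for pairs in pair_lists for p in pairs for h in p})
    idx = {h: k for k, h in enumerate(haps)}
    pair_idx = [
        np.array([(idx[h1], idx[h2]) for h1, h2 in pairs], dtype=int)
        for pairs in pair_lists
    ]
    K = len(haps)
    f = np.full(K, 1.0 / K)
    n = len(pair_lists)
    for _ in range(max_iter):
        counts = np.zeros(K)
        for pi in pair_idx:
            w = f[pi[:, 0]] * f[pi[:, 1]]
            s = w.sum()
            if s <= 0:
                w = np.full(len(pi), 1.0 / len(pi))
            else:
                w = w / s
            np.add.at(counts, pi[:, 0], w)
            np.add.at(counts, pi[:, 1], w)
        f_new = counts / (2.0 * n)
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    return {h: float(f[idx[h]]) for h in haps if f[idx[h]] > 1e-12}


def _em_restricted(genos: np.ndarray, candidates: np.ndarray) -> dict:
    """EM restricted to a candidate haplotype set (ligation step).

    ``genos``: (n, m) genotype codes; ``candidates``: (K, m) 0/1 alleles.
    Ordered pair (h1, h2) is compatible with g iff h1+h2 == g at every
    called site.
    """
    K, m = candidates.shape
    pair_sum = candidates[:, None, :] + candidates[None, :, :]  # (K, K, m)
    pair_lists = []
    for g in genos:
        called = g != MISSING
        ok = (pair_sum[:, :, called] == g[called]).all(axis=2)
        ii, jj = np.nonzero(ok)
        if len(ii) == 0:
            continue
        pair_lists.append([(tuple(candidates[i]), tuple(candidates[j])) for i, j in zip(ii, jj)])
    if not pair_lists:
        return {}
    return _em_haplotypes(pair_lists)


def _phase_block(genos: np.ndarray) -> dict:
    """Haplotype frequency dict for one block's genotypes (n × m codes)."""
    m = genos.shape[1]
    # drop all-missing individuals and those with intractable ambiguity
    keep = []
    for g in genos:
        called = g != MISSING
        if not called.any():
            continue
        amb = 2 ** int((g == 1).sum()) * 4 ** int((g == MISSING).sum())
        if amb > _MAX_AMBIGUITY:
            continue
        keep.append(g)
    if not keep:
        raise ValueError("no usable individuals in block")
    genos = np.array(keep)
    if m <= PL_MAX_DIRECT:
        pair_lists = [_compatible_pairs(tuple(int(x) for x in g)) for g in genos]
        return _em_haplotypes(pair_lists)
    # partition–ligation: halve, solve each side, ligate top haplotypes
    half = m // 2
    left = _phase_block(genos[:, :half])
    right = _phase_block(genos[:, half:])
    top_l = sorted(left, key=left.get, reverse=True)[:PL_TOP]
    top_r = sorted(right, key=right.get, reverse=True)[:PL_TOP]
    cand = np.array([l + r for l in top_l for r in top_r], dtype=np.int8)
    freqs = _em_restricted(genos, cand)
    total = sum(freqs.values())
    if total > 0:
        freqs = {h: f / total for h, f in freqs.items()}
    return freqs


def block_haplotype_freqs(ds: GenotypeDataset) -> list[tuple[str, float]]:
    """EM haplotype frequencies for a dataset restricted to one block.

    Returns (allele_string, frequency) sorted by descending frequency,
    keeping haplotypes with frequency ≥ 0.01.
    """
    if not 2 <= ds.n_snps <= 60:
        raise ValueError(f"block must span 2–60 markers, got {ds.n_snps}")
    poly = False
    for j in range(ds.n_snps):
        col = ds.calls[:, j]
        col = col[col != MISSING]
        if col.size and (np.any(col == 1) or (np.any(col == 0) and np.any(col == 2))):
            poly = True
            break
    if not poly:
        raise ValueError("block monomorphic after restriction")
    freqs = _phase_block(ds.calls)
    out = [
        ("".join(map(str, h)), f)
        for h, f in freqs.items()
        if f >= DISPLAY_FREQ_MIN
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def classify_haplotypes(haps: list[tuple[str, float]]) -> tuple[list[tuple[str, float, str]], float]:
    """Label haplotypes major / intermediate / rare; pool the rare mass.

    The major class is the single highest-frequency haplotype; intermediate
    haplotypes exceed frequency 0.1; everything else (including haplotypes
    below the display threshold) is pooled as rare with mass
    1 − Σ(major + intermediate).
    """
    if not haps:
        return [], 0.0
    labelled = []
    shown_mass = 0.0
    for k, (s, f) in enumerate(haps):
        if k == 0:
            cls = "major"
        elif f > INTERMEDIATE_FREQ:
            cls = "intermediate"
        else:
            cls = "rare"
        labelled.append((s, f, cls))
        if cls in ("major", "intermediate"):
            shown_mass += f
    rare_pooled = max(0.0, 1.0 - shown_mass)
    return labelled, rare_pooled


# ---------------------------------------------------------------------------
# Region / population drivers
# ---------------------------------------------------------------------------

def solid_spine_blocks(
    ds: GenotypeDataset,
    population: str,
    maf_min: float = 0.05,
    dprime_threshold: float = DPRIME_THRESHOLD,
    call_rate_min: float = 0.80,
    with_haplotypes: bool = True,
) -> list[HaplotypeBlock]:
    """Solid-spine blocks (and haplotypes) for every region of one population."""
    sub, _ = apply_qc(ds, population, maf_min=maf_min, call_rate_min=call_rate_min)
    blocks: list[HaplotypeBlock] = []
    for (chrom, region), grp in sub.snps.groupby(["chrom", "region"], sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            continue
        reg = sub.take_snps(idx)
        dp = dprime_matrix(reg)
        for i, j in spine_intervals(dp, dprime_threshold):
            blk = HaplotypeBlock(
                population=population,
                region=str(region),
                chrom=str(chrom),
                first=i,
                last=j,
                start_bp=int(reg.snps.pos.iloc[i]),
                end_bp=int(reg.snps.pos.iloc[j]),
                n_markers=j - i + 1,
            )
            if with_haplotypes and blk.n_markers <= 60:
                sli = reg.take_snps(np.arange(i, j + 1))
                haps = block_haplotype_freqs(sli)
                blk.haplotypes, blk.rare_pooled_freq = classify_haplotypes(haps)
            blocks.append(blk)
    return blocks


def diversity_summary(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """Block and haplotype counts per population × region, plus totals.

    Haplotype counts include haplotypes at or above the display threshold.
    """
    rows = {}
    for b in blocks:
        key = (b.population, b.region)
        rec = rows.setdefault(key, {"population": b.population, "region": b.region,
                                    "n_blocks": 0, "n_haplotypes": 0})
        rec["n_blocks"] += 1
        rec["n_haplotypes"] += b.n_haplotypes
    df = pd.DataFrame(rows.values()) if rows else pd.DataFrame(
        columns=["population", "region", "n_blocks", "n_haplotypes"]
    )
    if not df.empty:
        totals = (
            df.groupby("population", as_index=False)[["n_blocks", "n_haplotypes"]]
            .sum()
            .assign(region="TOTAL")
        )
        df = pd.concat([df, totals[df.columns]], ignore_index=True)
    return df


def blocks_frame(blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population": b.population,
                "region": b.region,
                "chrom": b.chrom,
                "start_bp": b.start_bp,
                "end_bp": b.end_bp,
                "n_markers": b.n_markers,
                "n_haplotypes": b.n_haplotypes,
                "major_freq": b.major_freq,
            }
            for b in blocks
        ]
    )
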