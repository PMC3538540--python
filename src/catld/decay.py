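"""Drift–recombination LD decay: model, fitting and summary statistics.

The expected squared correlation between two loci separated by population
recombination parameter C in a sample of n diploid individuals, at
drift–recombination equilibrium, is

    E[r²] = (10 + C) / ((2 + C)(11 + C))
            · [1 + ((3 + C)(12 + 12C + C²)) / (n (2 + C)(11 + C))]

which decreases from (5/11)(1 + 18/(11 n)) at C = 0 to the sampling floor
1/n as C → ∞.  Fitting C = a·d (d in kb) to all intra-chromosome pairs of a
population by nonlinear least squares gives a single decay coefficient ``a``
per population/scope; the distance at which the fitted curve falls to half
its C→0 maximum (d50) is the cross-population comparison statistic.

Note the half-decay r² *level* depends only on n, not on the data:
half of (5/11)(1 + 18/(11 n)).  This is why panels with similar sample sizes
report near-identical half-decay r² levels while their d50 differ widely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

MAX_DISTANCE_KB = 1000.0
#: distance classes (kb, half-open [lo, hi)) for GWAS-informative fractions
DEFAULT_CLASSES_KB = (
    (0, 20), (20, 40), (40, 60), (60, 80), (80, 100),
    (100, 200), (200, 400), (400, 600), (600, 1000),
)


def hill_weir_expected_r2(C, n) -> np.ndarray | float:
    """Expected r² at drift–recombination equilibrium (vectorised in C).

    ``C`` is the population recombination parameter (≥ 0), ``n`` the number
    of sampled diploid individuals (≥ 2).
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be non-negative")
    if n < 2:
        raise ValueError("n must be at least 2")
    left = (10 + C) / ((2 + C) * (11 + C))
    right = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    out = left * right
    return float(out) if out.ndim == 0 else out


def expected_r2_max(n: int) -> float:
    """C→0 supremum of the decay curve: (5/11)(1 + 18/(11 n))."""
    return (5.0 / 11.0) * (1.0 + 18.0 / (11.0 * n))


@dataclass
class DecayFit:
    population: str
    scope: str  # chromosome label, "Auto", or "All"
    a_per_kb: float
    n: int
    n_pairs: int
    rss: float
    converged: bool


@dataclass
class HalfDecayPoint:
    r2_level: float
    distance_kb: float  # np.inf when not reached within max_distance_kb
    reached: bool

    def distance_str(self, max_kb: float = MAX_DISTANCE_KB) -> str:
        return f"{self.distance_kb:.1f}" if self.reached else f">{max_kb:.0f}"


# fit search grid for the decay coefficient a (per kb)
_A_LO, _A_HI = 1e-6, 1.0


def fit_decay(
    pairs: pd.DataFrame,
    n: int,
    population: str = "",
    scope: str = "Auto",
) -> DecayFit:
    """Least-squares fit of a in C = a·d to unbinned intra-chromosome pairs.

    ``pairs`` needs columns ``distance_bp`` and ``r2``; distances enter the
    model in kb.  Initialisation is a coarse log-grid search over
    a ∈ [1e-6, 1] per kb followed by bounded scalar refinement.  A best fit
    pinned to the upper boundary is flagged non-converged (r² sits at the
    1/n floor and a diverges); a fit at the lower boundary is kept — it
    means LD barely decays over the observed range, and the half-decay
    summary reports its not-reached sentinel.
    """
    intra = pairs.loc[~pairs.get("inter_chromosome", pd.Series(False, index=pairs.index))]
    d_kb = intra.distance_bp.to_numpy(dtype=float) / 1000.0
    r2 = intra.r2.to_numpy(dtype=float)
    keep = d_kb > 0
    d_kb, r2 = d_kb[keep], r2[keep]
    if len(r2) < 10:
        raise ValueError(f"need at least 10 pairs to fit decay, got {len(r2)}")

    def rss(a: float) -> float:
        return float(np.sum((r2 - hill_weir_expected_r2(a * d_kb, n)) ** 2))

    grid = np.logspace(np.log10(_A_LO), np.log10(_A_HI), 121)
    losses = [rss(a) for a in grid]
    k = int(np.argmin(losses))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(rss, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    a_hat = float(res.x)
    converged = bool(res.success) and k != len(grid) - 1
    if not converged:
        warnings.warn(
            f"decay fit for {population or 'population'}/{scope} pinned at "
            f"search boundary (a={a_hat:.3g}); flagged non-converged",
            stacklevel=2,
        )
    return DecayFit(
        population=population,
        scope=scope,
        a_per_kb=a_hat,
        n=int(n),
        n_pairs=len(r2),
        rss=rss(a_hat),
        converged=converged,
    )


def half_decay(fit: DecayFit, max_distance_kb: float = MAX_DISTANCE_KB) -> HalfDecayPoint:
    """Distance at which the fitted curve reaches half its C→0 maximum.

    The maximum is the data-independent C→0 limit, so the target r² level
    depends only on n.  The crossing distance is solved by bisection to
    1e-6 kb; if the curve stays above the level out to ``max_distance_kb``
    the sentinel (inf, reached=False) is returned.
    """
    level = 0.5 * expected_r2_max(fit.n)

    def g(d: float) -> float:
        return hill_weir_expected_r2(fit.a_per_kb * d, fit.n) - level

    if g(max_distance_kb) > 0:
        return HalfDecayPoint(r2_level=level, distance_kb=np.inf, reached=False)
    lo, hi = 0.0, max_distance_kb
    # g(0) = E_max - level > 0 always; bisect to 1e-6 kb
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return HalfDecayPoint(r2_level=level, distance_kb=0.5 * (lo + hi), reached=True)


def fit_population_decay(
    ds,
    population: str,
    maf_min: float = 0.05,
    call_rate_min: float = 0.80,
    scope: str = "Auto",
    x_label: str = "X",
):
    """QC → all-pairs LD → decay fit for one population and scope.

    Scope "Auto" drops the X-labelled chromosome, "All" keeps every
    chromosome, any other value selects that single chromosome label.
    Returns (DecayFit, HalfDecayPoint, LD table).
    """
    from .genotype_io import apply_qc
    from .ld import pairwise_ld_region

    sub, _ = apply_qc(ds, population, maf_min=maf_min, call_rate_min=call_rate_min)
    if scope == "Auto":
        keep = sub.snps.chrom != x_label
    elif scope == "All":
        keep = pd.Series(True, index=sub.snps.index)
    else:
        keep = sub.snps.chrom == scope
    sub = sub.take_snps(np.flatnonzero(keep.to_numpy()))
    table = pairwise_ld_region(sub)
    fit = fit_decay(table, n=sub.n_samples, population=population, scope=scope)
    return fit, half_decay(fit), table


def maf_inflation(
    ds,
    population: str,
    scope: str = "Auto",
    maf_low: float = 0.05,
    maf_high: float = 0.1,
) -> float:
    """Percent inflation of the LD extent caused by the stricter MAF cutoff.

    100 × (d50(MAF=0.1) − d50(MAF=0.05)) / d50(MAF=0.1); raising the MAF
    cutoff removes low-frequency SNPs whose pairings drag r² down, so the
    apparent extent of LD grows.  Undefined (ValueError) when either fit is
    non-converged or either half-decay point is not reached.
    """
    fit_lo, hd_lo, _ = fit_population_decay(ds, population, maf_min=maf_low, scope=scope)
    fit_hi, hd_hi, _ = fit_population_decay(ds, population, maf_min=maf_high, scope=scope)
    if not (fit_lo.converged and fit_hi.converged):
        raise ValueError("MAF inflation undefined: non-converged decay fit")
    if not (hd_lo.reached and hd_hi.reached):
        raise ValueError("MAF inflation undefined: half-decay point not reached")
    return 100.0 * (hd_hi.distance_kb - hd_lo.distance_kb) / hd_hi.distance_kb


def informative_fractions(
    pairs: pd.DataFrame,
    r2_threshold: float = 0.8,
    classes_kb=DEFAULT_CLASSES_KB,
) -> pd.DataFrame:
    """Fraction of SNP pairs with r² ≥ threshold per distance class.

    Classes are half-open [lo, hi) in kb over intra-chromosome pairs.  An
    empty class yields NaN (undefined), never 0.
    """
    intra = pairs.loc[~pairs.get("inter_chromosome", pd.Series(False, index=pairs.index))]
    d_kb = intra.distance_bp.to_numpy(dtype=float) / 1000.0
    r2 = intra.r2.to_numpy(dtype=float)
    rows = []
    for lo, hi in classes_kb:
        in_class = (d_kb >= lo) & (d_kb < hi)
        n = int(in_class.sum())
        frac = float((r2[in_class] >= r2_threshold).mean()) if n else np.nan
        rows.append({"lo_kb": lo, "hi_kb": hi, "n_pairs": n, "fraction_ge_threshold": frac})
    return pd.DataFrame(rows)
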