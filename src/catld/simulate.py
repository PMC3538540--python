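"""Forward Wright–Fisher simulation of breed-structured SNP-array panels.

The generator reproduces the design of a ten-region, ~150-SNPs-per-region
array genotyped across two dozen populations founded from two diverged
ancestral pools: each breed is a founder draw from one pool followed by a
bottleneck and an expansion under random mating with recombination, and each
random-bred population is a weakly drifted pool sample.  The emitted panel is
unphased genotype codes with a few percent missing calls, alongside the
phased truth haplotypes used as an oracle for EM/phasing tests.

Demography drives LD exactly as in real breed panels: few founders and a
tight bottleneck generate long-range LD and long haplotype blocks; large
effective sizes keep LD near the background.  Regions live on distinct
chromosomes and segregate independently, so inter-chromosomal LD stays at
the sampling floor.

Mechanics: diploid Wright–Fisher, per-gamete crossover counts Poisson with
mean recomb_rate × region_length, breakpoints uniform; no mutation during
breed history (array SNPs are pre-ascertained).  Everything is a pure
function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset

REGION_LABELS = ("A1", "A2", "B3", "C2", "D1", "D2", "D4", "E2", "F2", "X")


@dataclass
class BreedConfig:
    """Demographic recipe for one sampled population."""

    name: str
    pool: str  # "east" or "west"
    sample_n: int
    founder_count: int = 40
    bottleneck_ne: int = 40
    bottleneck_generations: int = 10
    expansion_ne: int = 100
    total_generations: int = 40

    def __post_init__(self) -> None:
        if min(self.founder_count, self.bottleneck_ne, self.expansion_ne) < 1:
            raise ValueError(f"{self.name}: population sizes must be ≥ 1")
        if self.sample_n > self.expansion_ne:
            raise ValueError(f"{self.name}: sample_n exceeds expansion_ne")
        if self.bottleneck_generations > self.total_generations:
            raise ValueError(f"{self.name}: bottleneck longer than total history")


@dataclass
class SimConfig:
    """Panel design + demography; defaults mirror the ten-region array study."""

    seed: int = 0
    n_regions: int = 10
    region_length_bp: int = 1_000_000
    snps_per_region: int = 150
    dense_end_snps: int = 50       # SNPs packed into the first dense_end_bp
    dense_end_bp: int = 100_000
    recomb_rate: float = 1e-8      # per bp per generation
    pool_size: int = 400           # diploids per ancestral pool
    pool_generations: int = 150    # forward generations to accumulate standing LD
    split_F: float = 0.05          # drift variance parameter between the pools
    missing_rate: float = 0.02
    breeds: list[BreedConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dense_end_snps > self.snps_per_region:
            raise ValueError("dense-end SNP count exceeds snps_per_region")
        if self.n_regions > len(REGION_LABELS):
            raise ValueError(f"at most {len(REGION_LABELS)} regions supported")

    @property
    def region_labels(self) -> tuple[str, ...]:
        return REGION_LABELS[: self.n_regions]


@dataclass
class SimTruth:
    """Phased truth emitted with the genotypes (oracle for phasing tests)."""

    sample_ids: list
    populations: list
    haplotypes: np.ndarray        # (2·n_samples, n_snps) 0/1, rows 2i, 2i+1 per sample
    ancestral_freqs: dict         # pool -> per-SNP allele frequency vector
    founder_haplotypes: dict = field(default_factory=dict)  # population -> (2·founders, n_snps)


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------

def build_snp_map(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic SNP map: dense first 100 kb, sparser remainder."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11]))
    rows = []
    for chrom in cfg.region_labels:
        n_dense = cfg.dense_end_snps
        n_rest = cfg.snps_per_region - n_dense
        if n_dense > cfg.dense_end_bp or n_rest > cfg.region_length_bp - cfg.dense_end_bp:
            raise ValueError("infeasible SNP density for region length")
        dense = rng.choice(np.arange(1, cfg.dense_end_bp + 1), size=n_dense, replace=False)
        rest = rng.choice(
            np.arange(cfg.dense_end_bp + 1, cfg.region_length_bp + 1),
            size=n_rest,
            replace=False,
        )
        pos = np.sort(np.concatenate([dense, rest]))
        for k, p in enumerate(pos):
            rows.append(
                {"snp_id": f"{chrom}_{k:04d}", "chrom": chrom, "region": chrom, "pos": int(p)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wright–Fisher engine
# ---------------------------------------------------------------------------

def _region_slices(snp_map: pd.DataFrame) -> list[tuple[slice, np.ndarray]]:
    out = []
    chroms = snp_map.chrom.to_numpy()
    pos = snp_map.pos.to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        out.append((slice(idx[0], idx[-1] + 1), pos[idx]))
    return out


def _next_generation(
    rng: np.random.Generator,
    H: np.ndarray,
    regions: list[tuple[slice, np.ndarray]],
    recomb_mean: float,
    n_offspring: int,
) -> np.ndarray:
    """One generation of random mating with recombination.

    ``H`` is (2N, M); returns (2·n_offspring, M).  Chromosomes assort
    independently per region; the common zero-crossover case is a vectorised
    gather, recombinant gametes are built individually.
    """
    n_parents = H.shape[0] // 2
    n_gametes = 2 * n_offspring
    out = np.empty((n_gametes, H.shape[1]), dtype=np.int8)
    parents = rng.integers(0, n_parents, size=n_gametes)
    for sl, pos in regions:
        start = rng.integers(0, 2, size=n_gametes)
        k = rng.poisson(recomb_mean, size=n_gametes)
        out[:, sl] = H[2 * parents + start, sl]
        for g in np.flatnonzero(k > 0):
            bps = np.sort(rng.uniform(0, pos[-1] + 1, size=k[g]))
            # haplotype choice per SNP: start parity + crossovers passed
            which = (start[g] + np.searchsorted(bps, pos)) % 2
            h0 = H[2 * parents[g], sl]
            h1 = H[2 * parents[g] + 1, sl]
            out[g, sl] = np.where(which == 0, h0, h1)
    return out


def _evolve(rng, H, regions, recomb_mean, sizes) -> np.ndarray:
    for n in sizes:
        H = _next_generation(rng, H, regions, recomb_mean, n)
    return H


# ---------------------------------------------------------------------------
# Ancestral pools
# ---------------------------------------------------------------------------

def simulate_ancestral(cfg: SimConfig, snp_map: pd.DataFrame) -> tuple[dict, dict]:
    """Two diverged ancestral haplotype pools.

    Pool "east" draws per-SNP frequencies from Beta(0.5, 0.5) truncated to
    [0.05, 0.95]; pool "west" perturbs them by a drift step of variance
    F·p(1−p).  Haplotypes are assembled at linkage equilibrium and then
    evolved ``pool_generations`` forward to accumulate standing LD.

    Returns ({pool: haplotype array}, {pool: founding frequency vector}).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB00]))
    M = len(snp_map)
    p_east = rng.beta(0.5, 0.5, size=M)
    for _ in range(100):
        bad = (p_east < 0.05) | (p_east > 0.95)
        if not bad.any():
            break
        p_east[bad] = rng.beta(0.5, 0.5, size=int(bad.sum()))
    p_east = np.clip(p_east, 0.05, 0.95)
    if cfg.split_F > 0:
        step = rng.normal(0.0, np.sqrt(cfg.split_F * p_east * (1 - p_east)))
    else:
        step = 0.0
    p_west = np.clip(p_east + step, 0.01, 0.99)

    regions = _region_slices(snp_map)
    recomb_mean = cfg.recomb_rate * cfg.region_length_bp
    pools, freqs = {}, {"east": p_east, "west": p_west}
    for pool in ("east", "west"):
        H = (rng.random((2 * cfg.pool_size, M)) < freqs[pool]).astype(np.int8)
        H = _evolve(rng, H, regions, recomb_mean, [cfg.pool_size] * cfg.pool_generations)
        pools[pool] = H
    return pools, freqs


# ---------------------------------------------------------------------------
# Breeds
# ---------------------------------------------------------------------------

def found_breed(
    pool_H: np.ndarray,
    breed: BreedConfig,
    snp_map: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Found a breed from a pool; returns (genotype codes, truth haplotypes,
    founder haplotypes).

    Founder draw → bottleneck_generations at bottleneck_ne → remaining
    generations at expansion_ne → sample of ``sample_n`` diploids.
    Missingness is applied by the caller so truth stays complete.
    """
    n_pool = pool_H.shape[0] // 2
    if breed.founder_count > n_pool:
        raise ValueError(f"{breed.name}: founder_count exceeds pool size")
    founders = rng.choice(n_pool, size=breed.founder_count, replace=False)
    H0 = pool_H[np.sort(np.concatenate([2 * founders, 2 * founders + 1]))]
    H = H0
    regions = _region_slices(snp_map)
    recomb_mean = cfg.recomb_rate * cfg.region_length_bp
    sizes = [breed.bottleneck_ne] * breed.bottleneck_generations + [
        breed.expansion_ne
    ] * (breed.total_generations - breed.bottleneck_generations)
    H = _evolve(rng, H, regions, recomb_mean, sizes)
    picked = rng.choice(H.shape[0] // 2, size=breed.sample_n, replace=False)
    hap_idx = np.concatenate([[2 * i, 2 * i + 1] for i in np.sort(picked)])
    truth = H[hap_idx]
    genotypes = truth[0::2] + truth[1::2]
    return genotypes.astype(np.int8), truth, H0


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Full panel: SNP map, ancestral pools, every configured breed."""
    if not cfg.breeds:
        raise ValueError("SimConfig.breeds is empty")
    snp_map = build_snp_map(cfg)
    pools, freqs = simulate_ancestral(cfg, snp_map)
    root = np.random.SeedSequence([cfg.seed, 0xD4])
    children = root.spawn(len(cfg.breeds) + 1)
    miss_rng = np.random.default_rng(children[-1])

    sample_ids, populations, geno_rows, truth_rows = [], [], [], []
    founder_haps: dict[str, np.ndarray] = {}
    for k, breed in enumerate(cfg.breeds):
        rng = np.random.default_rng(children[k])
        geno, truth, h0 = found_breed(pools[breed.pool], breed, snp_map, cfg, rng)
        geno_rows.append(geno)
        truth_rows.append(truth)
        founder_haps[breed.name] = h0
        sample_ids.extend(f"{breed.name}_{i:03d}" for i in range(breed.sample_n))
        populations.extend([breed.name] * breed.sample_n)

    calls = np.concatenate(geno_rows, axis=0)
    truth = SimTruth(
        sample_ids=list(sample_ids),
        populations=list(populations),
        haplotypes=np.concatenate(truth_rows, axis=0),
        ancestral_freqs=freqs,
        founder_haplotypes=founder_haps,
    )
    if cfg.missing_rate > 0:
        mask = miss_rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    return GenotypeDataset(samples, snp_map, calls), truth


# ---------------------------------------------------------------------------
# Study preset
# ---------------------------------------------------------------------------

# roster: (abbreviation, sample n, ancestral pool, bottleneck strength)
CAT_PANEL_ROSTER = (
    ("ABY", 21, "west", "moderate"),
    ("ANG", 14, "west", "weak"),
    ("BIR", 20, "east", "strong"),
    ("BURD", 19, "east", "strong"),
    ("BURF", 19, "east", "strong"),
    ("CHA", 8, "west", "moderate"),
    ("COR", 21, "west", "moderate"),
    ("EGY", 9, "east", "moderate"),
    ("JAP", 12, "west", "weak"),
    ("KORD", 19, "east", "moderate"),
    ("KORF", 17, "east", "moderate"),
    ("MAIN", 19, "west", "strong"),
    ("MANX", 20, "west", "weak"),
    ("NFC", 20, "west", "moderate"),
    ("OCI", 21, "east", "moderate"),
    ("PER", 19, "west", "moderate"),
    ("RUS", 18, "west", "weak"),
    ("SIA", 19, "east", "strong"),
    ("SIB", 19, "west", "weak"),
    ("VAND", 19, "west", "weak"),
    ("VANF", 12, "west", "moderate"),
    ("ERB", 22, "east", "weak"),
    ("WRB", 21, "west", "weak"),
)

_STRENGTH = {
    # founder_count, bottleneck_ne, bottleneck_generations, expansion_ne, total_generations
    # severities are qualitative; they are pitched so that the per-population
    # share of SNPs surviving QC stays in the range a real breed panel shows
    "strong": dict(founder_count=8, bottleneck_ne=8, bottleneck_generations=8,
                   expansion_ne=60, total_generations=30),
    "moderate": dict(founder_count=20, bottleneck_ne=20, bottleneck_generations=6,
                     expansion_ne=80, total_generations=30),
    "weak": dict(founder_count=50, bottleneck_ne=50, bottleneck_generations=4,
                 expansion_ne=100, total_generations=30),
}


def preset_cat_panel(seed: int = 0) -> SimConfig:
    """Study-design preset: 23 sampled populations totalling 408 cats.

    Sample sizes follow the study roster; demographic strengths are
    qualitative (strong/moderate/weak bottleneck) chosen so that long-LD
    breeds get few founders and tight bottlenecks.  The combined random-bred
    population is the pooled ERB+WRB view, not extra individuals.
    """
    breeds = [
        BreedConfig(name=abr, sample_n=n, pool=pool, **_STRENGTH[strength])
        for abr, n, pool, strength in CAT_PANEL_ROSTER
    ]
    return SimConfig(seed=seed, breeds=breeds)


def emulate_study(seed: int = 0, out_dir=None) -> tuple[GenotypeDataset, SimTruth]:
    """Generate the preset panel; optionally write VCF/popmap/map/truth TSVs."""
    cfg = preset_cat_panel(seed)
    ds, truth = simulate_panel(cfg)
    if out_dir is not None:
        from pathlib import Path

        from .genotype_io import write_tsv, write_vcf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(ds, out / "panel.vcf")
        write_tsv(ds, out / "panel_genotypes.tsv", out / "panel_popmap.tsv",
                  out / "panel_map.tsv")
        write_truth_tsv(truth, ds, out / "panel_truth.tsv")
    return ds, truth


def combined_random_bred(ds: GenotypeDataset, members=("ERB", "WRB"), label="RB") -> GenotypeDataset:
    """Pooled view of the random-bred populations under one label."""
    mask = ds.samples.population.isin(members).to_numpy()
    sub = ds.take_samples(np.flatnonzero(mask))
    samples = sub.samples.copy()
    samples["population"] = label
    return GenotypeDataset(samples, sub.snps, sub.calls)


def write_truth_tsv(truth: SimTruth, ds: GenotypeDataset, path) -> None:
    """Phased truth: one row per sample × haplotype × region, allele string."""
    chroms = ds.snps.chrom.to_numpy()
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\thaplotype\tregion\talleles\n")
        for i, (sid, pop) in enumerate(zip(truth.sample_ids, truth.populations)):
            for h in (0, 1):
                row = truth.haplotypes[2 * i + h]
                for chrom in dict.fromkeys(chroms):
                    alleles = "".join(map(str, row[chroms == chrom]))
                    fh.write(f"{sid}\t{pop}\t{h}\t{chrom}\t{alleles}\n")
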