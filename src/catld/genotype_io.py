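"""Genotype containers, file IO and per-population SNP quality control.

The central object is :class:`GenotypeDataset`: a samples × SNPs matrix of
diploid genotype codes (0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing)
together with a SNP map (chromosome, region label, 1-based bp position) and a
population label per sample.  Everything downstream — pairwise LD, decay
fitting, haplotype blocks, population statistics — consumes this container.

Two on-disk representations are supported: VCF (biallelic SNVs, unphased
genotypes; read through cyvcf2) and a simple TSV dialect
(``sample_id<TAB>snp_1<TAB>...`` with cells in {0,1,2,NA}) plus side-car TSVs
for the SNP map and the sample→population map.

QC follows the standard array-panel recipe applied within each population
separately: drop SNPs with call rate below a threshold, then SNPs monomorphic
in that population, then SNPs below a minor-allele-frequency cutoff.  A SNP is
counted in the first category it fails, so the per-category counts always sum
to the number of SNPs considered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1
_VALID_CODES = frozenset({0, 1, 2, MISSING})


class GenotypeDataError(ValueError):
    """Raised for malformed genotype inputs (bad codes, unsorted maps, ...)."""


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes with SNP map and population labels.

    Attributes
    ----------
    samples : pandas.DataFrame
        Columns ``sample_id`` (unique) and ``population`` (non-empty).
    snps : pandas.DataFrame
        Columns ``snp_id``, ``chrom``, ``region``, ``pos`` (1-based bp,
        strictly increasing within each (chrom, region)).
    calls : numpy.ndarray
        ``(n_samples, n_snps)`` int8 matrix of codes {0, 1, 2, -1}.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise GenotypeDataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples × {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeDataError(
                f"invalid genotype code {self.calls[i, j]} at sample "
                f"{self.samples.sample_id.iloc[i]!r}, SNP {self.snps.snp_id.iloc[j]!r}"
            )
        if self.samples.sample_id.duplicated().any():
            dup = self.samples.sample_id[self.samples.sample_id.duplicated()].iloc[0]
            raise GenotypeDataError(f"duplicate sample_id {dup!r}")
        if (self.samples.population.astype(str).str.len() == 0).any():
            raise GenotypeDataError("empty population label")
        for (chrom, region), grp in self.snps.groupby(["chrom", "region"], sort=False):
            pos = grp.pos.to_numpy()
            if np.any(np.diff(pos) <= 0):
                k = int(np.argmax(np.diff(pos) <= 0))
                raise GenotypeDataError(
                    f"positions not strictly increasing on {chrom}/{region}: "
                    f"SNP {grp.snp_id.iloc[k + 1]!r} at {pos[k + 1]} follows {pos[k]}"
                )

    # -- basic properties ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples.population))

    # -- subsetting ---------------------------------------------------------
    def take_samples(self, idx: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(self.samples.iloc[idx], self.snps, self.calls[idx])

    def take_snps(self, idx: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(self.samples, self.snps.iloc[idx], self.calls[:, idx])

    def for_population(self, population: str) -> "GenotypeDataset":
        mask = (self.samples.population == population).to_numpy()
        if not mask.any():
            raise GenotypeDataError(f"population {population!r} has no samples")
        return self.take_samples(np.flatnonzero(mask))


@dataclass
class QCReport:
    """Per-population SNP filtering tally; categories are mutually exclusive."""

    population: str
    n_input: int
    n_failed_callrate: int
    n_monomorphic: int
    n_low_maf: int
    n_retained: int
    call_rate_min: float
    maf_min: float

    @property
    def pct_retained(self) -> float:
        return 100.0 * self.n_retained / self.n_input if self.n_input else 0.0

    def __post_init__(self) -> None:
        total = (
            self.n_failed_callrate + self.n_monomorphic + self.n_low_maf + self.n_retained
        )
        if total != self.n_input:
            raise GenotypeDataError(
                f"QC categories sum to {total}, expected {self.n_input}"
            )


def minor_allele_freq(calls: np.ndarray) -> float:
    """MAF from genotype codes of one SNP: ``min(p, 1-p)`` with
    ``p = (2·n_hom_alt + n_het) / (2·n_called)``."""
    calls = np.asarray(calls)
    called = calls[calls != MISSING]
    if called.size == 0:
        raise GenotypeDataError("MAF undefined: all calls missing")
    p = called.sum() / (2.0 * called.size)
    return float(min(p, 1.0 - p))


def _per_snp_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(call_rate, alt_freq, n_called) per SNP column; freq is NaN when no calls."""
    called = calls != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / calls.shape[0]
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return call_rate, p, n_called


def apply_qc(
    ds: GenotypeDataset,
    population: str,
    maf_min: float,
    call_rate_min: float = 0.80,
) -> tuple[GenotypeDataset, QCReport]:
    """Restrict to one population and drop SNPs failing the panel QC.

    Filter order is call-rate → monomorphic → MAF; a SNP is tallied in the
    first category it fails.  Call rate, polymorphism and MAF are all computed
    within the population only.  Returns the filtered dataset (possibly with
    zero SNPs) and the tally.
    """
    if not 0 < call_rate_min <= 1:
        raise ValueError(f"call_rate_min must be in (0, 1], got {call_rate_min}")
    if not 0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    sub = ds.for_population(population)
    call_rate, p, _ = _per_snp_stats(sub.calls)

    fail_cr = call_rate < call_rate_min
    mono = ~fail_cr & (np.isnan(p) | (p <= 0.0) | (p >= 1.0))
    maf = np.where(np.isnan(p), 0.0, np.minimum(p, 1.0 - p))
    low_maf = ~fail_cr & ~mono & (maf < maf_min)
    keep = ~(fail_cr | mono | low_maf)

    report = QCReport(
        population=population,
        n_input=sub.n_snps,
        n_failed_callrate=int(fail_cr.sum()),
        n_monomorphic=int(mono.sum()),
        n_low_maf=int(low_maf.sum()),
        n_retained=int(keep.sum()),
        call_rate_min=call_rate_min,
        maf_min=maf_min,
    )
    return sub.take_snps(np.flatnonzero(keep)), report


def qc_report_frame(reports: list[QCReport]) -> pd.DataFrame:
    rows = [
        {
            "population": r.population,
            "n_input": r.n_input,
            "n_failed_callrate": r.n_failed_callrate,
            "n_monomorphic": r.n_monomorphic,
            "n_low_maf": r.n_low_maf,
            "n_retained": r.n_retained,
            "pct_retained": round(r.pct_retained, 1),
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_popmap(popmap_path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(popmap_path, sep="\t", dtype=str)
    expected = {"sample_id", "population"}
    if not expected.issubset(pm.columns):
        # headerless two-column fallback
        pm = pd.read_csv(
            popmap_path, sep="\t", header=None, names=["sample_id", "population"], dtype=str
        )
    return pm[["sample_id", "population"]]


def _attach_populations(samples: list[str], popmap: pd.DataFrame) -> pd.DataFrame:
    lookup = dict(zip(popmap.sample_id, popmap.population))
    unknown = [s for s in samples if s not in lookup]
    if unknown:
        raise GenotypeDataError(
            f"samples missing from popmap: {', '.join(map(str, unknown[:10]))}"
            + ("..." if len(unknown) > 10 else "")
        )
    return pd.DataFrame(
        {"sample_id": samples, "population": [lookup[s] for s in samples]}
    )


def _read_snp_map(map_path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(map_path, sep="\t", dtype={"snp_id": str, "chromosome": str, "region": str})
    cols = {"snp_id", "chromosome", "region", "position_bp"}
    if not cols.issubset(m.columns):
        raise GenotypeDataError(f"SNP map must have columns {sorted(cols)}")
    return pd.DataFrame(
        {
            "snp_id": m.snp_id,
            "chrom": m.chromosome,
            "region": m.region,
            "pos": m.position_bp.astype(int),
        }
    )


def read_genotypes(
    genotype_path: str | Path,
    popmap_path: str | Path,
    map_path: str | Path | None = None,
    multiallelic: str = "error",
) -> GenotypeDataset:
    """Read genotypes (VCF or the TSV dialect) plus popmap and optional SNP map.

    ``multiallelic`` controls VCF records with more than one ALT allele:
    ``"error"`` rejects the file, ``"skip"`` drops them with a warning.
    """
    genotype_path = Path(genotype_path)
    if genotype_path.suffix in {".vcf", ".gz", ".bcf"} or genotype_path.name.endswith(
        ".vcf.gz"
    ):
        return _read_vcf(genotype_path, popmap_path, map_path, multiallelic)
    return _read_tsv(genotype_path, popmap_path, map_path)


def _read_tsv(
    genotype_path: Path, popmap_path: str | Path, map_path: str | Path | None
) -> GenotypeDataset:
    gt = pd.read_csv(
        genotype_path, sep="\t", dtype=str, keep_default_na=False
    ).set_index("sample_id")
    calls = gt.replace("NA", str(MISSING)).astype(np.int8).to_numpy()
    samples = _attach_populations(list(gt.index), _read_popmap(popmap_path))
    if map_path is not None:
        snps = _read_snp_map(map_path)
        snps = snps.set_index("snp_id").loc[list(gt.columns)].reset_index()
    else:
        snps = pd.DataFrame(
            {
                "snp_id": gt.columns,
                "chrom": "1",
                "region": "1",
                "pos": np.arange(1, gt.shape[1] + 1),
            }
        )
    return GenotypeDataset(samples, snps, calls)


def _read_vcf(
    vcf_path: Path,
    popmap_path: str | Path,
    map_path: str | Path | None,
    multiallelic: str,
) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    snp_rows, call_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if multiallelic == "skip":
                warnings.warn(
                    f"skipping multi-allelic record {var.CHROM}:{var.POS}", stacklevel=2
                )
                continue
            raise GenotypeDataError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; "
                "pass multiallelic='skip' to drop such sites"
            )
        snp_rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": var.CHROM,
                "region": var.CHROM,
                "pos": var.POS,
            }
        )
        # gts012: 0/1/2 = alt count, 3 = missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        call_rows.append(g)
    vcf.close()
    if not snp_rows:
        raise GenotypeDataError(f"no biallelic SNVs in {vcf_path}")
    snps = pd.DataFrame(snp_rows)
    calls = np.stack(call_rows, axis=1)
    if map_path is not None:
        snp_map = _read_snp_map(map_path).set_index("snp_id")
        snps["region"] = snp_map.reindex(snps.snp_id).region.fillna(snps.region).to_numpy()
    samples = _attach_populations(sample_ids, _read_popmap(popmap_path))
    return GenotypeDataset(samples, snps, calls)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_tsv(
    ds: GenotypeDataset,
    genotype_path: str | Path,
    popmap_path: str | Path | None = None,
    map_path: str | Path | None = None,
) -> None:
    """Write the TSV dialect (genotypes, optional popmap and SNP map)."""
    gt = pd.DataFrame(
        ds.calls, index=ds.samples.sample_id, columns=ds.snps.snp_id
    ).astype(object)
    gt[gt == MISSING] = "NA"
    gt.to_csv(genotype_path, sep="\t", index_label="sample_id")
    if popmap_path is not None:
        ds.samples.to_csv(popmap_path, sep="\t", index=False)
    if map_path is not None:
        out = ds.snps.rename(columns={"chrom": "chromosome", "pos": "position_bp"})
        out[["snp_id", "chromosome", "region", "position_bp"]].to_csv(
            map_path, sep="\t", index=False
        )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: GenotypeDataset, vcf_path: str | Path) -> None:
    """Write an uncompressed VCF v4.2 with unphased diploid genotypes."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=catld\n")
        for chrom in dict.fromkeys(ds.snps.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.samples.sample_id)
            + "\n"
        )
        for j, snp in ds.snps.iterrows():
            gts = "\t".join(_GT_STR[int(g)] for g in ds.calls[:, j])
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )
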