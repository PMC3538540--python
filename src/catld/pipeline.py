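"""End-to-end orchestration: QC → LD → decay → blocks → stats → reports.

``run_pipeline`` consumes a validated :class:`RunConfig` and writes, under
the output directory:

* ``qc_report.tsv`` — per population × MAF level filter tally
* ``ld_<pop>.tsv`` — intra-chromosome pairwise LD at the primary MAF
* ``decay_summary.tsv`` — one row per population with the panel-style
  columns (n, % SNPs retained, half-decay r² level and distance, MAF-0.1
  inflation, fraction of r² ≥ 0.8 pairs at 40–60 kb)
* ``fits.tsv`` — per population × scope decay coefficients
* ``blocks.tsv`` / ``haplotypes.tsv`` — solid-spine blocks and their
  EM haplotypes
* ``popstats.tsv`` — Ho/He/F_is and Tajima's D per population × region
* ``fst_matrix.tsv`` and ``nj_tree.nwk``
* ``manifest.json`` — config, seed and library versions; two runs with
  equal manifests produce byte-identical outputs

The "Auto" scope excludes the X-labelled chromosome (LD on X is elevated by
its smaller effective size), "All" keeps every chromosome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blocks import blocks_frame, diversity_summary, solid_spine_blocks
from .decay import (
    MAX_DISTANCE_KB,
    fit_population_decay,
    informative_fractions,
    maf_inflation,
)
from .genotype_io import GenotypeDataset, apply_qc, qc_report_frame, read_genotypes
from .ld import write_ld_table
from .popstats import fst_matrix, nj_tree, population_region_summary, tree_to_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotype_path: str
    popmap_path: str
    map_path: str | None = None
    out_dir: str = "results/run"
    maf_levels: tuple[float, float] = (0.05, 0.1)
    call_rate_min: float = 0.80
    dprime_threshold: float = 0.8
    r2_threshold: float = 0.8
    scopes: tuple[str, ...] = ("Auto",)
    x_label: str = "X"
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.genotype_path).exists():
            raise FileNotFoundError(self.genotype_path)
        if not Path(self.popmap_path).exists():
            raise FileNotFoundError(self.popmap_path)
        if not 0 < self.call_rate_min <= 1:
            raise ValueError("call_rate_min must be in (0, 1]")
        if len(self.maf_levels) != 2 or not all(0 <= m < 0.5 for m in self.maf_levels):
            raise ValueError("maf_levels must be two values in [0, 0.5)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("maf_levels", "scopes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(cfg: RunConfig, ds: GenotypeDataset | None = None) -> dict:
    """Run every stage and write the report bundle; returns output paths."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ds is None:
        ds = read_genotypes(cfg.genotype_path, cfg.popmap_path, cfg.map_path)

    maf_primary, maf_alt = sorted(cfg.maf_levels)
    reports = []
    summary_rows = []
    fit_rows = []
    all_blocks = []
    outputs: dict[str, str] = {}

    for pop in ds.populations:
        for maf in cfg.maf_levels:
            _, rep = apply_qc(ds, pop, maf_min=maf, call_rate_min=cfg.call_rate_min)
            rep.population = f"{pop}@maf{maf}"
            reports.append(rep)
        _, rep05 = apply_qc(ds, pop, maf_min=maf_primary, call_rate_min=cfg.call_rate_min)

        row = {
            "population": pop,
            "n": int((ds.samples.population == pop).sum()),
            "pct_snps_included": round(rep05.pct_retained, 1),
            "r2_at_half_decay": np.nan,
            "dist_kb": "",
            "pct_inflation_maf10": np.nan,
            "fraction_r2ge0.8_40_60kb": np.nan,
        }
        try:
            fit, hd, table = fit_population_decay(
                ds, pop, maf_min=maf_primary, call_rate_min=cfg.call_rate_min,
                scope="Auto", x_label=cfg.x_label,
            )
            ld_path = out / f"ld_{pop}.tsv"
            write_ld_table(table, ld_path)
            outputs[f"ld_{pop}"] = str(ld_path)
            fit_rows.append(
                {"population": pop, "scope": "Auto", "a_per_kb": fit.a_per_kb,
                 "n": fit.n, "n_pairs": fit.n_pairs, "rss": fit.rss,
                 "converged": fit.converged}
            )
            if fit.converged:
                row["r2_at_half_decay"] = round(hd.r2_level, 2)
                row["dist_kb"] = hd.distance_str()
            frac = informative_fractions(table, r2_threshold=cfg.r2_threshold)
            band = frac[(frac.lo_kb == 40) & (frac.hi_kb == 60)]
            if not band.empty:
                row["fraction_r2ge0.8_40_60kb"] = round(
                    float(band.fraction_ge_threshold.iloc[0]), 2
                )
            try:
                row["pct_inflation_maf10"] = round(
                    maf_inflation(ds, pop, scope="Auto",
                                  maf_low=maf_primary, maf_high=maf_alt), 1
                )
            except ValueError as exc:
                logger.warning("inflation undefined for %s: %s", pop, exc)
        except ValueError as exc:
            logger.warning("decay stage skipped for %s: %s", pop, exc)

        for scope in cfg.scopes:
            if scope == "Auto":
                continue
            try:
                fit_s, hd_s, _ = fit_population_decay(
                    ds, pop, maf_min=maf_primary, call_rate_min=cfg.call_rate_min,
                    scope=scope, x_label=cfg.x_label,
                )
                fit_rows.append(
                    {"population": pop, "scope": scope, "a_per_kb": fit_s.a_per_kb,
                     "n": fit_s.n, "n_pairs": fit_s.n_pairs, "rss": fit_s.rss,
                     "converged": fit_s.converged}
                )
            except ValueError as exc:
                logger.warning("scope %s skipped for %s: %s", scope, pop, exc)

        try:
            all_blocks.extend(
                solid_spine_blocks(ds, pop, maf_min=maf_primary,
                                   dprime_threshold=cfg.dprime_threshold,
                                   call_rate_min=cfg.call_rate_min)
            )
        except ValueError as exc:
            logger.warning("block stage skipped for %s: %s", pop, exc)

        summary_rows.append(row)

    qc_path = out / "qc_report.tsv"
    qc_report_frame(reports).to_csv(qc_path, sep="\t", index=False)
    summary_path = out / "decay_summary.tsv"
    pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
    fits_path = out / "fits.tsv"
    pd.DataFrame(fit_rows).to_csv(fits_path, sep="\t", index=False)

    blocks_path = out / "blocks.tsv"
    blocks_frame(all_blocks).to_csv(blocks_path, sep="\t", index=False)
    hap_rows = [
        {"population": b.population, "region": b.region,
         "block": f"{b.population}:{b.region}:{b.start_bp}-{b.end_bp}",
         "alleles": s, "frequency": round(f, 4), "class": c}
        for b in all_blocks
        for s, f, c in b.haplotypes
    ]
    hap_path = out / "haplotypes.tsv"
    pd.DataFrame(hap_rows).to_csv(hap_path, sep="\t", index=False)
    div_path = out / "diversity.tsv"
    diversity_summary(all_blocks).to_csv(div_path, sep="\t", index=False)

    stats_path = out / "popstats.tsv"
    population_region_summary(ds).to_csv(stats_path, sep="\t", index=False,
                                         float_format="%.4f")

    tree_path = fst_path = None
    if len(ds.populations) >= 3:
        mat = fst_matrix(ds)
        fst_path = out / "fst_matrix.tsv"
        mat.to_csv(fst_path, sep="\t", float_format="%.5f")
        tree_path = out / "nj_tree.nwk"
        Path(tree_path).write_text(tree_to_newick(nj_tree(mat)) + "\n")

    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "versions": {
            "catld": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": {
            "qc_report": str(qc_path),
            "decay_summary": str(summary_path),
            "fits": str(fits_path),
            "blocks": str(blocks_path),
            "haplotypes": str(hap_path),
            "diversity": str(div_path),
            "popstats": str(stats_path),
            "fst_matrix": str(fst_path) if fst_path else None,
            "nj_tree": str(tree_path) if tree_path else None,
            **outputs,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest["outputs"]
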