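"""End-to-end orchestration: simulate/load -> normalize -> three
contrasts -> inheritance classification -> enrichment -> report.

Every stage's table is written to the output directory together with a
JSON manifest recording the configuration, seed and per-stage row
counts, and a stats.json of headline numbers, all recomputable from the
written tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, enrichment, inheritance, io_formats, normalization, summary
from .diffexpr import ContrastSpec
from .simulate import SimConfig, simulate_experiment

log = logging.getLogger("hybriddom")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``sim`` (synthetic experiment) or ``counts_path`` +
    ``samples_path`` must be provided.  Group labels name the hybrid
    and the two parents in the sample table; the three contrasts
    (parent1 vs parent2, hybrid vs each parent) are derived from them.
    """

    sim: SimConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    go_path: str | None = None
    anchored_chroms: tuple = ()
    group_hybrid: str = "hybrid"
    group_parent1: str = "parent1"
    group_parent2: str = "parent2"
    alpha: float = 0.05
    lfc_threshold: float = 0.32  # log2(1.25), the 1.25-fold rule
    min_count: int = 10
    min_fraction: float = 0.5
    chisq_correction: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.lfc_threshold < 0:
            raise ValueError("alpha and lfc_threshold must be non-negative")
        if self.sim is None and (self.counts_path is None or self.samples_path is None):
            raise ValueError("provide either a SimConfig or counts_path + samples_path")
        groups = {self.group_hybrid, self.group_parent1, self.group_parent2}
        if len(groups) != 3:
            raise ValueError("hybrid/parent1/parent2 group labels must be distinct")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "replicates" in sim:
                sim["replicates"] = dict(sim["replicates"])
            if "size_factor_range" in sim:
                sim["size_factor_range"] = tuple(sim["size_factor_range"])
            raw["sim"] = SimConfig(**sim)
        if "anchored_chroms" in raw and raw["anchored_chroms"] is not None:
            raw["anchored_chroms"] = tuple(raw["anchored_chroms"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a dict of in-memory results.

    Keys: counts, samples, truth (synthetic runs), size_factors,
    contrasts (name -> ContrastResult table), calls, inheritance_summary,
    de_summary, enrichment, stats, manifest.
    """
    t0 = time.time()
    truth = None
    annotation = None
    if config.sim is not None:
        sim = config.sim
        if sim.seed != config.seed:
            from dataclasses import replace

            sim = replace(sim, seed=config.seed)
        cm, samples, truth = simulate_experiment(sim)
        annotation = pd.DataFrame(
            {
                "gene_id": truth["gene_id"],
                "chromosome": truth["chromosome"],
                "chrom_category": truth["chromosome"],
            }
        )
        log.info("simulate: %d genes x %d samples", cm.n_genes, cm.n_samples)
    else:
        cm = io_formats.read_counts(config.counts_path)
        samples = io_formats.read_sample_table(config.samples_path)
        io_formats.validate_samples(cm, samples)
        if config.annotation_path:
            annotation = io_formats.read_gff_gene_map(
                config.annotation_path, config.anchored_chroms
            )
        log.info("load: %d genes x %d samples", cm.n_genes, cm.n_samples)

    relabel = {
        config.group_parent1: "parent1",
        config.group_parent2: "parent2",
        config.group_hybrid: "hybrid",
    }
    samples = samples.copy()
    samples["group"] = samples["group"].map(lambda g: relabel.get(g, g))

    factors = normalization.size_factors_median_of_ratios(cm)
    log.info("normalize: size factors in [%.3f, %.3f]", factors.min(), factors.max())

    specs = [
        ContrastSpec("parent2_vs_parent1", "parent2", "parent1"),
        ContrastSpec("hybrid_vs_parent1", "hybrid", "parent1"),
        ContrastSpec("hybrid_vs_parent2", "hybrid", "parent2"),
    ]
    contrasts: dict[str, pd.DataFrame] = {}
    for spec in specs:
        res = diffexpr.run_contrast(
            cm,
            samples,
            factors,
            spec,
            alpha=config.alpha,
            lfc_threshold=config.lfc_threshold,
            min_count=config.min_count,
            min_fraction=config.min_fraction,
        )
        contrasts[spec.name] = res
        log.info(
            "contrast %s: %d tested, %d DE",
            spec.name,
            int(res["tested"].sum()),
            int(res["de"].sum()),
        )

    calls = inheritance.classify_all(
        contrasts["hybrid_vs_parent1"],
        contrasts["hybrid_vs_parent2"],
        lfc_threshold=config.lfc_threshold,
        alpha=config.alpha,
    )
    inh_summary = inheritance.inheritance_summary(calls)
    de_sum = summary.de_summary(contrasts)

    tally = inh_summary.set_index("category")["count"]
    stats: dict = {
        "alpha": config.alpha,
        "lfc_threshold": config.lfc_threshold,
        "background": int(tally["background"]),
        "transgressive": int(tally["transgressive"]),
        "nonconserved": int(tally["nonconserved"]),
        "transgressive_pct": float(
            inh_summary.set_index("category").loc["transgressive", "percent"]
        ),
    }
    de_by_name = de_sum.set_index("contrast")
    stats["divergence"] = summary.divergence_report(
        int(de_by_name.loc["hybrid_vs_parent1", "n_significant"]),
        int(de_by_name.loc["hybrid_vs_parent2", "n_significant"]),
        int(de_by_name.loc["parent2_vs_parent1", "n_significant"]),
    )
    try:
        chi_stat, chi_p = summary.updown_chisq(
            int(de_by_name.loc["hybrid_vs_parent1", "n_up"]),
            int(de_by_name.loc["hybrid_vs_parent1", "n_down"]),
            int(de_by_name.loc["hybrid_vs_parent2", "n_up"]),
            int(de_by_name.loc["hybrid_vs_parent2", "n_down"]),
            correction=config.chisq_correction,
        )
        stats["updown_chisq"] = {"statistic": chi_stat, "pvalue": chi_p}
    except ValueError:
        stats["updown_chisq"] = None

    enrich_rows = []
    if annotation is not None:
        for name, res in contrasts.items():
            tested = res[res["tested"].astype(bool)]
            flags = tested.set_index("gene_id")["de"].astype(bool)
            try:
                row = enrichment.chromosome_enrichment(flags, annotation)
            except ValueError:
                continue
            row["contrast"] = name
            enrich_rows.append(row)
    enrich_table = pd.DataFrame(enrich_rows) if enrich_rows else pd.DataFrame()

    go_tables = {}
    if config.go_path:
        go = io_formats.read_go_annotations(config.go_path)
        for name, res in contrasts.items():
            tested = res[res["tested"].astype(bool)]
            de_genes = tested.loc[tested["de"].astype(bool), "gene_id"]
            go_tables[name] = enrichment.go_ora(
                de_genes, tested["gene_id"], go, alpha=config.alpha
            )

    if truth is not None:
        merged = calls.merge(truth[["gene_id", "true_mode"]], on="gene_id")
        bg = merged[merged["in_background"].astype(bool)]
        correct = (bg["category"] == bg["true_mode"]).groupby(bg["true_mode"]).mean()
        stats["recovery_by_true_mode"] = {k: float(v) for k, v in correct.items()}
        true_trans = bg["true_mode"].isin(["over_dominant", "under_dominant"])
        stats["true_transgressive_pct"] = float(100.0 * true_trans.mean())

    results = {
        "counts": cm,
        "samples": samples,
        "truth": truth,
        "size_factors": factors,
        "contrasts": contrasts,
        "calls": calls,
        "inheritance_summary": inh_summary,
        "de_summary": de_sum,
        "enrichment": enrich_table,
        "go": go_tables,
        "stats": stats,
    }

    if config.out_dir is not None:
        tables = {
            "size_factors": factors.rename_axis("sample_id").reset_index(),
            "samples": samples,
            "calls": calls,
            "inheritance_summary": inh_summary,
            "de_summary": de_sum,
        }
        for name, res in contrasts.items():
            tables[f"contrast_{name}"] = res
        if truth is not None:
            tables["truth"] = truth
        if len(enrich_table):
            tables["chromosome_enrichment"] = enrich_table
        for name, tab in go_tables.items():
            tables[f"go_{name}"] = tab
        manifest = io_formats.write_results(
            tables, config.out_dir, config=config, seed=config.seed
        )
        io_formats.write_counts(cm, Path(config.out_dir) / "counts.tsv")
        with open(Path(config.out_dir) / "stats.json", "w") as fh:
            json.dump(io_formats._jsonable(stats), fh, indent=2)
        results["manifest"] = manifest

    log.info("pipeline finished in %.1f s", time.time() - t0)
    return results
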