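"""Config-driven orchestration: manifest in, analysis report bundle out.

``run_analysis`` composes the whole downstream analysis per subset x chain
class: per-sample unique-CDR3 counts with the exact WT-vs-KO rank-sum test,
pooled clone tables with the replicated (>1%) partition, contingency tables
with chi-squared association tests in unique- and total-count modes, isotype
distributions, V/J usage and pairing tables, kappa/lambda ratios, and the
four-group shared-CDR3 overlap.  Every number in the JSON report is also
present in a machine-readable TSV in the bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clonality import (
    DEFAULT_THRESHOLD,
    build_clone_table,
    build_contingency,
    replicated_summary,
    unique_counts_per_sample,
)
from .io import load_study
from .model import SUBSETS, Repertoire
from .overlap import overlap_from_clone_tables, top_clone_tracking
from .stats import exact_rank_sum, pearson_chi2
from .usage import isotype_distribution, kappa_lambda_ratio, usage_table, vj_pairing

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Settings of one analysis run."""

    manifest: str
    out_dir: str
    chains: tuple[str, ...] = ("heavy", "light")
    threshold: float = DEFAULT_THRESHOLD
    weighting: str = "abundance"  # usage/isotype weighting
    usage_level: str = "family"
    top_k: int = 2
    seed: int = 0
    productive_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update(overrides)
        if "chains" in payload:
            payload["chains"] = tuple(payload["chains"])
        return cls(**payload)


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Run the full pipeline and write the report bundle to ``cfg.out_dir``.

    Returns the JSON-serializable report.  Groups with fewer than two
    samples skip rank tests (with a warning) but keep pooled statistics.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reps = load_study(cfg.manifest, productive_only=cfg.productive_only)
    metas = [r.meta for r in reps]

    report: dict = {
        "config": {
            "manifest": str(cfg.manifest),
            "chains": list(cfg.chains),
            "threshold": cfg.threshold,
            "weighting": cfg.weighting,
            "usage_level": cfg.usage_level,
            "seed": cfg.seed,
            "productive_only": cfg.productive_only,
            "version": __version__,
        },
        "samples": [
            {"sample_id": m.sample_id, "genotype": m.genotype, "subset": m.subset}
            for m in metas
        ],
        "groups": {},
        "overlap": {},
    }

    clone_tables: dict[tuple[str, str, str], object] = {}
    for chain in cfg.chains:
        for subset in SUBSETS:
            group_reps = [r for r in reps if r.meta.subset == subset]
            if not group_reps:
                continue
            key = f"{subset}/{chain}"
            report["groups"][key] = _analyze_group(
                group_reps, subset, chain, cfg, out, clone_tables
            )
        # four-group overlap per chain on all clones
        tables = [clone_tables[k] for k in sorted(clone_tables) if k[2] == chain]
        if len(tables) >= 2:
            overlap_all = {}
            pairs = _overlap_pairs(tables)
            for label, pair in pairs.items():
                overlap_all[label] = overlap_from_clone_tables(pair).to_dict()
            if len(tables) >= 3:
                overlap_all["all_groups"] = overlap_from_clone_tables(tables).to_dict()
            report["overlap"][chain] = overlap_all

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    log.info("report written to %s", report_path)
    return report


def _overlap_pairs(tables) -> dict:
    by_key = {(t.subset, t.genotype): t for t in tables}
    wanted = [
        (("B-1a", "WT"), ("B-1a", "KO")),
        (("B-1b", "WT"), ("B-1b", "KO")),
        (("B-1a", "KO"), ("B-1b", "KO")),
        (("B-1a", "WT"), ("B-1b", "WT")),
    ]
    return {
        f"{a[0]}-{a[1]}_vs_{b[0]}-{b[1]}": (by_key[a], by_key[b])
        for a, b in wanted
        if a in by_key and b in by_key
    }


def _analyze_group(group_reps, subset, chain, cfg, out: Path, clone_tables) -> dict:
    """All per-(subset, chain) computations."""
    result: dict = {}
    tag = f"{subset.replace('-', '')}_{chain}"

    # per-sample unique counts + rank test
    counts = unique_counts_per_sample(group_reps, chain)
    by_geno = {
        g: [counts[r.meta.sample_id] for r in group_reps if r.meta.genotype == g]
        for g in ("WT", "KO")
    }
    result["unique_counts"] = {r.meta.sample_id: counts[r.meta.sample_id] for r in group_reps}
    if min(len(by_geno["WT"]), len(by_geno["KO"])) >= 2:
        rs = exact_rank_sum(by_geno["WT"], by_geno["KO"])
        result["unique_count_rank_sum"] = rs.to_dict()
    else:
        log.warning("%s/%s: fewer than 2 samples per genotype; rank test skipped", subset, chain)
        result["unique_count_rank_sum"] = None

    # pooled clone tables per genotype
    tables = {}
    for genotype in ("WT", "KO"):
        geno_reps = [r for r in group_reps if r.meta.genotype == genotype]
        if not geno_reps:
            continue
        ct = build_clone_table(geno_reps, chain, cfg.threshold)
        tables[genotype] = ct
        clone_tables[(subset, genotype, chain)] = ct
        ct.to_tsv(out / f"clone_table_{tag}_{genotype}.tsv")
        result.setdefault("replicated", {})[genotype] = replicated_summary(ct).to_dict()

    # contingency + chi-squared, both modes
    if {"WT", "KO"} <= set(tables):
        result["association"] = {}
        for mode in ("unique", "total"):
            table = build_contingency(tables["WT"], tables["KO"], mode)
            chi2 = pearson_chi2(table.table)
            result["association"][mode] = {"table": table.to_dict(), "chi2": chi2.to_dict()}

        # top-clone tracking: WT reference into KO
        tracking = top_clone_tracking(tables["WT"], [tables["KO"]], k=cfg.top_k)
        tracking.to_csv(out / f"top_clones_{tag}.tsv", sep="\t", lineterminator="\n")
        result["top_clones"] = json.loads(tracking.to_json(orient="index"))

    # usage, pairing, isotypes, kappa/lambda
    for seg_class in ("V", "J") if chain == "light" else ("V", "D", "J"):
        ut = usage_table(group_reps, cfg.usage_level, seg_class, cfg.weighting, chain)
        ut.frequencies.to_csv(
            out / f"usage_{tag}_{seg_class}.tsv", sep="\t",
            index_label="sample_id", lineterminator="\n",
        )
        metas = [r.meta for r in group_reps]
        if min(len(by_geno["WT"]), len(by_geno["KO"])) >= 2:
            comp = ut.compare_groups(metas)
            comp.to_csv(out / f"usage_{tag}_{seg_class}_comparison.tsv",
                        sep="\t", lineterminator="\n")

    for genotype, ct in tables.items():
        for scope in ("all", "replicated"):
            try:
                pm = vj_pairing(ct, cfg.usage_level, scope)
            except ValueError:
                continue  # no replicated clones in scope
            pm.to_tsv(out / f"vj_pairing_{tag}_{genotype}_{scope}.tsv")

    if chain == "heavy":
        iso_table, iso_comp = isotype_distribution(group_reps, cfg.weighting)
        iso_table.to_csv(out / f"isotypes_{tag}.tsv", sep="\t", lineterminator="\n")
        result["isotypes"] = {
            "per_sample": json.loads(iso_table.drop(columns=["genotype", "subset"]).to_json(orient="index")),
            "comparison": json.loads(iso_comp.to_json(orient="index")) if len(iso_comp) else None,
        }
    else:
        kl_table, kl_comp = kappa_lambda_ratio(group_reps, cfg.weighting)
        kl_table.to_csv(out / f"kappa_lambda_{tag}.tsv", sep="\t", lineterminator="\n")
        result["kappa_lambda"] = {
            "per_sample": json.loads(
                kl_table.drop(columns=["genotype", "subset"]).replace(
                    [float("inf")], "inf").to_json(orient="index")
            ),
            "comparison": kl_comp.to_dict() if kl_comp else None,
        }

    return result
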