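"""Segment usage, V-J pairing, isotype distribution, kappa/lambda ratio.

Gene names follow IMGT nomenclature: an allele suffix ``*NN`` after the gene,
and a family number directly after the locus + segment-class prefix (so
``IGHV11-2*01`` is allele 01 of gene IGHV11-2 in family IGHV11).  Family is
the default reporting level, matching how murine B-1 V_H skew (V_H_1, V_H_11,
V_H_12) is usually reported.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ISOTYPES, assign_isotype
from .model import Repertoire, SampleMeta
from .clonality import CloneTable
from .stats import RankSumResult, exact_rank_sum

log = logging.getLogger(__name__)

_GENE_RE = re.compile(r"^(IG[HKL][VDJ])(\d+)")


@dataclass(frozen=True)
class GeneName:
    gene: str
    family: str


def parse_gene(call: str) -> GeneName:
    """Split a segment call into (gene, family), stripping the allele.

    ``IGHV11-2*01`` -> gene ``IGHV11-2``, family ``IGHV11``.  Unparseable
    names keep the stripped string as gene with family ``"unknown"``.
    """
    if not call:
        raise ValueError("empty segment call")
    gene = call.split("*", 1)[0].strip()
    m = _GENE_RE.match(gene.upper())
    if not m:
        log.debug("unparseable segment name %r", call)
        return GeneName(gene=gene, family="unknown")
    return GeneName(gene=gene, family=m.group(1) + m.group(2))


def _segment_of(call: str, level: str) -> str | None:
    if not call:
        return None
    name = parse_gene(call)
    return name.gene if level == "gene" else name.family


@dataclass
class UsageTable:
    """Per-sample segment usage frequencies.

    ``frequencies`` is samples x segments; each sample row sums to 1 over
    the segments observed in that sample.
    """

    level: str  # "gene" | "family"
    segment_class: str  # "V" | "D" | "J"
    weighting: str  # "abundance" | "clonotype"
    frequencies: pd.DataFrame  # index: sample_id, columns: segment names

    def compare_groups(self, metas: Sequence[SampleMeta]) -> pd.DataFrame:
        """Per-segment WT-vs-KO rank-sum comparison, unadjusted p-values."""
        by_id = {m.sample_id: m for m in metas}
        genotype = self.frequencies.index.map(lambda s: by_id[s].genotype)
        wt = self.frequencies[genotype == "WT"]
        ko = self.frequencies[genotype == "KO"]
        rows = []
        for seg in self.frequencies.columns:
            result = exact_rank_sum(wt[seg].to_numpy(), ko[seg].to_numpy())
            rows.append(
                {
                    "segment": seg,
                    "wt_mean": float(wt[seg].mean()),
                    "ko_mean": float(ko[seg].mean()),
                    "u_statistic": result.u_statistic,
                    "p": result.p_two_sided,
                    "method": result.method,
                }
            )
        return pd.DataFrame(rows).set_index("segment")


def usage_table(
    reps: Iterable[Repertoire],
    level: str = "family",
    segment_class: str = "V",
    weighting: str = "abundance",
    chain: str = "heavy",
) -> UsageTable:
    """Per-sample normalized segment usage.

    ``weighting="abundance"`` weights each record by its read count;
    ``"clonotype"`` counts each unique CDR3 once per sample.
    """
    if level not in ("gene", "family"):
        raise ValueError("level must be 'gene' or 'family'")
    if segment_class not in ("V", "D", "J"):
        raise ValueError("segment_class must be 'V', 'D' or 'J'")
    if weighting not in ("abundance", "clonotype"):
        raise ValueError("weighting must be 'abundance' or 'clonotype'")
    call_attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment_class]

    per_sample: dict[str, dict[str, float]] = {}
    for rep in reps:
        weights: dict[str, float] = {}
        seen_clones: set[str] = set()
        for rec in rep.chain_class(chain):
            seg = _segment_of(getattr(rec, call_attr), level)
            if seg is None:
                continue
            if weighting == "abundance":
                weights[seg] = weights.get(seg, 0.0) + rec.abundance
            else:
                if rec.junction_aa in seen_clones:
                    continue
                seen_clones.add(rec.junction_aa)
                weights[seg] = weights.get(seg, 0.0) + 1.0
        total = sum(weights.values())
        per_sample[rep.meta.sample_id] = (
            {seg: w / total for seg, w in weights.items()} if total else {}
        )

    frequencies = pd.DataFrame.from_dict(per_sample, orient="index").fillna(0.0)
    frequencies = frequencies.reindex(sorted(frequencies.columns), axis=1)
    return UsageTable(level=level, segment_class=segment_class,
                      weighting=weighting, frequencies=frequencies)


@dataclass
class PairingMatrix:
    """Relative frequency of each V-J pairing within one pooled group.

    Cells sum to 1 over the chosen scope ("all" clones, or "replicated"
    clones renormalized).  Row sums are the V usage and column sums the J
    usage of the same pooled clones under the same weighting.
    """

    level: str
    scope: str  # "all" | "replicated"
    matrix: pd.DataFrame  # index: V segments, columns: J segments

    def v_marginal(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    def j_marginal(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="v_segment", lineterminator="\n")


def vj_pairing(ct: CloneTable, level: str = "family", scope: str = "all") -> PairingMatrix:
    """V-J pairing matrix from a clone table (the circos-plot table).

    Pair frequency is the summed clone frequency per (V, J) pair; in
    ``scope="replicated"`` only replicated clones contribute and their
    frequencies are renormalized.  Clones with a missing V or J call are
    excluded and logged.
    """
    if scope not in ("all", "replicated"):
        raise ValueError("scope must be 'all' or 'replicated'")
    entries = ct.replicated if scope == "replicated" else ct.entries
    rows = []
    skipped = 0
    for junction_aa, entry in entries.iterrows():
        v = _segment_of(entry["v_call"], level)
        j = _segment_of(entry["j_call"], level)
        if v is None or j is None:
            skipped += 1
            continue
        rows.append((v, j, entry["frequency"]))
    if skipped:
        log.info("vj_pairing: excluded %d clones with missing V or J call", skipped)
    if not rows:
        raise ValueError(f"no clones with complete V/J calls in scope {scope!r}")
    df = pd.DataFrame(rows, columns=["v", "j", "freq"])
    matrix = df.pivot_table(index="v", columns="j", values="freq", aggfunc="sum", fill_value=0.0)
    matrix = matrix.sort_index().sort_index(axis=1)
    matrix /= matrix.to_numpy().sum()
    return PairingMatrix(level=level, scope=scope, matrix=matrix)


def usage_from_clone_table(
    ct: CloneTable, segment_class: str = "V", level: str = "family", scope: str = "all"
) -> pd.Series:
    """Pooled segment usage over a clone table's representative calls.

    Weighted by clone frequency (renormalized in replicated scope); this is
    the marginal a :func:`vj_pairing` matrix must reproduce exactly.
    """
    call_col = {"V": "v_call", "J": "j_call"}[segment_class]
    entries = ct.replicated if scope == "replicated" else ct.entries
    weights: dict[str, float] = {}
    for _, entry in entries.iterrows():
        seg = _segment_of(entry[call_col], level)
        if seg is None:
            continue
        weights[seg] = weights.get(seg, 0.0) + entry["frequency"]
    series = pd.Series(weights).sort_index()
    return series / series.sum()


@dataclass(frozen=True)
class KappaLambdaSample:
    sample_id: str
    kappa: float
    lambda_: float

    @property
    def ratio(self) -> float:
        return self.kappa / self.lambda_ if self.lambda_ > 0 else math.inf

    @property
    def degenerate(self) -> bool:
        return self.lambda_ == 0


def kappa_lambda_ratio(
    reps: Iterable[Repertoire], weighting: str = "abundance"
) -> tuple[pd.DataFrame, RankSumResult | None]:
    """Per-sample IGK/IGL ratio and the WT-vs-KO rank-sum comparison.

    Samples with zero IGL mass are flagged infinite; the rank test runs on
    the finite log-scale-safe ratios unless a group is entirely degenerate
    (then no comparison is returned).
    """
    if weighting not in ("abundance", "clonotype"):
        raise ValueError("weighting must be 'abundance' or 'clonotype'")
    rows = []
    for rep in reps:
        light = rep.chain_class("light")
        if weighting == "abundance":
            kappa = sum(r.abundance for r in light if r.locus == "IGK")
            lam = sum(r.abundance for r in light if r.locus == "IGL")
        else:
            kappa = len({r.junction_aa for r in light if r.locus == "IGK"})
            lam = len({r.junction_aa for r in light if r.locus == "IGL"})
        sample = KappaLambdaSample(rep.meta.sample_id, float(kappa), float(lam))
        rows.append(
            {
                "sample_id": sample.sample_id,
                "genotype": rep.meta.genotype,
                "subset": rep.meta.subset,
                "kappa": sample.kappa,
                "lambda": sample.lambda_,
                "ratio": sample.ratio,
                "degenerate": sample.degenerate,
            }
        )
    table = pd.DataFrame(rows).set_index("sample_id")
    wt = table.loc[(table["genotype"] == "WT") & np.isfinite(table["ratio"]), "ratio"]
    ko = table.loc[(table["genotype"] == "KO") & np.isfinite(table["ratio"]), "ratio"]
    comparison = exact_rank_sum(wt, ko) if len(wt) and len(ko) else None
    return table, comparison


def isotype_distribution(
    reps: Iterable[Repertoire], weighting: str = "abundance"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample isotype proportions and per-isotype WT-vs-KO comparison.

    Proportions are over {IgM, IgD, IgG, IgA, IgE} from heavy-chain records
    with an assignable constant gene (others excluded and logged); each
    sample's proportions sum to 1.  Returns (proportion table, comparison
    table of unadjusted rank-sum p per isotype).
    """
    reps = list(reps)
    rows = []
    for rep in reps:
        weights = dict.fromkeys(ISOTYPES, 0.0)
        seen: set[str] = set()
        excluded = 0
        for rec in rep.chain_class("heavy"):
            isotype = assign_isotype(rec.c_call)
            if isotype is None:
                excluded += 1
                continue
            if weighting == "clonotype":
                if rec.junction_aa in seen:
                    continue
                seen.add(rec.junction_aa)
                weights[isotype] += 1.0
            else:
                weights[isotype] += rec.abundance
        if excluded:
            log.info("%s: %d heavy records lack an assignable isotype", rep.meta.sample_id, excluded)
        total = sum(weights.values())
        if total == 0:
            log.warning("%s: no isotype-bearing records (degenerate sample)", rep.meta.sample_id)
        row = {iso: (w / total if total else 0.0) for iso, w in weights.items()}
        row.update(sample_id=rep.meta.sample_id, genotype=rep.meta.genotype,
                   subset=rep.meta.subset, degenerate=total == 0)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("sample_id")

    comp_rows = []
    wt = table[table["genotype"] == "WT"]
    ko = table[table["genotype"] == "KO"]
    if len(wt) and len(ko):
        for iso in ISOTYPES:
            result = exact_rank_sum(wt[iso].to_numpy(), ko[iso].to_numpy())
            comp_rows.append(
                {
                    "isotype": iso,
                    "wt_mean": float(wt[iso].mean()),
                    "ko_mean": float(ko[iso].mean()),
                    "p": result.p_two_sided,
                    "method": result.method,
                }
            )
    comparison = pd.DataFrame(comp_rows).set_index("isotype") if comp_rows else pd.DataFrame()
    return table, comparison
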