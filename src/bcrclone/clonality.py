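"""Clone tables and the replicated-CDR3 classification.

The clone is identified by its CDR3 amino-acid sequence.  Within a pooled
group (same cell subset and genotype), a clone is *replicated* when its
frequency — pooled abundance over the group's total abundance — is strictly
greater than a threshold, 1% by default.  This module builds the pooled
clone tables, the per-sample unique-CDR3 counts fed to the rank-sum test,
and the 2x2 replicated-vs-genotype contingency tables fed to the
chi-squared test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import Repertoire

DEFAULT_THRESHOLD = 0.01


@dataclass
class CloneTable:
    """Unique-CDR3 aggregation over one pooled group.

    ``entries`` has one row per unique ``junction_aa`` with columns
    ``abundance`` (pooled), ``frequency`` (of pooled abundance),
    ``replicated`` (strictly > threshold), ``n_samples`` and ``samples``
    (contributing sample ids), and the modal ``v_call``/``j_call``
    representatives used by the pairing analysis.
    """

    subset: str
    genotype: str
    chain: str
    threshold: float
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        total = float(self.entries["frequency"].sum())
        if len(self.entries) and abs(total - 1) > 1e-9:
            raise ValueError(f"clone frequencies sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def replicated(self) -> pd.DataFrame:
        return self.entries[self.entries["replicated"]]

    @property
    def non_replicated(self) -> pd.DataFrame:
        return self.entries[~self.entries["replicated"]]

    def junctions(self) -> set[str]:
        return set(self.entries.index)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index_label="junction_aa", lineterminator="\n")


@dataclass(frozen=True)
class ReplicatedSummary:
    """Counts and coverage of the replicated/non-replicated partition."""

    replicated_unique: int
    non_replicated_unique: int
    replicated_coverage: float  # fraction of pooled abundance in replicated clones

    @property
    def non_replicated_coverage(self) -> float:
        return 1.0 - self.replicated_coverage

    def to_dict(self) -> dict:
        return {
            "replicated_unique": self.replicated_unique,
            "non_replicated_unique": self.non_replicated_unique,
            "replicated_coverage": self.replicated_coverage,
        }


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows {replicated, non-replicated} x columns {WT, KO}.

    ``mode="unique"`` counts unique clones per cell; ``mode="total"`` sums
    pooled abundances.
    """

    subset: str
    chain: str
    mode: str
    table: np.ndarray  # shape (2, 2), rows (replicated, non-replicated), cols (WT, KO)

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "chain": self.chain,
            "mode": self.mode,
            "rows": ["replicated", "non_replicated"],
            "columns": ["WT", "KO"],
            "table": self.table.tolist(),
        }


def build_clone_table(
    reps: Sequence[Repertoire],
    chain: str = "heavy",
    threshold: float = DEFAULT_THRESHOLD,
) -> CloneTable:
    """Pool same-condition repertoires into a clone table.

    All repertoires must share subset and genotype (sequences are pooled
    from mice of the same cell type and condition).  Pooling is
    abundance-weighted; the replicated flag applies the strict
    ``frequency > threshold`` rule.
    """
    if not reps:
        raise ValueError("no repertoires to pool")
    keys = {(r.meta.subset, r.meta.genotype) for r in reps}
    if len(keys) > 1:
        raise ValueError(f"pooled repertoires span multiple groups: {sorted(keys)}")
    (subset, genotype), = keys

    rows = [
        {
            "junction_aa": rec.junction_aa,
            "abundance": rec.abundance,
            "v_call": rec.v_call,
            "j_call": rec.j_call,
            "sample_id": rec.sample_id,
        }
        for rep in reps
        for rec in rep.chain_class(chain)
    ]
    if not rows:
        raise ValueError(f"pooled {chain}-chain repertoire for {subset}/{genotype} is empty")
    df = pd.DataFrame(rows)

    abundance = df.groupby("junction_aa")["abundance"].sum()
    samples = df.groupby("junction_aa")["sample_id"].agg(lambda s: ",".join(sorted(set(s))))
    n_samples = df.groupby("junction_aa")["sample_id"].nunique()
    v_rep = _modal_call(df, "v_call")
    j_rep = _modal_call(df, "j_call")

    entries = pd.DataFrame(
        {
            "abundance": abundance,
            "frequency": abundance / abundance.sum(),
            "v_call": v_rep,
            "j_call": j_rep,
            "n_samples": n_samples,
            "samples": samples,
        }
    ).sort_values(["abundance", "junction_aa"], ascending=[False, True], kind="mergesort")
    entries["replicated"] = entries["frequency"] > threshold
    return CloneTable(subset=subset, genotype=genotype, chain=chain,
                      threshold=threshold, entries=entries)


def _modal_call(df: pd.DataFrame, col: str) -> pd.Series:
    """Highest-abundance call per clone; lexicographic tie-break."""
    agg = df.groupby(["junction_aa", col])["abundance"].sum().reset_index()
    agg = agg.sort_values(["junction_aa", "abundance", col],
                          ascending=[True, False, True], kind="mergesort")
    return agg.drop_duplicates("junction_aa").set_index("junction_aa")[col]


def replicated_summary(ct: CloneTable) -> ReplicatedSummary:
    """Replicated/non-replicated unique counts and replicated coverage."""
    rep = ct.replicated
    return ReplicatedSummary(
        replicated_unique=int(len(rep)),
        non_replicated_unique=int(len(ct) - len(rep)),
        replicated_coverage=float(rep["frequency"].sum()),
    )


def unique_counts_per_sample(reps: Iterable[Repertoire], chain: str = "heavy") -> dict[str, int]:
    """Unique junction_aa count per sample, no pooling.

    The WT and KO count vectors are the inputs of the unique-CDR3 rank-sum
    comparison.
    """
    return {
        rep.meta.sample_id: len({rec.junction_aa for rec in rep.chain_class(chain)})
        for rep in reps
    }


def build_contingency(wt: CloneTable, ko: CloneTable, mode: str = "unique") -> ContingencyTable:
    """Assemble the replicated-vs-genotype 2x2 table for a chi-squared test."""
    if mode not in ("unique", "total"):
        raise ValueError(f"mode must be 'unique' or 'total', got {mode!r}")
    if (wt.subset, wt.chain, wt.threshold) != (ko.subset, ko.chain, ko.threshold):
        raise ValueError(
            "clone tables disagree on subset/chain/threshold: "
            f"{(wt.subset, wt.chain, wt.threshold)} vs {(ko.subset, ko.chain, ko.threshold)}"
        )
    if wt.genotype != "WT" or ko.genotype != "KO":
        raise ValueError("build_contingency expects (WT table, KO table) in that order")

    def cells(ct: CloneTable) -> tuple[int, int]:
        if mode == "unique":
            return len(ct.replicated), len(ct.non_replicated)
        return int(ct.replicated["abundance"].sum()), int(ct.non_replicated["abundance"].sum())

    wt_rep, wt_non = cells(wt)
    ko_rep, ko_non = cells(ko)
    table = np.array([[wt_rep, ko_rep], [wt_non, ko_non]], dtype=int)
    return ContingencyTable(subset=wt.subset, chain=wt.chain, mode=mode, table=table)
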