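"""Shared-CDR3 analysis across groups and tracking of top clones.

A sequence is *shared* between groups when it is expressed at least once in
each group being compared — presence only, abundance ignored.  Top-clone
tracking follows a reference group's most abundant CDR3s into other groups
and reports their frequency there (0 when absent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .clonality import CloneTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapReport:
    """Region counts of a multi-set CDR3 overlap (the Venn numbers)."""

    labels: tuple[str, ...]
    shared: int
    set_sizes: dict[str, int]
    nonshared: dict[str, int]
    flagged_empty: tuple[str, ...] = ()

    @property
    def nonshared_pct(self) -> dict[str, float]:
        return {
            label: (100.0 * self.nonshared[label] / self.set_sizes[label]
                    if self.set_sizes[label] else 0.0)
            for label in self.labels
        }

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "shared": self.shared,
            "set_sizes": dict(self.set_sizes),
            "nonshared": dict(self.nonshared),
            "nonshared_pct": {k: round(v, 1) for k, v in self.nonshared_pct.items()},
            "nonshared_pct_full": self.nonshared_pct,
            "flagged_empty": list(self.flagged_empty),
        }


def shared_sequences(sets: Mapping[str, set[str]]) -> OverlapReport:
    """Intersection-based overlap of two or more labeled CDR3 sets.

    ``shared`` counts sequences present in every set; per set, ``shared +
    nonshared`` equals that set's unique count.  Empty input sets are
    flagged (shared is then necessarily 0).
    """
    if len(sets) < 2:
        raise ValueError("overlap needs at least two sets")
    labels = tuple(sets)
    empty = tuple(label for label, s in sets.items() if not s)
    if empty:
        log.warning("overlap: empty input sets %s", empty)
    common = set.intersection(*(set(s) for s in sets.values()))
    return OverlapReport(
        labels=labels,
        shared=len(common),
        set_sizes={label: len(s) for label, s in sets.items()},
        nonshared={label: len(set(s) - common) for label, s in sets.items()},
        flagged_empty=empty,
    )


def overlap_from_clone_tables(tables: Sequence[CloneTable],
                              replicated_only: bool = False) -> OverlapReport:
    """Overlap of clone tables, labeled ``subset/genotype``.

    By default all clones count (a shared sequence is one expressed at least
    once in each group); ``replicated_only`` restricts to replicated clones.
    """
    sets = {
        f"{ct.subset}/{ct.genotype}": (
            set(ct.replicated.index) if replicated_only else ct.junctions()
        )
        for ct in tables
    }
    return shared_sequences(sets)


def top_clone_tracking(
    reference: CloneTable, targets: Sequence[CloneTable], k: int = 1
) -> pd.DataFrame:
    """Frequencies of the reference group's top-k clones in every group.

    Rows are the reference's k most abundant CDR3s (ties at rank k broken
    lexicographically); columns are the reference and each target group,
    holding that group's frequency for the clone (0 when absent).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(reference):
        log.warning("top_clone_tracking: k=%d exceeds the %d reference clones; truncating",
                    k, len(reference))
        k = len(reference)
    ranked = reference.entries.sort_values(
        ["abundance", "junction_aa"], ascending=[False, True], kind="mergesort"
    )
    top = ranked.index[:k]

    columns = {f"{reference.subset}/{reference.genotype}": reference}
    for target in targets:
        columns[f"{target.subset}/{target.genotype}"] = target
    out = pd.DataFrame(index=pd.Index(top, name="junction_aa"))
    out["rank"] = range(1, len(top) + 1)
    for label, table in columns.items():
        freq = table.entries["frequency"]
        out[label] = [float(freq.get(j, 0.0)) for j in top]
    return out
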