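"""Core data model: rearrangement records, sample metadata, and repertoires.

A :class:`Rearrangement` is one reconstructed receptor chain (one clonotype row
of a TRUST4 report or one row of an AIRR rearrangement table).  A
:class:`Repertoire` is all rearrangements of one sorted-cell sample together
with its :class:`SampleMeta` (genotype and B-cell subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

LOCI = ("IGH", "IGK", "IGL")
GENOTYPES = ("WT", "KO")
SUBSETS = ("B-1a", "B-1b")

#: chain classes used throughout the analysis: heavy = IGH, light = IGK + IGL
CHAIN_CLASSES = {"heavy": ("IGH",), "light": ("IGK", "IGL")}


@dataclass(frozen=True)
class Rearrangement:
    """One receptor-chain record keyed by its CDR3 (junction) sequence."""

    sequence_id: str
    locus: str
    v_call: str
    d_call: str
    j_call: str
    c_call: str
    junction: str
    junction_aa: str
    productive: bool
    abundance: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}; expected one of {LOCI}")
        if self.locus != "IGH" and self.d_call:
            raise ValueError(f"light-chain record {self.sequence_id!r} carries a D call")
        if self.abundance < 1:
            raise ValueError(f"record {self.sequence_id!r} has abundance {self.abundance} < 1")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sorted-cell sample."""

    sample_id: str
    genotype: str
    subset: str
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}, got {self.subset!r}")


@dataclass
class Repertoire:
    """All rearrangements of one sample."""

    meta: SampleMeta
    records: list[Rearrangement] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = [r.sequence_id for r in self.records if r.sample_id != self.meta.sample_id]
        if bad:
            raise ValueError(
                f"records {bad[:3]} carry a sample_id other than {self.meta.sample_id!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Rearrangement]:
        return iter(self.records)

    def subset_by_locus(self, loci: Iterable[str]) -> "Repertoire":
        """Return a new repertoire restricted to the given loci."""
        loci = tuple(loci)
        return Repertoire(self.meta, [r for r in self.records if r.locus in loci])

    def chain_class(self, chain: str) -> "Repertoire":
        """Restrict to a chain class, ``"heavy"`` (IGH) or ``"light"`` (IGK+IGL)."""
        try:
            loci = CHAIN_CLASSES[chain]
        except KeyError:
            raise ValueError(f"chain class must be 'heavy' or 'light', got {chain!r}") from None
        return self.subset_by_locus(loci)

    def total_abundance(self) -> int:
        return sum(r.abundance for r in self.records)


def records_with_sample_id(records: Iterable[Rearrangement], sample_id: str) -> list[Rearrangement]:
    """Re-stamp records with a sample id (used when re-homing parsed rows)."""
    return [r if r.sample_id == sample_id else replace(r, sample_id=sample_id) for r in records]
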