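"""Reading and writing repertoire tables.

Two input dialects are supported:

* AIRR rearrangement TSV — tab-separated with AIRR Standards column names
  (``v_call``, ``j_call``, ``junction``, ``junction_aa``, ...), one row per
  rearrangement.
* TRUST4 report TSV — the ``*_report.tsv`` layout emitted by TRUST4
  (``count, frequency, CDR3nt, CDR3aa, V, D, J, C, ...``), one row per
  clonotype.

Both are normalized into the :class:`~bcrclone.model.Repertoire` data model.
A sample manifest (TSV with ``sample_id, genotype, subset, path``) maps files
to their metadata.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import pandas as pd

from .model import LOCI, Rearrangement, Repertoire, SampleMeta

log = logging.getLogger(__name__)

ISOTYPE_PREFIXES = (
    ("IGHM", "IgM"),
    ("IGHD", "IgD"),
    ("IGHG", "IgG"),
    ("IGHA", "IgA"),
    ("IGHE", "IgE"),
)
ISOTYPES = ("IgM", "IgD", "IgG", "IgA", "IgE")

#: AIRR count-column preference: consensus_count, then duplicate_count, else 1
ABUNDANCE_COLUMNS = ("consensus_count", "duplicate_count")

AIRR_REQUIRED = {"v_call", "j_call", "junction_aa", "junction"}

#: columns written by :func:`write_airr_table`
AIRR_OUTPUT_COLUMNS = (
    "sequence_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "junction",
    "junction_aa",
    "productive",
    "consensus_count",
    "sample_id",
)

STOP_SYMBOL = "*"
TRUST4_PARTIAL_MARKERS = ("_", "?")


class FormatError(ValueError):
    """Input table does not match the expected dialect."""


class EmptyRepertoireError(ValueError):
    """Input table contains no usable rearrangement rows."""


def assign_isotype(c_call: str) -> str | None:
    """Map a heavy-chain constant-gene call to its isotype label.

    Subclasses collapse to the class (``IGHG2B*02`` -> ``IgG``); light-chain
    constants, empty strings and unrecognized names map to ``None``.
    """
    if not c_call:
        return None
    name = c_call.strip().upper()
    for prefix, label in ISOTYPE_PREFIXES:
        if name.startswith(prefix):
            return label
    if not name.startswith(("IGKC", "IGLC")):
        log.debug("unrecognized constant gene %r; no isotype assigned", c_call)
    return None


def infer_locus(v_call: str = "", c_call: str = "", locus: str = "") -> str | None:
    """Infer the locus, preferring an explicit value, then V call, then C call."""
    for candidate in (locus, v_call, c_call):
        prefix = candidate.strip().upper()[:3]
        if prefix in LOCI:
            return prefix
    return None


def _complete_junction(junction_aa: str) -> bool:
    return (
        len(junction_aa) >= 2
        and junction_aa.startswith("C")
        and junction_aa.endswith(("W", "F"))
        and STOP_SYMBOL not in junction_aa
    )


def filter_productive_complete(rep: Repertoire) -> Repertoire:
    """Keep records that are productive with a complete, stop-free CDR3.

    Complete means the junction starts at the conserved cysteine (``C``) and
    ends at the conserved tryptophan/phenylalanine (``W``/``F``).  Diversity
    statistics on translated CDR3s require such translatable junctions.
    """
    kept = [r for r in rep.records if r.productive and _complete_junction(r.junction_aa)]
    dropped = len(rep.records) - len(kept)
    if dropped:
        log.info("%s: dropped %d non-productive/incomplete records", rep.meta.sample_id, dropped)
    return Repertoire(rep.meta, kept)


def _as_int_abundance(value) -> int:
    if pd.isna(value):
        return 1
    try:
        n = int(round(float(value)))
    except (TypeError, ValueError):
        return 1
    return max(n, 1)


def read_airr_table(path: str | Path, meta: SampleMeta, *, productive_only: bool = True) -> Repertoire:
    """Read an AIRR rearrangement TSV into a :class:`Repertoire`.

    Rows without a CDR3 amino-acid value are dropped (and counted in the log).
    Abundance is taken from ``consensus_count``, then ``duplicate_count``,
    else 1.  ``productive_only`` applies :func:`filter_productive_complete`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path} is empty") from None
    missing = AIRR_REQUIRED - set(df.columns)
    if missing:
        raise FormatError(f"{path} lacks required AIRR columns: {sorted(missing)}")
    if df.empty:
        raise EmptyRepertoireError(f"{path} has a header but no rearrangement rows")

    count_col = next((c for c in ABUNDANCE_COLUMNS if c in df.columns), None)
    records: list[Rearrangement] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        junction_aa = _clean(row.get("junction_aa"))
        if not junction_aa:
            dropped += 1
            continue
        locus = infer_locus(
            v_call=_clean(row.get("v_call")),
            c_call=_clean(row.get("c_call")),
            locus=_clean(row.get("locus")),
        )
        if locus is None:
            dropped += 1
            continue
        records.append(
            Rearrangement(
                sequence_id=_clean(row.get("sequence_id")) or f"{meta.sample_id}-{i}",
                locus=locus,
                v_call=_clean(row.get("v_call")),
                d_call=_clean(row.get("d_call")) if locus == "IGH" else "",
                j_call=_clean(row.get("j_call")),
                c_call=_clean(row.get("c_call")),
                junction=_clean(row.get("junction")).upper(),
                junction_aa=junction_aa,
                productive=_parse_bool(row.get("productive"), default=True),
                abundance=_as_int_abundance(row.get(count_col)) if count_col else 1,
                sample_id=meta.sample_id,
            )
        )
    if dropped:
        log.info("%s: dropped %d rows without usable CDR3/locus", meta.sample_id, dropped)
    rep = Repertoire(meta, records)
    return filter_productive_complete(rep) if productive_only else rep


# TRUST4 report column names as emitted by trust-simplerep.pl
_TRUST4_COLUMNS = {"count", "frequency", "CDR3nt", "CDR3aa", "V", "D", "J", "C"}


def read_trust4_report(path: str | Path, meta: SampleMeta, *, productive_only: bool = True) -> Repertoire:
    """Read a TRUST4 ``*_report.tsv`` into a :class:`Repertoire`.

    Locus is inferred from the V (or C) gene-name prefix; allele suffixes are
    preserved verbatim.  Rows whose CDR3aa carries TRUST4's partial markers
    (``_`` or ``?``) or is ``out_of_frame`` are dropped and logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path} is empty") from None
    df.columns = [c.lstrip("#") for c in df.columns]
    if not _TRUST4_COLUMNS <= set(df.columns):
        raise FormatError(
            f"{path} is not a TRUST4 report: missing {sorted(_TRUST4_COLUMNS - set(df.columns))}"
        )
    if df.empty:
        raise EmptyRepertoireError(f"{path} has a header but no clonotype rows")

    records: list[Rearrangement] = []
    dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        cdr3aa = _clean(row.get("CDR3aa"))
        if (
            not cdr3aa
            or cdr3aa == "out_of_frame"
            or any(m in cdr3aa for m in TRUST4_PARTIAL_MARKERS)
        ):
            dropped += 1
            continue
        v_call = _none_to_empty(_clean(row.get("V")))
        c_call = _none_to_empty(_clean(row.get("C")))
        locus = infer_locus(v_call=v_call, c_call=c_call)
        if locus is None:
            dropped += 1
            continue
        records.append(
            Rearrangement(
                sequence_id=f"{meta.sample_id}-{i}",
                locus=locus,
                v_call=v_call,
                d_call=_none_to_empty(_clean(row.get("D"))) if locus == "IGH" else "",
                j_call=_none_to_empty(_clean(row.get("J"))),
                c_call=c_call,
                junction=_clean(row.get("CDR3nt")).upper(),
                junction_aa=cdr3aa,
                productive=cdr3aa != "out_of_frame",
                abundance=_as_int_abundance(row.get("count")),
                sample_id=meta.sample_id,
            )
        )
    if dropped:
        log.info("%s: dropped %d partial/unassignable TRUST4 rows", meta.sample_id, dropped)
    rep = Repertoire(meta, records)
    return filter_productive_complete(rep) if productive_only else rep


def write_airr_table(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as a normalized AIRR rearrangement TSV."""
    rows = [
        {
            "sequence_id": r.sequence_id,
            "locus": r.locus,
            "v_call": r.v_call,
            "d_call": r.d_call,
            "j_call": r.j_call,
            "c_call": r.c_call,
            "junction": r.junction,
            "junction_aa": r.junction_aa,
            "productive": "T" if r.productive else "F",
            "consensus_count": r.abundance,
            "sample_id": r.sample_id,
        }
        for r in rep.records
    ]
    df = pd.DataFrame(rows, columns=list(AIRR_OUTPUT_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest (TSV: sample_id, genotype, subset, path)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "subset", "path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"manifest {path} has duplicate sample_id values: {dupes}")
    return df


def load_study(manifest_path: str | Path, *, productive_only: bool = True) -> list[Repertoire]:
    """Load every sample referenced by a manifest as AIRR tables."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    reps = []
    for row in manifest.itertuples(index=False):
        meta = SampleMeta(
            sample_id=row.sample_id,
            genotype=row.genotype,
            subset=row.subset,
            replicate_index=int(getattr(row, "replicate_index", 0) or 0),
        )
        sample_path = Path(row.path)
        if not sample_path.is_absolute():
            sample_path = manifest_path.parent / sample_path
        reps.append(read_airr_table(sample_path, meta, productive_only=productive_only))
    return reps


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def _none_to_empty(value: str) -> str:
    # TRUST4 writes "*" for unassigned segments
    return "" if value in ("*", ".", "-") else value


def _parse_bool(value, *, default: bool) -> bool:
    text = _clean(value).upper()
    if not text:
        return default
    return text in ("T", "TRUE", "1", "YES", "Y")
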