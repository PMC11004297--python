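"""Synthetic V(D)J repertoire generator with known ground truth.

Generates AIRR-format repertoires that emulate the statistical structure of
sorted B-1 cell BCR sequencing: toy germline segment libraries with skewed
V-family usage, junctional trimming and N-insertion, a two-component clone
size model (diffuse background + expanded block), IgM-dominant isotype
composition, kappa-dominant light chains, and the 4+4 / 4+3 WT-vs-KO sample
design.  Every draw flows from one master seed through
:class:`numpy.random.SeedSequence` spawning, so outputs are reproducible
record for record.

The generator's purpose is verification: the ground truth (clone identities,
true frequencies, expanded flags) is returned alongside the repertoires so
each analysis stage can be checked against what was planted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import write_airr_table
from .model import Rearrangement, Repertoire, SampleMeta

log = logging.getLogger(__name__)

NUCLEOTIDES = np.array(list("ACGT"))

#: isotype label -> constant-gene call written into simulated records
ISOTYPE_TO_C_CALL = {"IgM": "IGHM", "IgD": "IGHD", "IgG": "IGHG1", "IgA": "IGHA", "IgE": "IGHE"}

_RETRY_BUDGET = 500


class SimulationError(RuntimeError):
    """Raised when a configuration cannot produce a valid record."""


# ---------------------------------------------------------------------------
# germline segment library


@dataclass(frozen=True)
class LocusSegments:
    """Toy germline segments for one locus, junction-region parts only.

    ``v`` maps gene names to the junction prefix contributed by the V
    segment, beginning with the conserved cysteine codon (TGT); ``j`` maps
    names to the junction suffix, ending with the conserved anchor codon
    (TGG for IGH, TTC for light chains); ``d`` is empty for light loci.
    Weights are probability vectors aligned with the sorted name order.
    """

    locus: str
    v: dict[str, str]
    d: dict[str, str]
    j: dict[str, str]
    v_weights: np.ndarray
    d_weights: np.ndarray
    j_weights: np.ndarray

    def __post_init__(self) -> None:
        for cls, weights in (("v", self.v_weights), ("d", self.d_weights), ("j", self.j_weights)):
            names = getattr(self, cls)
            if len(names) != len(weights):
                raise ValueError(f"{self.locus} {cls}: weights do not align with segments")
            if len(weights) and (np.any(np.asarray(weights) < 0) or abs(sum(weights) - 1) > 1e-9):
                raise ValueError(f"{self.locus} {cls}: weights must be a probability vector")
        if self.locus != "IGH" and self.d:
            raise ValueError(f"light locus {self.locus} must not carry D segments")


SegmentLibrary = dict[str, LocusSegments]

# gene inventories: (family, gene-number) pairs; families IGHV1/11/12 appear
# so family-level skew analysis is exercised
_V_GENES = {
    "IGH": [(1, 1), (1, 2), (2, 1), (3, 1), (5, 1), (9, 1), (11, 2), (11, 3), (12, 1), (12, 3)],
    "IGK": [(1, 1), (2, 1), (3, 1), (4, 1), (4, 59), (5, 1), (6, 1), (8, 1)],
    "IGL": [(1, 1), (1, 2), (2, 1), (3, 1), (4, 1), (5, 1), (6, 1), (8, 1)],
}
_N_D = {"IGH": 4}
_N_J = 4

# default V-family usage boost: high IGHV1 / IGHV11 / IGHV12 usage, with
# IGHV11 the single most-used family, as seen in peritoneal B-1 repertoires
_IGH_FAMILY_WEIGHTS = {"IGHV1": 0.24, "IGHV11": 0.30, "IGHV12": 0.24}


def _random_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame codons avoiding stop codons."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for _ in range(n_codons):
        codon = "".join(rng.choice(NUCLEOTIDES, 3))
        while codon in stops:
            codon = "".join(rng.choice(NUCLEOTIDES, 3))
        out.append(codon)
    return "".join(out)


def build_germline_library(loci: tuple[str, ...] = ("IGH", "IGK", "IGL"), seed: int = 0) -> SegmentLibrary:
    """Build deterministic toy segment libraries for the requested loci.

    Per locus: >= 8 V genes (with family structure), 4 D genes (IGH only),
    4 J genes.  V parts begin with the cysteine codon and J parts end with
    the anchor codon so productive, anchored junctions are producible.
    """
    lib: SegmentLibrary = {}
    seqs = np.random.SeedSequence(seed).spawn(len(loci))
    for locus, seq in zip(loci, seqs):
        rng = np.random.default_rng(seq)
        v = {
            f"{locus}V{fam}-{num}*01": "TGT" + _random_codons(rng, 3)
            for fam, num in _V_GENES[locus]
        }
        d = (
            {f"{locus}D{i}-1*01": "".join(rng.choice(NUCLEOTIDES, int(rng.integers(9, 16))))
             for i in range(1, _N_D[locus] + 1)}
            if locus == "IGH"
            else {}
        )
        anchor = "TGG" if locus == "IGH" else "TTC"
        j = {
            f"{locus}J{i}*01": _random_codons(rng, 2) + anchor
            for i in range(1, _N_J + 1)
        }
        lib[locus] = LocusSegments(
            locus=locus,
            v=v,
            d=d,
            j=j,
            v_weights=_default_v_weights(locus, sorted(v)),
            d_weights=np.full(len(d), 1 / len(d)) if d else np.array([]),
            j_weights=np.full(len(j), 1 / len(j)),
        )
    return lib


def _default_v_weights(locus: str, names: list[str]) -> np.ndarray:
    if locus != "IGH":
        return np.full(len(names), 1 / len(names))
    from .usage import parse_gene

    families = [parse_gene(n).family for n in names]
    boosted_total = sum(_IGH_FAMILY_WEIGHTS.values())
    other_families = sorted(set(families) - set(_IGH_FAMILY_WEIGHTS))
    per_other = (1 - boosted_total) / len(other_families)
    weights = np.array(
        [
            (_IGH_FAMILY_WEIGHTS.get(fam, per_other)) / families.count(fam)
            for fam in families
        ]
    )
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated clone pool and its sample draws.

    ``expanded_count`` clones share ``expanded_mass`` of the true frequency
    vector equally; the remaining clones share ``1 - expanded_mass`` under
    ``clone_size_law`` ("uniform" — the default two-component model —
    "dirichlet" or "powerlaw" with ``clone_size_param``).  Reads per sample
    are drawn multinomially from the true clone frequencies.
    """

    seed: int = 0
    n_clones: int = 500
    expanded_count: int = 0
    expanded_mass: float = 0.0
    clone_size_law: str = "uniform"
    clone_size_param: float = 1.0
    reads_per_sample: int = 5000
    deletion_mean: float = 2.0
    insertion_mean: float = 4.0
    heavy_fraction: float = 0.6
    isotype_probs: dict[str, float] = field(
        default_factory=lambda: {"IgM": 0.85, "IgD": 0.08, "IgG": 0.04, "IgA": 0.025, "IgE": 0.005}
    )
    kappa_lambda_probs: tuple[float, float] = (0.9, 0.1)
    #: coefficient of variation of per-sample sequencing depth; 0 means every
    #: sample receives exactly reads_per_sample reads
    depth_cv: float = 0.0
    productive_only: bool = True
    sample_design: tuple[SampleMeta, ...] = (
        SampleMeta("sim-1", "WT", "B-1a", 1),
        SampleMeta("sim-2", "WT", "B-1a", 2),
        SampleMeta("sim-3", "WT", "B-1a", 3),
        SampleMeta("sim-4", "WT", "B-1a", 4),
    )

    def __post_init__(self) -> None:
        if not 0 <= self.expanded_count <= self.n_clones:
            raise ValueError("expanded_count must lie in [0, n_clones]")
        if not 0 <= self.expanded_mass < 1:
            raise ValueError("expanded_mass must lie in [0, 1)")
        if self.expanded_count == 0 and self.expanded_mass > 0:
            raise ValueError("expanded_mass > 0 requires expanded_count > 0")
        if abs(sum(self.isotype_probs.values()) - 1) > 1e-9:
            raise ValueError("isotype_probs must sum to 1")
        if abs(sum(self.kappa_lambda_probs) - 1) > 1e-9:
            raise ValueError("kappa_lambda_probs must sum to 1")
        if not 0 <= self.heavy_fraction <= 1:
            raise ValueError("heavy_fraction must lie in [0, 1]")
        if self.clone_size_law not in ("uniform", "dirichlet", "powerlaw"):
            raise ValueError(f"unknown clone_size_law {self.clone_size_law!r}")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be non-negative")


@dataclass(frozen=True)
class Clone:
    """One planted clone: identity plus true pooled frequency."""

    clone_id: str
    locus: str
    v_call: str
    d_call: str
    j_call: str
    c_call: str
    isotype: str
    junction: str
    junction_aa: str
    true_freq: float
    expanded: bool


@dataclass
class GroundTruth:
    """The planted clones of one simulated pool."""

    clones: list[Clone]

    def __post_init__(self) -> None:
        total = sum(c.true_freq for c in self.clones)
        if self.clones and abs(total - 1) > 1e-9:
            raise ValueError(f"true clone frequencies sum to {total}, not 1")

    @property
    def expanded_junctions(self) -> set[str]:
        return {c.junction_aa for c in self.clones if c.expanded}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clone_id": c.clone_id,
                    "junction_aa": c.junction_aa,
                    "locus": c.locus,
                    "v_call": c.v_call,
                    "d_call": c.d_call,
                    "j_call": c.j_call,
                    "isotype": c.isotype,
                    "true_freq": c.true_freq,
                    "expanded": c.expanded,
                }
                for c in self.clones
            ]
        )


# ---------------------------------------------------------------------------
# junction simulation


def _geometric_0(rng: np.random.Generator, mean: float) -> int:
    """Geometric on {0, 1, ...} with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (1.0 + mean)) - 1)


def simulate_rearrangement(
    lib: SegmentLibrary,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    *,
    locus: str | None = None,
) -> Rearrangement:
    """Simulate one rearrangement: segment choice, trimming, N-insertion.

    Segments are drawn from the library usage weights; junction-edge
    deletions are geometric with mean ``cfg.deletion_mean`` (capped so the
    conserved anchors survive); N-insertion lengths are Poisson with mean
    ``cfg.insertion_mean``, bases uniform.  With ``cfg.productive_only`` the
    draw is repeated until the junction is in-frame, stop-free and anchored;
    a bounded retry budget guards against inconsistent configurations.
    """
    if locus is None:
        locus = _draw_locus(cfg, rng)
    seg = lib[locus]
    v_names, j_names = sorted(seg.v), sorted(seg.j)
    d_names = sorted(seg.d)

    for _ in range(_RETRY_BUDGET):
        v_name = v_names[rng.choice(len(v_names), p=seg.v_weights)]
        j_name = j_names[rng.choice(len(j_names), p=seg.j_weights)]
        v_part = seg.v[v_name]
        j_part = seg.j[j_name]
        # trim, preserving the anchor codons
        v_trim = min(_geometric_0(rng, cfg.deletion_mean), len(v_part) - 3)
        j_trim = min(_geometric_0(rng, cfg.deletion_mean), len(j_part) - 3)
        v_piece = v_part[: len(v_part) - v_trim]
        j_piece = j_part[j_trim:]
        if locus == "IGH":
            d_name = d_names[rng.choice(len(d_names), p=seg.d_weights)]
            d_part = seg.d[d_name]
            d_trim5 = min(_geometric_0(rng, cfg.deletion_mean), len(d_part))
            d_trim3 = min(_geometric_0(rng, cfg.deletion_mean), len(d_part) - d_trim5)
            d_piece = d_part[d_trim5 : len(d_part) - d_trim3]
            n1 = _n_insert(rng, cfg.insertion_mean)
            n2 = _n_insert(rng, cfg.insertion_mean)
            junction = v_piece + n1 + d_piece + n2 + j_piece
        else:
            d_name = ""
            n1 = _n_insert(rng, cfg.insertion_mean)
            junction = v_piece + n1 + j_piece

        in_frame = len(junction) % 3 == 0
        junction_aa = str(Seq(junction).translate()) if in_frame else ""
        productive = (
            in_frame
            and junction_aa.startswith("C")
            and junction_aa.endswith(("W", "F"))
            and "*" not in junction_aa
        )
        if productive or not cfg.productive_only:
            if locus == "IGH":
                isotypes = sorted(cfg.isotype_probs)
                probs = np.array([cfg.isotype_probs[i] for i in isotypes])
                isotype = isotypes[rng.choice(len(isotypes), p=probs)]
                c_call = ISOTYPE_TO_C_CALL[isotype]
            else:
                c_call = locus + "C"
            return Rearrangement(
                sequence_id="sim",
                locus=locus,
                v_call=v_name,
                d_call=d_name,
                j_call=j_name,
                c_call=c_call,
                junction=junction,
                junction_aa=junction_aa,
                productive=productive,
                abundance=1,
                sample_id="sim",
            )
    raise SimulationError(
        f"no productive junction after {_RETRY_BUDGET} draws for locus {locus}; "
        "check deletion/insertion settings"
    )


def _n_insert(rng: np.random.Generator, mean: float) -> str:
    n = int(rng.poisson(mean)) if mean > 0 else 0
    return "".join(rng.choice(NUCLEOTIDES, n)) if n else ""


def _draw_locus(cfg: SimulationConfig, rng: np.random.Generator) -> str:
    if rng.random() < cfg.heavy_fraction:
        return "IGH"
    return "IGK" if rng.random() < cfg.kappa_lambda_probs[0] else "IGL"


# ---------------------------------------------------------------------------
# clone pools and repertoires


def _clone_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """True frequency vector: equal expanded block + background law."""
    n_bg = cfg.n_clones - cfg.expanded_count
    freqs = np.empty(cfg.n_clones)
    freqs[: cfg.expanded_count] = (
        cfg.expanded_mass / cfg.expanded_count if cfg.expanded_count else 0.0
    )
    bg_mass = 1.0 - cfg.expanded_mass
    if n_bg:
        if cfg.clone_size_law == "uniform":
            bg = np.full(n_bg, 1.0 / n_bg)
        elif cfg.clone_size_law == "dirichlet":
            bg = rng.dirichlet(np.full(n_bg, cfg.clone_size_param))
        else:  # powerlaw: frequency ~ rank^-param
            bg = np.arange(1, n_bg + 1, dtype=float) ** -cfg.clone_size_param
            bg /= bg.sum()
        freqs[cfg.expanded_count :] = bg_mass * bg
    return freqs


def _generate_clones(
    cfg: SimulationConfig,
    lib: SegmentLibrary,
    rng: np.random.Generator,
    preset_expanded: list[Clone] | None = None,
) -> list[Clone]:
    """Generate ``n_clones`` clones with distinct CDR3 aa identities.

    Expanded clones are placed on the heavy chain (the clonality analyses'
    headline chain class) whenever heavy chains are simulated.  A
    ``preset_expanded`` list reuses existing clone identities as this pool's
    first expanded clones — used to plant clones shared between groups.
    """
    freqs = _clone_frequencies(cfg, rng)
    preset = list(preset_expanded or [])[: cfg.expanded_count]
    clones: list[Clone] = []
    seen: set[str] = {c.junction_aa for c in preset}
    expanded_locus = "IGH" if cfg.heavy_fraction > 0 else None

    for i in range(cfg.n_clones):
        expanded = i < cfg.expanded_count
        if expanded and i < len(preset):
            src = preset[i]
            clones.append(replace(src, clone_id=f"clone-{i:05d}", true_freq=freqs[i], expanded=True))
            continue
        locus = expanded_locus if (expanded and expanded_locus) else None
        for _ in range(_RETRY_BUDGET):
            rec = simulate_rearrangement(lib, cfg, rng, locus=locus)
            if rec.junction_aa not in seen:
                break
        else:
            raise SimulationError(
                "could not generate a distinct CDR3; junction diversity too low for n_clones"
            )
        seen.add(rec.junction_aa)
        clones.append(
            Clone(
                clone_id=f"clone-{i:05d}",
                locus=rec.locus,
                v_call=rec.v_call,
                d_call=rec.d_call,
                j_call=rec.j_call,
                c_call=rec.c_call,
                isotype={"IGK": "", "IGL": ""}.get(rec.locus, _isotype_of(rec.c_call)),
                junction=rec.junction,
                junction_aa=rec.junction_aa,
                true_freq=freqs[i],
                expanded=expanded,
            )
        )
    return clones


def _isotype_of(c_call: str) -> str:
    from .io import assign_isotype

    return assign_isotype(c_call) or ""


def simulate_repertoire(
    cfg: SimulationConfig,
    *,
    lib: SegmentLibrary | None = None,
    preset_expanded: list[Clone] | None = None,
) -> tuple[list[Repertoire], GroundTruth]:
    """Simulate one clone pool and draw every sample in ``cfg.sample_design``.

    Per sample, ``reads_per_sample`` reads are drawn multinomially from the
    true clone frequencies; clones observed at least once become records
    whose abundance is the read count.  Returns the repertoires and the
    planted ground truth.
    """
    master = np.random.SeedSequence(cfg.seed)
    pool_seq, *sample_seqs = master.spawn(1 + len(cfg.sample_design))
    rng = np.random.default_rng(pool_seq)
    if lib is None:
        loci: tuple[str, ...] = ("IGH", "IGK", "IGL") if cfg.heavy_fraction < 1 else ("IGH",)
        lib = build_germline_library(loci, seed=cfg.seed)
    clones = _generate_clones(cfg, lib, rng, preset_expanded)
    freqs = np.array([c.true_freq for c in clones])

    repertoires = []
    for meta, seq in zip(cfg.sample_design, sample_seqs):
        sample_rng = np.random.default_rng(seq)
        depth = cfg.reads_per_sample
        if cfg.depth_cv > 0:
            # gamma-distributed library depth, mean reads_per_sample
            shape = 1.0 / cfg.depth_cv**2
            depth = max(1, int(round(sample_rng.gamma(shape, cfg.reads_per_sample / shape))))
        counts = sample_rng.multinomial(depth, freqs)
        records = [
            Rearrangement(
                sequence_id=f"{meta.sample_id}-{clone.clone_id}",
                locus=clone.locus,
                v_call=clone.v_call,
                d_call=clone.d_call,
                j_call=clone.j_call,
                c_call=clone.c_call,
                junction=clone.junction,
                junction_aa=clone.junction_aa,
                productive=True,
                abundance=int(k),
                sample_id=meta.sample_id,
            )
            for clone, k in zip(clones, counts)
            if k > 0
        ]
        repertoires.append(Repertoire(meta, records))
    return repertoires, GroundTruth(clones)


# ---------------------------------------------------------------------------
# full-study emulation


@dataclass(frozen=True)
class GroupEffect:
    """Clone-pool parameters of one (subset, genotype) group."""

    n_clones: int
    expanded_count: int
    expanded_mass: float

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be at least 1")
        if not 0 <= self.expanded_count <= self.n_clones:
            raise ValueError("expanded_count must lie in [0, n_clones]")
        if not 0 <= self.expanded_mass < 1:
            raise ValueError("expanded_mass must lie in [0, 1)")


@dataclass(frozen=True)
class StudyConfig:
    """The emulated study: 4+4 B-1a and 4+3 B-1b samples, WT vs KO.

    KO groups default to fewer clones and a larger expanded mass than WT, so
    the analysis pipeline reproduces the qualitative pattern of reduced
    unique-CDR3 diversity with increased clonal expansion in KO.
    ``shared_ko_expanded`` expanded clones are planted in both KO pools, so
    KO B-1a and KO B-1b share repertoire the WT pools do not.

    ``depth_cv`` spreads per-sample library depth (gamma, mean
    ``reads_per_sample``), as real libraries never sequence to identical
    depth.  ``pool_per`` controls what shares a clone pool: ``"group"``
    (default) gives each (subset, genotype) its own pool; ``"subset"`` makes
    WT and KO of a subset draw from one common pool, which is the correct
    null model when both genotypes have identical generative parameters —
    samples are then exchangeable across genotype.
    """

    seed: int = 0
    reads_per_sample: int = 2000
    groups: dict[tuple[str, str], GroupEffect] = field(
        default_factory=lambda: {
            ("B-1a", "WT"): GroupEffect(n_clones=900, expanded_count=3, expanded_mass=0.08),
            ("B-1a", "KO"): GroupEffect(n_clones=300, expanded_count=8, expanded_mass=0.55),
            ("B-1b", "WT"): GroupEffect(n_clones=900, expanded_count=3, expanded_mass=0.08),
            ("B-1b", "KO"): GroupEffect(n_clones=450, expanded_count=8, expanded_mass=0.30),
        }
    )
    replicates: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("B-1a", "WT"): 4,
            ("B-1a", "KO"): 4,
            ("B-1b", "WT"): 4,
            ("B-1b", "KO"): 3,
        }
    )
    shared_ko_expanded: int = 3
    heavy_fraction: float = 0.6
    isotype_probs: dict[str, float] = field(
        default_factory=lambda: {"IgM": 0.85, "IgD": 0.08, "IgG": 0.04, "IgA": 0.025, "IgE": 0.005}
    )
    kappa_lambda_probs: tuple[float, float] = (0.9, 0.1)
    deletion_mean: float = 2.0
    insertion_mean: float = 4.0
    depth_cv: float = 0.2
    pool_per: str = "group"  # "group" | "subset"

    def __post_init__(self) -> None:
        if self.pool_per not in ("group", "subset"):
            raise ValueError(f"pool_per must be 'group' or 'subset', got {self.pool_per!r}")
        if self.pool_per == "subset":
            for subset in {s for s, _ in self.groups}:
                effects = {self.groups[(s, g)] for s, g in self.groups if s == subset}
                if len(effects) > 1:
                    raise ValueError(
                        "pool_per='subset' requires identical WT/KO effects "
                        f"within subset {subset!r}"
                    )


def zero_effect_config(seed: int = 0, **overrides) -> StudyConfig:
    """A null study: WT and KO of each subset draw from one common pool."""
    shared = GroupEffect(n_clones=600, expanded_count=3, expanded_mass=0.10)
    settings: dict = {
        "groups": {key: shared for key in
                   [("B-1a", "WT"), ("B-1a", "KO"), ("B-1b", "WT"), ("B-1b", "KO")]},
        "shared_ko_expanded": 0,
        "pool_per": "subset",
    }
    settings.update(overrides)
    return StudyConfig(seed=seed, **settings)


def _sample_design(cfg: StudyConfig, keys: list[tuple[str, str]]) -> tuple[SampleMeta, ...]:
    return tuple(
        SampleMeta(f"{subset}-{genotype}-{i + 1}", genotype, subset, i + 1)
        for subset, genotype in keys
        for i in range(cfg.replicates[(subset, genotype)])
    )


def simulate_study(cfg: StudyConfig) -> tuple[list[Repertoire], dict[tuple[str, str], GroundTruth]]:
    """Simulate every group of the study design, in memory.

    One clone pool per (subset, genotype) group — or per subset under
    ``pool_per="subset"`` — with each sample drawn from its pool.  Pool
    seeds derive from the master seed.
    """
    if cfg.pool_per == "subset":
        pools = [
            [(subset, genotype) for (subset, genotype) in sorted(cfg.groups) if subset == s]
            for s in sorted({s for s, _ in cfg.groups})
        ]
    else:
        pools = [[key] for key in sorted(cfg.groups)]
    seqs = np.random.SeedSequence(cfg.seed).spawn(len(pools))
    pool_seeds = [int(seq.generate_state(1)[0] >> 1) for seq in seqs]

    lib = build_germline_library(("IGH", "IGK", "IGL"), seed=cfg.seed)
    repertoires: list[Repertoire] = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    ko_shared: list[Clone] = []

    # generate KO-containing pools first so shared expanded clones can be
    # planted across them (no-op when shared_ko_expanded is 0)
    order = sorted(range(len(pools)), key=lambda i: (all(g != "KO" for _, g in pools[i]), pools[i]))
    results: dict[int, tuple[list[Repertoire], GroundTruth]] = {}
    for i in order:
        keys = pools[i]
        effect = cfg.groups[keys[0]]
        sim_cfg = SimulationConfig(
            seed=pool_seeds[i],
            n_clones=effect.n_clones,
            expanded_count=effect.expanded_count,
            expanded_mass=effect.expanded_mass,
            reads_per_sample=cfg.reads_per_sample,
            deletion_mean=cfg.deletion_mean,
            insertion_mean=cfg.insertion_mean,
            heavy_fraction=cfg.heavy_fraction,
            isotype_probs=cfg.isotype_probs,
            kappa_lambda_probs=cfg.kappa_lambda_probs,
            depth_cv=cfg.depth_cv,
            sample_design=_sample_design(cfg, keys),
        )
        is_ko_pool = cfg.pool_per == "group" and keys[0][1] == "KO"
        preset = ko_shared[: cfg.shared_ko_expanded] if is_ko_pool else None
        reps, truth = simulate_repertoire(sim_cfg, lib=lib, preset_expanded=preset)
        if is_ko_pool and not ko_shared:
            ko_shared = [c for c in truth.clones if c.expanded]
        results[i] = (reps, truth)
        for key in keys:
            truths[key] = truth
    for i in sorted(results):
        repertoires.extend(results[i][0])
    repertoires.sort(key=lambda r: (r.meta.subset, r.meta.genotype, r.meta.replicate_index))
    return repertoires, truths


def emulate_study(cfg: StudyConfig, out_dir: str | Path) -> Path:
    """Write the emulated study to disk: AIRR TSVs, manifest, ground truth.

    Returns the manifest path.  Output is byte-identical for a fixed
    ``cfg.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    repertoires, truths = simulate_study(cfg)

    manifest_rows = []
    for rep in repertoires:
        fname = f"{rep.meta.sample_id}.airr.tsv"
        write_airr_table(rep, out_dir / fname)
        manifest_rows.append(
            {
                "sample_id": rep.meta.sample_id,
                "genotype": rep.meta.genotype,
                "subset": rep.meta.subset,
                "replicate_index": rep.meta.replicate_index,
                "path": fname,
            }
        )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False, lineterminator="\n")

    truth_frames = []
    for (subset, genotype), truth in sorted(truths.items()):
        frame = truth.to_frame()
        frame.insert(0, "genotype", genotype)
        frame.insert(0, "subset", subset)
        truth_frames.append(frame)
    pd.concat(truth_frames, ignore_index=True).to_csv(
        out_dir / "ground_truth.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.10g"
    )

    with open(out_dir / "study_config.yaml", "w") as fh:
        fh.write(_config_yaml(cfg))
    return manifest_path


def _config_yaml(cfg: StudyConfig) -> str:
    import yaml

    payload = {
        "seed": cfg.seed,
        "reads_per_sample": cfg.reads_per_sample,
        "heavy_fraction": cfg.heavy_fraction,
        "kappa_lambda_probs": list(cfg.kappa_lambda_probs),
        "isotype_probs": dict(cfg.isotype_probs),
        "deletion_mean": cfg.deletion_mean,
        "insertion_mean": cfg.insertion_mean,
        "shared_ko_expanded": cfg.shared_ko_expanded,
        "groups": {
            f"{subset}/{genotype}": {
                "n_clones": eff.n_clones,
                "expanded_count": eff.expanded_count,
                "expanded_mass": eff.expanded_mass,
                "replicates": cfg.replicates[(subset, genotype)],
            }
            for (subset, genotype), eff in sorted(cfg.groups.items())
        },
    }
    return yaml.safe_dump(payload, sort_keys=True)
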