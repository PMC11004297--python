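"""Generator contracts: determinism, junction model, clone-size model."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from bcrclone.model import SampleMeta
from bcrclone.simulate import (
    SimulationConfig,
    StudyConfig,
    build_germline_library,
    emulate_study,
    simulate_rearrangement,
    simulate_repertoire,
    simulate_study,
)
from bcrclone.usage import parse_gene

DESIGN4 = tuple(SampleMeta(f"s{i}", "WT", "B-1a", i) for i in range(1, 5))


class TestGermlineLibrary:
    def test_deterministic_given_seed(self):
        a, b = build_germline_library(seed=1), build_germline_library(seed=1)
        assert a.keys() == b.keys()
        for locus in a:
            assert (a[locus].v, a[locus].d, a[locus].j) == (b[locus].v, b[locus].d, b[locus].j)
            assert np.array_equal(a[locus].v_weights, b[locus].v_weights)
            assert np.array_equal(a[locus].j_weights, b[locus].j_weights)

    def test_light_loci_carry_no_d_segments(self):
        lib = build_germline_library(("IGK", "IGL"), seed=0)
        assert lib["IGK"].d == {} and lib["IGL"].d == {}

    def test_inventory_sizes(self):
        lib = build_germline_library(seed=0)
        assert len(lib["IGH"].v) >= 8
        assert len(lib["IGH"].d) >= 4
        assert len(lib["IGH"].j) >= 4

    def test_anchor_codons_present(self):
        lib = build_germline_library(seed=3)
        for locus, seg in lib.items():
            assert all(v.startswith("TGT") for v in seg.v.values())
            anchor = "TGG" if locus == "IGH" else "TTC"
            assert all(j.endswith(anchor) for j in seg.j.values())

    def test_ighv11_family_is_top_weighted(self):
        seg = build_germline_library(seed=0)["IGH"]
        by_family: dict[str, float] = {}
        for name, w in zip(sorted(seg.v), seg.v_weights):
            fam = parse_gene(name).family
            by_family[fam] = by_family.get(fam, 0.0) + w
        top = max(by_family, key=by_family.get)
        assert top == "IGHV11"
        assert all(by_family["IGHV11"] > w for f, w in by_family.items() if f != "IGHV11")


class TestSimulateRearrangement:
    def test_zero_noise_is_exact_germline_concatenation(self):
        lib = build_germline_library(seed=2)
        cfg = SimulationConfig(deletion_mean=0.0, insertion_mean=0.0, heavy_fraction=1.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            rec = simulate_rearrangement(lib, cfg, rng, locus="IGH")
            seg = lib["IGH"]
            assert rec.junction == seg.v[rec.v_call] + seg.d[rec.d_call] + seg.j[rec.j_call]

    def test_productive_only_contract(self):
        lib = build_germline_library(seed=2)
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        for _ in range(100):
            rec = simulate_rearrangement(lib, cfg, rng)
            assert rec.productive
            assert len(rec.junction) % 3 == 0
            assert rec.junction_aa.startswith("C")
            assert rec.junction_aa.endswith(("W", "F"))
            assert "*" not in rec.junction_aa

    def test_fixed_seed_reproduces_record(self):
        lib = build_germline_library(seed=2)
        cfg = SimulationConfig()
        a = simulate_rearrangement(lib, cfg, np.random.default_rng(5))
        b = simulate_rearrangement(lib, cfg, np.random.default_rng(5))
        assert a == b


class TestSimulateRepertoire:
    def test_read_conservation_and_frequency_sum(self):
        cfg = SimulationConfig(seed=3, n_clones=100, reads_per_sample=4000,
                               sample_design=DESIGN4)
        reps, truth = simulate_repertoire(cfg)
        assert sum(r.total_abundance() for r in reps) == 4000 * len(DESIGN4)
        assert sum(c.true_freq for c in truth.clones) == pytest.approx(1.0, abs=1e-12)

    def test_expanded_block_frequency_floor(self):
        cfg = SimulationConfig(seed=3, n_clones=50, expanded_count=5, expanded_mass=0.6,
                               sample_design=DESIGN4)
        _, truth = simulate_repertoire(cfg)
        expanded = [c for c in truth.clones if c.expanded]
        assert len(expanded) == 5
        assert all(c.true_freq >= 0.12 - 1e-12 for c in expanded)
        # flagged clones are exactly the largest
        floor = min(c.true_freq for c in expanded)
        assert all(c.true_freq <= floor + 1e-12 for c in truth.clones if not c.expanded)

    def test_clone_identities_are_unique(self):
        cfg = SimulationConfig(seed=9, n_clones=300, sample_design=DESIGN4)
        _, truth = simulate_repertoire(cfg)
        junctions = [c.junction_aa for c in truth.clones]
        assert len(set(junctions)) == len(junctions)

    def test_diffuse_pool_yields_no_percent_level_clones(self):
        # 500 equal clones at 10,000 reads/sample: pooled frequencies
        # concentrate far below the 1% mark in every seed
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_clones=500, reads_per_sample=10_000,
                                   heavy_fraction=1.0, sample_design=DESIGN4)
            reps, _ = simulate_repertoire(cfg)
            pooled: dict[str, int] = {}
            for rep in reps:
                for rec in rep:
                    pooled[rec.junction_aa] = pooled.get(rec.junction_aa, 0) + rec.abundance
            total = sum(pooled.values())
            assert max(pooled.values()) / total < 0.01

    def test_realized_frequencies_converge_to_truth(self):
        # L1 distance between realized pooled frequencies and planted truth
        # shrinks as depth grows (averaged over seeds)
        depths = (500, 5_000, 50_000)
        mean_l1 = []
        for reads in depths:
            dists = []
            for seed in range(3):
                cfg = SimulationConfig(seed=seed, n_clones=100, reads_per_sample=reads,
                                       heavy_fraction=1.0,
                                       sample_design=DESIGN4[:2])
                reps, truth = simulate_repertoire(cfg)
                pooled = {c.junction_aa: 0 for c in truth.clones}
                for rep in reps:
                    for rec in rep:
                        pooled[rec.junction_aa] += rec.abundance
                total = sum(pooled.values())
                dists.append(
                    sum(abs(pooled[c.junction_aa] / total - c.true_freq)
                        for c in truth.clones)
                )
            mean_l1.append(float(np.mean(dists)))
        assert mean_l1[0] > mean_l1[1] > mean_l1[2]

    def test_family_usage_matches_configured_weights(self):
        # goodness of fit of simulated V-family draws against the library
        # weights; >= 5000 records
        lib = build_germline_library(seed=0)
        cfg = SimulationConfig(seed=0, heavy_fraction=1.0)
        rng = np.random.default_rng(11)
        counts: dict[str, int] = {}
        n = 5000
        for _ in range(n):
            rec = simulate_rearrangement(lib, cfg, rng, locus="IGH")
            fam = parse_gene(rec.v_call).family
            counts[fam] = counts.get(fam, 0) + 1
        seg = lib["IGH"]
        expected: dict[str, float] = {}
        for name, w in zip(sorted(seg.v), seg.v_weights):
            fam = parse_gene(name).family
            expected[fam] = expected.get(fam, 0.0) + w
        families = sorted(expected)
        observed = np.array([counts.get(f, 0) for f in families])
        probs = np.array([expected[f] for f in families])
        gof = sps.chisquare(observed, n * probs / probs.sum())
        assert gof.pvalue > 0.01


class TestStudyEmulation:
    def test_sample_design_matches_study(self, default_study):
        reps, _ = default_study
        layout = {}
        for rep in reps:
            key = (rep.meta.subset, rep.meta.genotype)
            layout[key] = layout.get(key, 0) + 1
        assert layout == {("B-1a", "WT"): 4, ("B-1a", "KO"): 4,
                          ("B-1b", "WT"): 4, ("B-1b", "KO"): 3}

    def test_ko_unique_counts_fall_below_wt(self, default_study):
        from bcrclone.clonality import unique_counts_per_sample

        reps, _ = default_study
        for subset in ("B-1a", "B-1b"):
            group = [r for r in reps if r.meta.subset == subset]
            counts = unique_counts_per_sample(group, "heavy")
            wt = [counts[r.meta.sample_id] for r in group if r.meta.genotype == "WT"]
            ko = [counts[r.meta.sample_id] for r in group if r.meta.genotype == "KO"]
            assert max(ko) < min(wt)

    def test_fixed_seed_writes_byte_identical_files(self, tmp_path):
        cfg = StudyConfig(
            seed=5,
            reads_per_sample=400,
            groups={("B-1a", "WT"): StudyConfig().groups[("B-1a", "WT")],
                    ("B-1a", "KO"): StudyConfig().groups[("B-1a", "KO")]},
            replicates={("B-1a", "WT"): 2, ("B-1a", "KO"): 2},
        )
        a, b = tmp_path / "a", tmp_path / "b"
        emulate_study(cfg, a)
        emulate_study(cfg, b)
        files_a = sorted(p.name for p in a.iterdir())
        assert files_a == sorted(p.name for p in b.iterdir())
        for name in files_a:
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_zero_effect_pools_are_shared_within_subset(self):
        from bcrclone.simulate import zero_effect_config

        _, truths = simulate_study(zero_effect_config(seed=2))
        assert truths[("B-1a", "WT")] is truths[("B-1a", "KO")]
        assert truths[("B-1b", "WT")] is truths[("B-1b", "KO")]
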