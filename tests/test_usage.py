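"""Gene parsing, usage tables, V-J pairing, isotypes, kappa/lambda."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from bcrclone.clonality import build_clone_table
from bcrclone.model import Rearrangement, Repertoire, SampleMeta
from bcrclone.simulate import SimulationConfig, simulate_repertoire
from bcrclone.usage import (
    isotype_distribution,
    kappa_lambda_ratio,
    parse_gene,
    usage_from_clone_table,
    usage_table,
    vj_pairing,
)

from conftest import make_repertoire


class TestParseGene:
    @pytest.mark.parametrize(
        ("call", "gene", "family"),
        [
            ("IGHV11-2*01", "IGHV11-2", "IGHV11"),
            ("IGHJ4*01", "IGHJ4", "IGHJ4"),
            ("IGKV4-59", "IGKV4-59", "IGKV4"),
            ("IGHD1-1*02", "IGHD1-1", "IGHD1"),
            ("IGLV2-1", "IGLV2-1", "IGLV2"),
        ],
    )
    def test_nomenclature_rule(self, call, gene, family):
        parsed = parse_gene(call)
        assert (parsed.gene, parsed.family) == (gene, family)

    def test_unparseable_name_flagged_unknown(self):
        assert parse_gene("TRBV20*01").family == "unknown"

    def test_idempotent_on_gene_component(self):
        for call in ("IGHV11-2*01", "IGKV4-59", "oddball"):
            gene = parse_gene(call).gene
            assert parse_gene(gene).gene == gene

    def test_empty_call_rejected(self):
        with pytest.raises(ValueError):
            parse_gene("")


def two_family_sample(abundances=(1, 1, 1, 1)) -> Repertoire:
    meta = SampleMeta("s1", "WT", "B-1a", 1)
    vs = ["IGHV1-1*01", "IGHV1-2*01", "IGHV11-2*01", "IGHV11-3*01"]
    records = [
        Rearrangement(f"r{i}", "IGH", v, "IGHD1-1*01", "IGHJ1*01", "IGHM",
                      "TGTTGG", f"CA{i}W", True, a, "s1")
        for i, (v, a) in enumerate(zip(vs, abundances))
    ]
    return Repertoire(meta, records)


class TestUsageTable:
    def test_clonotype_weighting_counts_each_clone_once(self):
        ut = usage_table([two_family_sample()], "family", "V", "clonotype")
        row = ut.frequencies.loc["s1"]
        assert row["IGHV1"] == pytest.approx(0.5)
        assert row["IGHV11"] == pytest.approx(0.5)

    def test_abundance_weighting(self):
        ut = usage_table([two_family_sample((45, 45, 5, 5))], "family", "V", "abundance")
        row = ut.frequencies.loc["s1"]
        assert row["IGHV1"] == pytest.approx(0.9)
        assert row["IGHV11"] == pytest.approx(0.1)

    def test_rows_sum_to_one(self, default_study):
        reps, _ = default_study
        ut = usage_table(reps, "family", "V", "abundance")
        assert np.allclose(ut.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_uniform_abundance_scaling(self):
        base = usage_table([two_family_sample((4, 3, 2, 1))], "gene", "V", "abundance")
        scaled = usage_table([two_family_sample((12, 9, 6, 3))], "gene", "V", "abundance")
        pd.testing.assert_frame_equal(base.frequencies, scaled.frequencies)

    def test_boosted_family_ranks_high_in_simulated_samples(self, default_study):
        reps, _ = default_study
        ut = usage_table(reps, "family", "V", "abundance")
        for _, row in ut.frequencies.iterrows():
            top3 = row.sort_values(ascending=False).index[:3]
            assert "IGHV11" in top3


class TestVJPairing:
    def test_two_clone_matrix(self):
        clones = {"CAAW": 70, "CABW": 30}
        meta = SampleMeta("s1", "WT", "B-1a", 1)
        records = [
            Rearrangement("r1", "IGH", "IGHV11-2*01", "IGHD1-1*01", "IGHJ1*01",
                          "IGHM", "TGTTGG", "CAAW", True, 70, "s1"),
            Rearrangement("r2", "IGH", "IGHV12-1*01", "IGHD1-1*01", "IGHJ4*01",
                          "IGHM", "TGTTGG", "CABW", True, 30, "s1"),
        ]
        ct = build_clone_table([Repertoire(meta, records)], "heavy")
        pm = vj_pairing(ct, "family", "all")
        assert pm.matrix.loc["IGHV11", "IGHJ1"] == pytest.approx(0.7)
        assert pm.matrix.loc["IGHV12", "IGHJ4"] == pytest.approx(0.3)

    def test_marginals_equal_independent_usage(self, default_study):
        reps, _ = default_study
        group = [r for r in reps if r.meta.subset == "B-1a" and r.meta.genotype == "KO"]
        ct = build_clone_table(group, "heavy")
        for scope in ("all", "replicated"):
            pm = vj_pairing(ct, "family", scope)
            v_usage = usage_from_clone_table(ct, "V", "family", scope)
            j_usage = usage_from_clone_table(ct, "J", "family", scope)
            pd.testing.assert_series_equal(pm.v_marginal(), v_usage,
                                           check_names=False, atol=1e-12, rtol=0)
            pd.testing.assert_series_equal(pm.j_marginal(), j_usage,
                                           check_names=False, atol=1e-12, rtol=0)
            assert pm.matrix.to_numpy().sum() == pytest.approx(1.0, abs=1e-12)

    def test_replicated_scope_isolates_planted_pairing(self):
        # one expanded clone family: replicated-scope matrix is a single cell
        meta = SampleMeta("s1", "WT", "B-1a", 1)
        records = [
            Rearrangement("r1", "IGH", "IGHV12-1*01", "IGHD1-1*01", "IGHJ4*01",
                          "IGHM", "TGTTGG", "CEXPW", True, 500, "s1"),
        ] + [
            Rearrangement(f"b{i}", "IGH", "IGHV1-1*01", "IGHD1-1*01", "IGHJ1*01",
                          "IGHM", "TGTTGG", f"CB{i:03d}W", True, 1, "s1")
            for i in range(150)
        ]
        ct = build_clone_table([Repertoire(meta, records)], "heavy")
        pm = vj_pairing(ct, "family", "replicated")
        assert pm.matrix.shape == (1, 1)
        assert pm.matrix.loc["IGHV12", "IGHJ4"] == pytest.approx(1.0)


class TestKappaLambda:
    def light_rep(self, kappa, lam, sample_id="s1", genotype="WT"):
        meta = SampleMeta(sample_id, genotype, "B-1a", 1)
        records = []
        if kappa:
            records.append(Rearrangement(f"{sample_id}-k", "IGK", "IGKV1-1*01", "",
                                         "IGKJ1*01", "IGKC", "TGTTTC", "CQKF", True,
                                         kappa, sample_id))
        if lam:
            records.append(Rearrangement(f"{sample_id}-l", "IGL", "IGLV1-1*01", "",
                                         "IGLJ1*01", "IGLC", "TGTTTC", "CQLF", True,
                                         lam, sample_id))
        return Repertoire(meta, records)

    def test_ratio_computed_per_sample(self):
        table, _ = kappa_lambda_ratio([self.light_rep(75, 25)])
        assert table.loc["s1", "ratio"] == pytest.approx(3.0)
        assert not table.loc["s1", "degenerate"]

    def test_all_kappa_sample_flagged_infinite(self):
        table, _ = kappa_lambda_ratio([self.light_rep(10, 0)])
        assert math.isinf(table.loc["s1", "ratio"])
        assert bool(table.loc["s1", "degenerate"])

    def test_group_comparison_returned(self):
        reps = [self.light_rep(60, 20, f"w{i}", "WT") for i in range(3)] + [
            self.light_rep(30, 30, f"k{i}", "KO") for i in range(3)
        ]
        _, comparison = kappa_lambda_ratio(reps)
        assert comparison is not None
        assert 0 < comparison.p_two_sided <= 1

    def test_balanced_simulation_gives_median_ratio_near_one(self):
        design = (SampleMeta("s1", "WT", "B-1a", 1),)
        ratios = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_clones=200, heavy_fraction=0.0,
                                   kappa_lambda_probs=(0.5, 0.5),
                                   reads_per_sample=2000, sample_design=design)
            reps, _ = simulate_repertoire(cfg)
            table, _ = kappa_lambda_ratio(reps)
            ratios.append(table["ratio"].iloc[0])
        assert 0.8 < np.median(ratios) < 1.25


class TestIsotypeDistribution:
    def iso_rep(self, counts: dict[str, int], sample_id="s1", genotype="WT"):
        meta = SampleMeta(sample_id, genotype, "B-1a", 1)
        records = [
            Rearrangement(f"{sample_id}-{c}", "IGH", "IGHV1-1*01", "IGHD1-1*01",
                          "IGHJ1*01", c, "TGTTGG", f"CA{i}W", True, n, sample_id)
            for i, (c, n) in enumerate(counts.items())
        ]
        return Repertoire(meta, records)

    def test_proportions_from_abundances(self):
        table, _ = isotype_distribution([self.iso_rep({"IGHM": 80, "IGHD": 15, "IGHG1": 5})])
        row = table.loc["s1"]
        assert (row["IgM"], row["IgD"], row["IgG"]) == (0.80, 0.15, 0.05)
        assert (row["IgA"], row["IgE"]) == (0.0, 0.0)

    def test_proportions_sum_to_one(self, default_study):
        reps, _ = default_study
        table, _ = isotype_distribution(reps)
        assert np.allclose(table[["IgM", "IgD", "IgG", "IgA", "IgE"]].sum(axis=1), 1.0)

    def test_igm_modal_under_igm_dominant_config(self, default_study):
        reps, _ = default_study
        table, _ = isotype_distribution(reps)
        iso = table[["IgM", "IgD", "IgG", "IgA", "IgE"]]
        assert (iso.idxmax(axis=1) == "IgM").all()

    def test_degenerate_sample_flagged(self):
        meta = SampleMeta("s1", "WT", "B-1a", 1)
        rec = Rearrangement("r1", "IGH", "IGHV1-1*01", "IGHD1-1*01", "IGHJ1*01",
                            "", "TGTTGG", "CAW", True, 5, "s1")
        table, _ = isotype_distribution([Repertoire(meta, [rec])])
        assert bool(table.loc["s1", "degenerate"])
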