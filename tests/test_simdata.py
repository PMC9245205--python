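"""Synthetic-data generator: determinism, planted-truth realizability,
and the statistical contracts of each simulator."""

import numpy as np
import pandas as pd
import pytest

from heteroseq import simdata
from heteroseq.dominance import classify_dominance, hp_statistic
from heteroseq.simdata import ConfigurationError, SimConfig


class TestConfig:
    def test_category_fractions_over_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(hp_category_fractions={"additive": 0.6, "dominance": 0.5})

    def test_ase_fold_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(ase_fold=1.0)

    def test_impact_probs_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(impact_category_probs={"HIGH": 0.5, "MODERATE": 0.2,
                                             "LOW": 0.2, "MODIFIER": 0.2})

    def test_default_category_fractions_sum_to_frac_de(self):
        cfg = SimConfig(frac_de=0.3)
        assert sum(cfg.category_fractions().values()) == pytest.approx(0.3)


class TestTrioCounts:
    def test_same_seed_identical_twice(self):
        cfg = SimConfig(seed=2, n_genes=100)
        cm1, t1 = simdata.simulate_trio_counts(cfg)
        cm2, t2 = simdata.simulate_trio_counts(cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_config_has_equal_means(self):
        cfg = SimConfig(seed=3, n_genes=300, frac_de=0.0, n_replicates=30,
                        dispersion=0.01, tissues=("leaf",))
        cm, truth = simdata.simulate_trio_counts(cfg)
        assert not truth["de_status"].any()
        hyb = cm.counts[cm.sample_ids(role="hybrid")].mean(axis=1)
        mot = cm.counts[cm.sample_ids(role="maternal")].mean(axis=1)
        ratio = (hyb + 1) / (mot + 1)
        assert np.median(np.abs(np.log2(ratio))) < 0.1

    def test_planted_fraction_matches_frac_de(self):
        cfg = SimConfig(seed=1, n_genes=2000, frac_de=0.3)
        _, truth = simdata.simulate_trio_counts(cfg)
        frac = truth["de_status"].mean()
        assert abs(frac - 0.30) <= 0.02

    def test_planted_hp_is_recovered_exactly_from_noiseless_means(self):
        cfg = SimConfig(seed=4, n_genes=500)
        _, truth = simdata.simulate_trio_counts(cfg)
        planted = truth[truth["de_status"]]
        assert len(planted) > 50
        for r in planted.itertuples(index=False):
            a, d, hp = hp_statistic(r.p1, r.p2, r.f1)
            assert classify_dominance(hp) == r.hp_category
            assert hp == pytest.approx(r.hp_planted, abs=1e-9)
            # margin of at least 0.1 from every interval endpoint
            assert min(abs(hp - b) for b in (-1.2, -0.8, -0.2, 0.2, 0.8, 1.2)) >= 0.1 - 1e-9

    def test_planted_fold_change_guarantee(self):
        cfg = SimConfig(seed=5, n_genes=400, lfc_magnitude=1.0)
        _, truth = simdata.simulate_trio_counts(cfg)
        planted = truth[truth["de_status"]]
        fc = np.maximum.reduce([
            planted["f1"] / planted["p1"], planted["p1"] / planted["f1"],
            planted["f1"] / planted["p2"], planted["p2"] / planted["f1"]])
        assert (fc >= 2.0 - 1e-9).all()


class TestAllelicCounts:
    def test_balanced_gene_fraction_near_half(self):
        cfg = SimConfig(seed=6, n_genes=60, frac_ase=0.0,
                        allelic_depth_mean=10000.0, tissues=("leaf",))
        _, truth = simdata.simulate_trio_counts(cfg)
        al = simdata.simulate_allelic_counts(cfg, truth)
        frac = al["maternal_count"].sum() / (al["maternal_count"].sum() +
                                             al["paternal_count"].sum())
        n = al[["maternal_count", "paternal_count"]].to_numpy().sum()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n) + 1e-3
        per_gene = al.groupby("gene_id")[["maternal_count", "paternal_count"]].sum()
        g_frac = per_gene["maternal_count"] / per_gene.sum(axis=1)
        assert g_frac.between(0.48, 0.52).all()

    def test_expected_maternal_fraction_for_fourfold_bias(self):
        cfg = SimConfig(seed=7, n_genes=200, frac_ase=1.0, ase_fold=4.0,
                        allelic_depth_mean=2000.0, tissues=("leaf",))
        _, truth = simdata.simulate_trio_counts(cfg)
        al = simdata.simulate_allelic_counts(cfg, truth)
        mat_genes = set(truth.loc[truth["ase_direction"] == "maternal", "gene_id"])
        sub = al[al["gene_id"].isin(mat_genes)]
        frac = sub["maternal_count"].sum() / sub[["maternal_count",
                                                  "paternal_count"]].to_numpy().sum()
        assert frac == pytest.approx(0.8, abs=0.01)

    def test_zero_depth_mean_gives_all_zero(self):
        cfg = SimConfig(seed=8, n_genes=20, allelic_depth_mean=0.0, tissues=("leaf",))
        _, truth = simdata.simulate_trio_counts(cfg)
        al = simdata.simulate_allelic_counts(cfg, truth)
        assert (al[["maternal_count", "paternal_count"]] == 0).all().all()


class TestAnnotation:
    def test_planted_impacts_realized_by_construction(self):
        from heteroseq import varannot

        cfg = SimConfig(seed=9, n_genes=150)
        _, truth = simdata.simulate_trio_counts(cfg)
        genes, genome, variants, vt = simdata.simulate_genome_annotation(cfg, truth)
        effects = varannot.classify_variants(variants, genes, genome)
        eff = varannot.effects_to_frame(effects).merge(vt, on="variant_id",
                                                       suffixes=("", "_truth"))
        assert len(eff) == len(variants)
        assert (eff["impact"] == eff["impact_truth"]).all()
        # HIGH plants include both stop gains and frameshifts
        high = eff[eff["impact_truth"] == "HIGH"]["consequence"]
        assert {"stop_gained", "frameshift"} <= set(high)

    def test_genes_are_separated_and_ref_alleles_match_genome(self):
        cfg = SimConfig(seed=10, n_genes=60)
        genes, genome, variants, _ = simdata.simulate_genome_annotation(cfg)
        by_chrom: dict = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs = sorted(gs, key=lambda g: g.start)
            for g1, g2 in zip(gs, gs[1:]):
                assert g2.start - g1.end - 1 >= 1000
        for v in variants:
            assert genome[v.chrom][v.pos - 1: v.pos - 1 + len(v.ref)] == v.ref

    def test_ase_genes_carry_more_variants(self):
        cfg = SimConfig(seed=11, n_genes=400, frac_ase=0.3,
                        ase_variant_multiplier=3.0, tissues=("leaf",))
        _, truth = simdata.simulate_trio_counts(cfg)
        _, _, variants, _ = simdata.simulate_genome_annotation(cfg, truth)
        # variants sit in/near their source gene; count per gene id via truth
        ase = set(truth.loc[truth["ase_direction"] != "none", "gene_id"])
        from heteroseq import varannot

        genes, genome, variants, _ = simdata.simulate_genome_annotation(cfg, truth)
        eff = varannot.effects_to_frame(
            varannot.classify_variants(variants, genes, genome))
        per_gene = eff.dropna(subset=["gene_id"]).groupby("gene_id").size()
        per_gene = per_gene.reindex([g.gene_id for g in genes], fill_value=0)
        in_ase = per_gene.index.isin(ase)
        assert per_gene[in_ase].mean() > 2 * per_gene[~in_ase].mean()


def test_fixture_set_round_trip_and_byte_determinism(tmp_path):
    from heteroseq import io as hio

    cfg = SimConfig(seed=12, n_genes=40, n_terms=5)
    p1 = simdata.write_fixture_set(cfg, tmp_path / "a")
    p2 = simdata.write_fixture_set(cfg, tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key
    cm = hio.read_counts(p1["counts"], p1["samples"])
    assert cm.counts.shape == (40, 18)
    genes = hio.read_gff(p1["gff"])
    assert len(genes) == 40
    variants = hio.read_variants(p1["vcf"])
    assert variants
    genome = hio.read_fasta(p1["fasta"])
    assert set(genome) == {g.chrom for g in genes}
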