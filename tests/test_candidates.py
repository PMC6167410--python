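"""Candidate-gene cascade: interval lookup, impact filter, cis calls, tiers."""

import numpy as np
import pandas as pd
import pytest

from ridqtl.candidates import (cis_eqtl_test, genes_in_interval,
                               high_impact_filter, legacy_trait_correlations,
                               prioritize_candidates)
from ridqtl.scan_hk import Thresholds, hk_permutation_thresholds
from ridqtl.simulate import simulate_omics


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_symbol", "chromosome",
                                       "start_mb", "end_mb", "biotype"])


def _variants(rows):
    return pd.DataFrame(rows, columns=["chromosome", "position_mb",
                                       "gene_symbol", "consequence"])


class TestGenesInInterval:
    def test_empty_interval(self):
        genes = _genes([("A", 1, 5.0, 6.0, "protein_coding")])
        assert genes_in_interval(genes, (1, 5.5, 5.5)).empty

    def test_boundary_spanning_gene_included(self):
        genes = _genes([("A", 1, 4.0, 5.5, "protein_coding")])
        assert list(genes_in_interval(genes, (1, 5.0, 10.0))["gene_symbol"]) == ["A"]

    def test_counts_with_constructed_fixture(self):
        rng = np.random.default_rng(0)
        inside = [(f"I{i}", 2, p, p + 0.1, "protein_coding")
                  for i, p in enumerate(rng.uniform(10, 19.8, 10))]
        outside = [(f"O{i}", 2, p, p + 0.1, "protein_coding")
                   for i, p in enumerate(rng.uniform(30, 40, 5))]
        hit = genes_in_interval(_genes(inside + outside), (2, 10.0, 20.0))
        assert sorted(hit["gene_symbol"]) == sorted(g[0] for g in inside)

    def test_validation(self):
        genes = _genes([("A", 1, 5.0, 6.0, "protein_coding")])
        with pytest.raises(KeyError):
            genes_in_interval(genes, (9, 0.0, 1.0))
        with pytest.raises(ValueError):
            genes_in_interval(genes, (1, 2.0, 1.0))


class TestHighImpactFilter:
    def test_missense_kept_synonymous_dropped(self):
        genes = _genes([("A", 1, 1.0, 2.0, "protein_coding"),
                        ("B", 1, 3.0, 4.0, "protein_coding")])
        variants = _variants([(1, 1.5, "A", "missense variant"),
                              (1, 3.5, "B", "synonymous variant")])
        assert high_impact_filter(genes, variants) == ["A"]

    def test_case_insensitive_consequences(self):
        genes = _genes([("A", 1, 1.0, 2.0, "protein_coding")])
        variants = _variants([(1, 1.5, "A", "Stop Gained")])
        assert high_impact_filter(genes, variants) == ["A"]

    def test_empty_impact_set_rejected(self):
        with pytest.raises(ValueError):
            high_impact_filter(["A"], _variants([]), impact_set=set())


@pytest.fixture(scope="module")
def panel_thresholds(panel_geno):
    probe = pd.Series(np.random.default_rng(1).normal(size=panel_geno.n_strains),
                      index=panel_geno.strains)
    return hk_permutation_thresholds(probe, panel_geno, n_perm=200, seed=1)


class TestCisEqtl:
    def test_perfect_cis_signal_significant(self, panel_geno, panel_thresholds):
        j = 25
        pos = panel_geno.markers.iloc[j]
        probe = pd.Series(panel_geno.calls[:, j]
                          + 0.01 * np.random.default_rng(2).normal(size=panel_geno.n_strains),
                          index=panel_geno.strains, name="probe")
        call = cis_eqtl_test(probe, (int(pos["chromosome"]), float(pos["position_mb"])),
                             panel_geno, panel_thresholds)
        assert call == "significant"

    def test_distal_driver_classified_trans(self, panel_geno, panel_thresholds):
        # strong peak 50+ Mb away from the gene must not count as cis
        sub = panel_geno.markers[panel_geno.markers["chromosome"] == 1]
        j = sub.index[np.argmin(np.abs(sub["position_mb"] - 90.0))]
        probe = pd.Series(panel_geno.calls[:, j]
                          + 0.01 * np.random.default_rng(3).normal(size=panel_geno.n_strains),
                          index=panel_geno.strains, name="probe")
        call = cis_eqtl_test(probe, (1, 10.0), panel_geno, panel_thresholds,
                             window_mb=10.0)
        assert call == "none"

    def test_affine_invariance_of_classification(self, panel_geno, panel_thresholds):
        j = 60
        pos = panel_geno.markers.iloc[j]
        rng = np.random.default_rng(4)
        probe = pd.Series(0.5 * panel_geno.calls[:, j] + 0.4 * rng.normal(size=panel_geno.n_strains),
                          index=panel_geno.strains, name="probe")
        loc = (int(pos["chromosome"]), float(pos["position_mb"]))
        a = cis_eqtl_test(probe, loc, panel_geno, panel_thresholds)
        b = cis_eqtl_test(5.0 * probe - 2.0, loc, panel_geno, panel_thresholds)
        assert a == b

    def test_null_probes_rarely_exceed_significant(self, panel_geno, panel_thresholds):
        # genome-wide significant threshold holds ~5% of null scans
        from ridqtl.scan_hk import hk_lod_profile
        rng = np.random.default_rng(5)
        G = panel_geno.calls
        n_exceed = sum(
            hk_lod_profile(rng.normal(size=panel_geno.n_strains), G).max()
            >= panel_thresholds.significant
            for _ in range(200)
        )
        assert 1 <= n_exceed <= 25  # ~10 expected at the 0.95 quantile

    def test_zero_variance_probe_rejected(self, panel_geno, panel_thresholds):
        probe = pd.Series(np.ones(panel_geno.n_strains), index=panel_geno.strains)
        with pytest.raises(ValueError):
            cis_eqtl_test(probe, (1, 10.0), panel_geno, panel_thresholds)

    def test_strong_cis_simulation_all_detected(self, panel_geno, panel_thresholds):
        # cis_fraction = 1 with gamma/sigma = 10: every gene called cis
        genes, _, expr = simulate_omics(panel_geno, n_genes=15, cis_fraction=1.0,
                                        cis_effect=2.0, expr_noise_sd=0.2, seed=6)
        strain_cols = panel_geno.strains
        for sym in genes["gene_symbol"]:
            probe = expr.loc[sym, strain_cols].astype(float)
            probe.name = sym
            loc = (int(expr.loc[sym, "chromosome"]), float(expr.loc[sym, "position_mb"]))
            assert cis_eqtl_test(probe, loc, panel_geno, panel_thresholds) != "none"


class TestPrioritize:
    def test_engineered_gene_is_tier_one_rank_one(self, panel_geno, panel_thresholds):
        rng = np.random.default_rng(7)
        genes, variants, expr = simulate_omics(panel_geno, n_genes=40,
                                               cis_fraction=0.3, impact_fraction=0.5,
                                               seed=7)
        interval = (1, 10.0, 90.0)
        in_iv = genes_in_interval(genes, interval)
        planted = in_iv["gene_symbol"].iloc[0]
        grow = genes.index[genes["gene_symbol"] == planted][0]
        genes.loc[grow, "biotype"] = "protein_coding"
        sub = panel_geno.markers[panel_geno.markers["chromosome"] == 1]
        mid = 0.5 * (genes.loc[grow, "start_mb"] + genes.loc[grow, "end_mb"])
        j = sub.index[np.argmin(np.abs(sub["position_mb"] - mid))]
        strain_cols = panel_geno.strains
        expr.loc[planted, strain_cols] = (panel_geno.calls[:, j]
                                          + 0.05 * rng.normal(size=panel_geno.n_strains))
        variants = pd.concat([variants, _variants(
            [(1, mid, planted, "missense variant")])], ignore_index=True)
        trait = pd.Series(expr.loc[planted, strain_cols].astype(float).to_numpy()
                          + 0.2 * rng.normal(size=panel_geno.n_strains),
                          index=panel_geno.strains, name="W1D4")
        table = prioritize_candidates(interval, genes, variants, expr, trait,
                                      panel_geno, panel_thresholds)
        assert table.iloc[0]["gene_symbol"] == planted
        assert table.iloc[0]["priority_tier"] == 1

    def test_no_high_impact_gene_excluded_despite_correlation(
            self, panel_geno, panel_thresholds):
        genes = _genes([("A", 1, 20.0, 20.2, "protein_coding")])
        variants = _variants([(1, 20.1, "A", "synonymous variant")])
        trait = pd.Series(np.linspace(0, 1, panel_geno.n_strains),
                          index=panel_geno.strains)
        expr = pd.DataFrame([trait.to_numpy()], index=pd.Index(["A"], name="gene_symbol"),
                            columns=panel_geno.strains)
        expr.insert(0, "chromosome", [1])
        expr.insert(1, "position_mb", [20.1])
        table = prioritize_candidates((1, 10.0, 30.0), genes, variants, expr,
                                      trait, panel_geno, panel_thresholds)
        assert table.empty

    def test_excluded_biotypes_filtered(self, panel_geno, panel_thresholds):
        genes = _genes([("P", 1, 20.0, 20.2, "pseudogene")])
        variants = _variants([(1, 20.1, "P", "missense variant")])
        expr = pd.DataFrame([np.zeros(panel_geno.n_strains)],
                            index=pd.Index(["P"], name="gene_symbol"),
                            columns=panel_geno.strains)
        expr.insert(0, "chromosome", [1])
        expr.insert(1, "position_mb", [20.1])
        trait = pd.Series(np.linspace(0, 1, panel_geno.n_strains),
                          index=panel_geno.strains)
        table = prioritize_candidates((1, 10.0, 30.0), genes, variants, expr,
                                      trait, panel_geno, panel_thresholds)
        assert table.empty

    def test_empty_interval_empty_table(self, panel_geno, panel_thresholds):
        genes = _genes([("A", 1, 20.0, 20.2, "protein_coding")])
        table = prioritize_candidates((1, 50.0, 50.0), genes, _variants([]),
                                      pd.DataFrame(columns=["chromosome", "position_mb"]),
                                      pd.Series(dtype=float), panel_geno,
                                      panel_thresholds)
        assert table.empty


class TestLegacyCorrelations:
    def test_trait_against_itself_retained(self):
        strains = [f"S{i}" for i in range(20)]
        trait = pd.Series(np.random.default_rng(8).normal(size=20), index=strains)
        legacy = pd.DataFrame([trait.to_numpy()], index=["self"], columns=strains)
        out = legacy_trait_correlations(trait, legacy)
        assert len(out) == 1 and out.iloc[0]["r"] == pytest.approx(1.0)

    def test_null_screen_calibrated(self):
        rng = np.random.default_rng(9)
        strains = [f"S{i}" for i in range(30)]
        trait = pd.Series(rng.normal(size=30), index=strains)
        legacy = pd.DataFrame(rng.normal(size=(1000, 30)), columns=strains,
                              index=[f"L{i}" for i in range(1000)])
        out = legacy_trait_correlations(trait, legacy, p_cut=0.005)
        assert len(out) <= 15  # ~5 expected under the null

    def test_negative_correlate_recovered(self):
        rng = np.random.default_rng(10)
        strains = [f"S{i}" for i in range(25)]
        trait = pd.Series(rng.normal(size=25), index=strains)
        legacy = pd.DataFrame([-trait.to_numpy() + 0.05 * rng.normal(size=25)],
                              index=["anti"], columns=strains)
        out = legacy_trait_correlations(trait, legacy)
        assert len(out) == 1 and out.iloc[0]["r"] < -0.9

    def test_spearman_flag_and_overlap_validation(self):
        strains = [f"S{i}" for i in range(10)]
        trait = pd.Series(np.arange(10.0), index=strains)
        legacy = pd.DataFrame([np.arange(10.0) ** 3], index=["cubed"], columns=strains)
        out = legacy_trait_correlations(trait, legacy, p_cut=0.05, method="spearman")
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        with pytest.raises(ValueError):
            legacy_trait_correlations(trait, legacy.rename(columns=lambda c: "X" + c))
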