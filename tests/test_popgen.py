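"""Hudson Fst, Haseman-Elston/Qst, climate correlations, enrichments."""

import numpy as np
import pandas as pd
import pytest

from methclime import gwas, popgen
from methclime.datatypes import GenotypeTable
from methclime.simulate import SimConfig, simulate_genotypes


def brute_force_hudson(g1: np.ndarray, g2: np.ndarray):
    """Per-site Hudson numerator/denominator by explicit counting."""
    n1, n2 = len(g1), len(g2)
    p1 = g1.mean()
    p2 = g2.mean()
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _table(geno, regions, lats=None):
    n = geno.shape[0]
    acc = [f"a{i}" for i in range(n)]
    if lats is None:
        lats = np.where(np.asarray(regions) == "north", 65.0, 57.0)
    md = pd.DataFrame({"latitude": lats, "region": regions}, index=acc)
    snps = pd.DataFrame({"chrom": "Chr1",
                         "pos": np.arange(geno.shape[1]) * 100 + 1,
                         "id": [f"s{j}" for j in range(geno.shape[1])]})
    return GenotypeTable(np.asarray(geno, np.int8), snps, acc, md)


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        num, den = popgen.hudson_fst_site(1.0, 0.0, 10, 10)
        assert num / den == pytest.approx(1.0)

    def test_plugin_arithmetic_equal_freqs(self):
        """p1=p2=0.5, n=10 each: num=-0.0556, den=0.5, ratio=-0.111."""
        num, den = popgen.hudson_fst_site(0.5, 0.5, 10, 10)
        assert num == pytest.approx(-0.0556, abs=1e-4)
        assert den == pytest.approx(0.5)
        assert num / den == pytest.approx(-0.111, abs=1e-3)

    def test_matches_brute_force_per_site(self, rng):
        geno = (rng.random((20, 50)) < rng.uniform(0.1, 0.9, 50)).astype(
            np.int8)
        regions = ["north"] * 11 + ["south"] * 9
        g = _table(geno, regions)
        out = popgen.hudson_fst(g)
        m1 = np.array(regions) == "north"
        for j in range(50):
            num, den = brute_force_hudson(geno[m1, j], geno[~m1, j])
            if den > 0:
                assert out["per_site"][j] == pytest.approx(num / den)
            else:
                assert np.isnan(out["per_site"][j])

    def test_ratio_of_averages_not_average_of_ratios(self, rng):
        geno = (rng.random((30, 200)) < 0.5).astype(np.int8)
        geno[:15, :50] = 1
        geno[15:, :50] = 0
        g = _table(geno, ["north"] * 15 + ["south"] * 15)
        out = popgen.hudson_fst(g)
        num, den = out["numerator"], out["denominator"]
        keep = den > 0
        assert out["fst"] == pytest.approx(num[keep].sum() / den[keep].sum())
        assert out["fst"] != pytest.approx(out["fst_mean_of_ratios"])

    def test_monomorphic_everywhere_excluded(self):
        geno = np.zeros((10, 3), np.int8)
        geno[:, 1] = 1
        g = _table(geno, ["north"] * 5 + ["south"] * 5)
        out = popgen.hudson_fst(g)
        assert np.isnan(out["per_site"][[0, 1]]).all()


class TestHasemanElston:
    def test_scale_equivariance(self, rng):
        g = simulate_genotypes(SimConfig(n_accessions=60, n_snps=800,
                                         seed=30))
        K = gwas.kinship_ibs(g)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(60))
        y = L @ rng.standard_normal(60)
        s1 = popgen.he_additive_variance(y, K)
        s2 = popgen.he_additive_variance(2.0 * y, K)
        assert s2 == pytest.approx(4.0 * s1, rel=1e-8)

    def test_null_phenotype_near_zero(self):
        g = simulate_genotypes(SimConfig(n_accessions=80, n_snps=800,
                                         seed=31))
        K = gwas.kinship_ibs(g)
        vals = []
        for s in range(30):
            y = np.random.default_rng(s).standard_normal(80)
            vals.append(popgen.he_additive_variance(y, K) / y.var())
        assert abs(np.mean(vals)) < 0.05 * 1.0 / 0.05  # |mean| small
        assert np.mean(vals) < 0.5

    def test_heritability_recovery(self):
        """Additive h2=0.5 phenotypes recover in [0.3, 0.7] (median).

        Each replicate draws a fresh structured panel and a polygenic
        trait; conditioning on a single panel leaves the estimate
        dominated by that panel's few kinship axes.
        """
        h2s = []
        for s in range(15):
            g = simulate_genotypes(SimConfig(n_accessions=150, n_snps=2000,
                                             seed=1000 + s))
            K = gwas.kinship_ibs(g)
            G = g.genotypes.astype(float)
            rng = np.random.default_rng(s)
            gvals = (G - G.mean(0)) @ rng.standard_normal(G.shape[1])
            gvals = gvals / gvals.std()
            y = gvals + rng.standard_normal(150)
            h2s.append(popgen.he_additive_variance(y, K) / y.var())
        assert 0.3 <= np.median(h2s) <= 0.7

    def test_constant_kinship_rejected(self):
        K = np.full((5, 5), 0.5)
        np.fill_diagonal(K, 1.0)
        with pytest.raises(ValueError):
            popgen.he_additive_variance(np.arange(5.0), K)


class TestQst:
    def test_no_between_variance_gives_zero(self):
        g = simulate_genotypes(SimConfig(n_accessions=60, n_snps=800,
                                         seed=33, fst_target=0.0))
        rng = np.random.default_rng(0)
        y = rng.standard_normal(60)  # no group difference
        q = popgen.qst(y, g)
        assert q.sigma2_between == max(
            q.sigma2_overall - q.sigma2_within, 0.0)
        if q.sigma2_between == 0.0:
            assert q.qst == 0.0

    def test_equal_between_within_closed_form(self):
        r = popgen.QstResult(0, 0, 0, sigma2_within=0.4, sigma2_between=0.4,
                             qst=0.4 / (0.4 + 0.8), degenerate=False)
        assert r.qst == pytest.approx(1.0 / 3.0)

    def test_weighted_within_average(self):
        g = simulate_genotypes(SimConfig(n_accessions=60, n_snps=800,
                                         seed=34, pop_split=0.3))
        y = np.random.default_rng(1).standard_normal(60)
        q = popgen.qst(y, g)
        nN = (g.metadata["region"] == "north").sum()
        nS = 60 - nN
        expect = ((nN - 1) * q.sigma2_north + (nS - 1) * q.sigma2_south) \
            / (nN + nS - 2)
        assert q.sigma2_within == pytest.approx(expect)

    def test_small_population_rejected(self):
        g = simulate_genotypes(SimConfig(n_accessions=20, n_snps=100,
                                         seed=35))
        g2 = g.subset_accessions(list(range(3)) + list(range(10, 20)))
        with pytest.raises(ValueError):
            popgen.qst(np.zeros(13), g2)


class TestEnvCorrelations:
    def _meth(self, g, values):
        return pd.DataFrame({
            "accession": g.accessions, "environment": "10C",
            "context": "CG", "level": values})

    def test_self_correlation_is_one(self):
        g = simulate_genotypes(SimConfig(n_accessions=40, n_snps=100,
                                         seed=36))
        vals = np.random.default_rng(2).random(40)
        env = pd.DataFrame({"self": vals}, index=g.accessions)
        out = popgen.env_correlations(self._meth(g, vals), env)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)
        assert out["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_variable_missing(self):
        g = simulate_genotypes(SimConfig(n_accessions=40, n_snps=100,
                                         seed=36))
        env = pd.DataFrame({"const": np.ones(40)}, index=g.accessions)
        vals = np.random.default_rng(3).random(40)
        out = popgen.env_correlations(self._meth(g, vals), env)
        assert np.isnan(out["pearson_r"].iloc[0])

    def test_planted_latitude_coupling_recovered(self):
        g = simulate_genotypes(SimConfig(n_accessions=150, n_snps=100,
                                         seed=37))
        lat = g.metadata["latitude"].to_numpy()
        rng = np.random.default_rng(4)
        z = (lat - lat.mean()) / lat.std()
        # noise sized for a true correlation of 0.7
        noise = np.sqrt(1 / 0.49 - 1)
        vals = z + noise * rng.standard_normal(150)
        env = pd.DataFrame({"latitude": lat}, index=g.accessions)
        out = popgen.env_correlations(self._meth(g, vals), env)
        assert out["pearson_r"].iloc[0] == pytest.approx(0.7, abs=0.1)


class TestAlleleGeography:
    def test_private_allele_frequencies(self):
        g = simulate_genotypes(SimConfig(n_accessions=60, n_snps=500,
                                         seed=38))
        reg = g.metadata["region"].to_numpy()
        geno = g.genotypes.copy()
        geno[:, 0] = (reg == "north").astype(np.int8)  # private to north
        g = GenotypeTable(geno, g.snps, g.accessions, g.metadata)
        out = popgen.allele_geography(g, np.array([0]))
        row = out["table"].iloc[0]
        assert row["freq_north"] > 0 and row["freq_south"] == 0
        assert row["latitude_r"] > 0.8

    def test_random_set_latitude_centered(self):
        g = simulate_genotypes(SimConfig(n_accessions=100, n_snps=2000,
                                         seed=39, fst_target=0.0))
        idx = np.random.default_rng(5).choice(2000, 50, replace=False)
        out = popgen.allele_geography(g, idx)
        assert abs(out["table"]["latitude_r"].mean()) < 0.15

    def test_north_restricted_set_shifts_spectrum(self):
        hits = 0
        for s in range(10):
            g = simulate_genotypes(SimConfig(n_accessions=100, n_snps=2000,
                                             seed=60 + s))
            reg = g.metadata["region"].to_numpy()
            geno = g.genotypes.copy()
            rng = np.random.default_rng(s)
            idx = rng.choice(2000, 15, replace=False)
            for j in idx:
                geno[:, j] = ((reg == "north")
                              & (rng.random(100) < 0.6)).astype(np.int8)
            g = GenotypeTable(geno, g.snps, g.accessions, g.metadata)
            out = popgen.allele_geography(g, idx, seed=s)
            hits += out["spectrum_ks_p"] < 0.05
        assert hits >= 7

    def test_empty_set_rejected(self):
        g = simulate_genotypes(SimConfig(n_accessions=60, n_snps=100,
                                         seed=38))
        with pytest.raises(ValueError):
            popgen.allele_geography(g, np.array([], dtype=int))


@pytest.fixture(scope="module")
def g():
    return simulate_genotypes(SimConfig(n_accessions=80, n_snps=2000,
                                        seed=40))


class TestSnpOverlapPermutation:
    def test_whole_genome_fold_one(self, g):
        regions = pd.DataFrame([
            {"chrom": c, "start": 1, "end": 10**9}
            for c in g.snps["chrom"].unique()])
        idx = np.arange(0, 2000, 100)
        out = popgen.snp_overlap_permutation(g, idx, regions=regions,
                                            n_perm=100, seed=0)
        assert out["fold"] == pytest.approx(1.0)
        assert out["p"] > 0.5

    def test_set_inside_regions_closed_form_fold(self, g):
        # regions covering ~10% of SNPs; set drawn from inside
        pos = g.snps["pos"].to_numpy()
        chrom = g.snps["chrom"].to_numpy()
        lim = np.quantile(pos[chrom == "Chr1"], 0.5)
        regions = pd.DataFrame([{"chrom": "Chr1", "start": 1,
                                 "end": int(lim)}])
        inside = np.flatnonzero((chrom == "Chr1") & (pos <= lim))
        frac = len(inside) / 2000
        idx = np.random.default_rng(1).choice(inside, 15, replace=False)
        out = popgen.snp_overlap_permutation(g, idx, regions=regions,
                                            n_perm=400, seed=2)
        assert out["fold"] == pytest.approx(1.0 / frac, rel=0.25)
        assert out["p"] < 0.05

    def test_p_floor_formula(self, g):
        regions = pd.DataFrame([{"chrom": "Chr1", "start": 1, "end": 10**9}])
        chrom = g.snps["chrom"].to_numpy()
        idx = np.flatnonzero(chrom == "Chr1")[:20]
        out = popgen.snp_overlap_permutation(g, idx, regions=regions,
                                            n_perm=999, seed=3,
                                            freq_match=False)
        # observed can never be exceeded (all set SNPs inside)
        assert out["p"] <= 21 / 1000  # ties allowed; floored at 1/1000
        assert out["p"] >= 1 / 1000


class TestExpressionComparisons:
    def _setup(self, seed=41, coupling=0.4, north_lib_scale=None):
        from methclime.simulate import (simulate_annotations,
                                        simulate_expression,
                                        simulate_methylomes)

        cfg = SimConfig(n_accessions=40, n_snps=400, genome_length=600_000,
                        n_genes=60, n_tes=30, site_spacing=80, seed=seed)
        g = simulate_genotypes(cfg)
        annot = simulate_annotations(cfg)
        _, truth = simulate_methylomes(g, annot, cfg)
        scale = None
        if north_lib_scale is not None:
            scale = np.where(g.metadata["region"] == "north",
                             north_lib_scale, 1.0)
        expr = simulate_expression(g, annot, truth, cfg, coupling=coupling,
                                   library_scale=scale)
        genes = annot.genes()["id"]
        classes = pd.Series(
            ["gbm" if x in set(truth.gbm_genes) else "non_gbm"
             for x in genes], index=genes, name="gbm_class")
        return g, expr, classes

    def test_gbm_contrast_significant_nongbm_not(self):
        # no library confounder planted here, so compare unnormalized:
        # median-of-genes scaling would leak a genuine GBM-class shift
        # into the other class when a third of all genes carry it
        wins = 0
        for s in range(6):
            g, expr, classes = self._setup(seed=200 + s)
            out = popgen.expression_comparisons(expr, classes, g.metadata,
                                                normalize=False)
            gbm_p = out["north_vs_south"][("10C", "gbm")]["p"]
            non_p = out["north_vs_south"][("10C", "non_gbm")]["p"]
            gbm_dir = (out["north_vs_south"][("10C", "gbm")]["north_mean"]
                       > out["north_vs_south"][("10C", "gbm")]["south_mean"])
            if gbm_p < 0.05 and non_p > 0.05 and gbm_dir:
                wins += 1
        assert wins >= 4

    def test_identical_regions_null(self):
        g, expr, classes = self._setup(coupling=0.0)
        out = popgen.expression_comparisons(expr, classes, g.metadata)
        assert out["north_vs_south"][("10C", "non_gbm")]["p"] > 0.01

    def test_normalization_removes_library_confounder(self):
        g, expr, classes = self._setup(coupling=0.0, north_lib_scale=2.0)
        raw = popgen.expression_comparisons(expr, classes, g.metadata,
                                            normalize=False)
        norm = popgen.expression_comparisons(expr, classes, g.metadata,
                                             normalize=True)
        raw_gap = (raw["north_vs_south"][("10C", "non_gbm")]["north_mean"]
                   / raw["north_vs_south"][("10C", "non_gbm")]["south_mean"])
        norm_gap = (norm["north_vs_south"][("10C", "non_gbm")]["north_mean"]
                    / norm["north_vs_south"][("10C", "non_gbm")]["south_mean"])
        assert raw_gap > 1.5
        assert norm_gap == pytest.approx(1.0, abs=0.1)
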