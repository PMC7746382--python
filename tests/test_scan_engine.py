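import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gccscan.errors import (
    ConfigError,
    DegenerateInputError,
    JoinError,
    RankError,
)
from gccscan.io_gwas import AssocResult, PhenoTable
from gccscan.scan_engine import (
    ScanConfig,
    adjust_phenotype,
    boxcox_transform,
    genomic_inflation,
    genotype_density_table,
    manhattan_table,
    qq_table,
    run_scan,
)
from gccscan.twin_sim import (
    TwinSimConfig,
    effect_size_for_variance_explained,
    simulate_phenotype,
    simulate_twin_genotypes,
)

from .conftest import make_pheno_frame


class TestAdjustPhenotype:
    def test_pure_noise_returns_centered_noise(self, rng):
        df = make_pheno_frame(n_dz=50, seed=1)
        noise = rng.standard_normal(len(df))
        df["phenotype"] = 3.0 + 0.0 * df["age"] + noise
        resid = adjust_phenotype(PhenoTable(df), ["age"])
        # residuals equal noise centered and de-trended against age
        assert abs(resid.mean()) < 1e-10
        np.testing.assert_allclose(resid, noise - noise.mean(), atol=0.5)

    def test_orthogonality_to_covariates(self, rng):
        df = make_pheno_frame(n_dz=100, seed=2)
        df["phenotype"] = 2.0 * df["age"] + rng.standard_normal(len(df))
        pt = PhenoTable(df)
        resid = adjust_phenotype(pt, ["age", "sex"])
        age = df["age"].to_numpy()
        assert abs(np.corrcoef(resid, age)[0, 1]) < 1e-10

    def test_recovery_matches_normal_equations(self, rng):
        df = make_pheno_frame(n_dz=100, seed=3)
        noise = rng.standard_normal(len(df))
        df["phenotype"] = 0.5 * df["age"] + noise
        resid = adjust_phenotype(PhenoTable(df), ["age"])
        # direct normal-equations solve as oracle
        age = df["age"].to_numpy()
        W = np.column_stack([np.ones(len(df)), age])
        beta = np.linalg.solve(W.T @ W, W.T @ df["phenotype"].to_numpy())
        np.testing.assert_allclose(resid, df["phenotype"].to_numpy() - W @ beta,
                                   atol=1e-10)
        slope = np.polyfit(age, resid, 1)[0]
        assert abs(slope) < 1e-10

    def test_collinear_covariates_rejected(self):
        df = make_pheno_frame(n_dz=20, seed=4)
        df["age2"] = 2.0 * df["age"]
        with pytest.raises(RankError):
            adjust_phenotype(PhenoTable(df), ["age", "age2"])


class TestBoxCox:
    def test_normal_input_near_identity(self, rng):
        y = 10.0 + rng.standard_normal(1000)
        yt, lam, shift = boxcox_transform(y)
        assert 0.7 <= lam <= 1.3 or np.corrcoef(yt, y)[0, 1] > 0.99
        assert np.corrcoef(yt, y)[0, 1] > 0.99

    def test_lognormal_input_finds_log(self, rng):
        y = np.exp(rng.standard_normal(2000))
        _, lam, shift = boxcox_transform(y)
        assert -0.2 <= lam <= 0.2
        assert shift == 0.0

    def test_nonpositive_input_shifted(self, rng):
        y = rng.standard_normal(100)
        y[0] = 0.0
        y = y - y.min()  # min exactly 0
        _, lam, shift = boxcox_transform(y)
        assert shift == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            boxcox_transform(np.full(50, 2.0))


class TestGenomicInflation:
    def test_reference_median_gives_exactly_one(self):
        assert genomic_inflation(np.full(1001, 0.5)) == pytest.approx(1.0, abs=1e-4)

    def test_uniform_pvalues_give_one(self, rng):
        p = rng.uniform(size=100_000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_inflated_chisq_recovers_scale(self, rng):
        stats_null = rng.chisquare(1, size=100_000) * 1.2
        p = stats.chi2.sf(stats_null, df=1)
        assert genomic_inflation(p) == pytest.approx(1.2, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            genomic_inflation(np.array([]))


class TestPlottingTables:
    def test_qq_single_pvalue_convention(self):
        qq = qq_table(np.array([0.1]))
        assert qq["expected_neglog10"].iloc[0] == pytest.approx(-np.log10(0.5))
        assert qq["observed_neglog10"].iloc[0] == pytest.approx(1.0)

    def test_qq_uniform_hugs_diagonal(self, rng):
        qq = qq_table(rng.uniform(size=10_000))
        gap = np.abs(qq["observed_neglog10"] - qq["expected_neglog10"])
        assert np.quantile(gap, 0.99) < 0.5

    def test_genotype_density_classes(self, rng):
        g = np.repeat([0.05, 0.95, 2.0], 30)  # dosages rounding to 0/1/2
        y = rng.standard_normal(90)
        table = genotype_density_table(g, y)
        assert set(table) == {0, 1, 2}
        assert all(len(v) == 30 for v in table.values())

    def test_manhattan_sorted_by_coordinate(self):
        results = [
            AssocResult(snp_id="a", model="gcc", statistic=1, pvalue=0.5,
                        n_used=10, chrom="2", pos=50),
            AssocResult(snp_id="b", model="gcc", statistic=1, pvalue=0.1,
                        n_used=10, chrom="1", pos=99),
            AssocResult(snp_id="c", model="gcc", statistic=1, pvalue=0.9,
                        n_used=10, chrom="1", pos=10),
        ]
        mh = manhattan_table(results)
        assert mh["snp_id"].tolist() == ["c", "b", "a"]


def _sim_scan_inputs(n_snps=50, seed=0, n_mz=30, n_dz=120):
    cfg = TwinSimConfig(n_mz_pairs=n_mz, n_dz_pairs=n_dz, n_snps=n_snps, seed=seed)
    dm, skel = simulate_twin_genotypes(cfg)
    pt = simulate_phenotype(np.zeros(cfg.n_total), skel, cfg)
    return dm, pt, cfg


class TestRunScan:
    def test_null_scan_yields_result_per_snp_and_no_hits(self):
        dm, pt, _ = _sim_scan_inputs(n_snps=50, seed=5)
        rep = run_scan(dm, pt, ScanConfig(model="kinship", seed=1))
        retained = [s.snp_id for s in dm.snps if s.maf >= 0.05]
        assert [r.snp_id for r in rep.results] == retained
        assert rep.n_gw_significant <= 1

    def test_low_maf_snp_filtered_out(self):
        cfg = TwinSimConfig(n_snps=5, maf=0.01, seed=2)
        dm, skel = simulate_twin_genotypes(cfg)
        pt = simulate_phenotype(np.zeros(cfg.n_total), skel, cfg)
        rep = run_scan(dm, pt, ScanConfig(model="kinship", seed=1))
        assert len(rep.results) == 0

    def test_monomorphic_snp_skipped_with_reason(self):
        dm, pt, _ = _sim_scan_inputs(n_snps=5, seed=3)
        dm.values[:, 2] = 1.0
        dm.snps[2] = type(dm.snps[2])(
            snp_id=dm.snps[2].snp_id, chrom=dm.snps[2].chrom, pos=dm.snps[2].pos,
            ref_allele="A", alt_allele="G", maf=0.5, info=None,
        )
        rep = run_scan(dm, pt, ScanConfig(model="kinship", seed=1))
        assert (dm.snps[2].snp_id, "monomorphic") in rep.skipped
        assert dm.snps[2].snp_id not in [r.snp_id for r in rep.results]

    def test_injected_effect_snp_ranks_first_under_all_models(self):
        cfg = TwinSimConfig(n_mz_pairs=50, n_dz_pairs=125, n_snps=30, seed=8)
        dm, skel = simulate_twin_genotypes(cfg)
        g = dm.values[:, 7]
        beta = effect_size_for_variance_explained(0.08, g, "additive")
        eff_cfg = TwinSimConfig(
            n_mz_pairs=50, n_dz_pairs=125, n_snps=30, seed=8,
            effect_model="additive", effect_size=beta,
        )
        pt = simulate_phenotype(g, skel, eff_cfg)
        target = dm.snps[7].snp_id
        for model in ("kinship", "lme", "gcc"):
            cfgscan = ScanConfig(model=model, seed=4, n_perm=199)
            rep = run_scan(dm, pt, cfgscan)
            best = min(rep.results, key=lambda r: (r.pvalue, -abs(r.statistic)))
            assert best.snp_id == target, model

    def test_sample_order_invariance(self, rng):
        dm, pt, _ = _sim_scan_inputs(n_snps=10, seed=9)
        rep1 = run_scan(dm, pt, ScanConfig(model="kinship", seed=2))
        shuffled = PhenoTable(
            pt.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        rep2 = run_scan(dm, shuffled, ScanConfig(model="kinship", seed=2))
        p1 = {r.snp_id: r.pvalue for r in rep1.results}
        p2 = {r.snp_id: r.pvalue for r in rep2.results}
        for snp in p1:
            assert p2[snp] == pytest.approx(p1[snp], rel=1e-8)

    def test_disjoint_sample_ids_raise_join_error(self):
        dm, pt, _ = _sim_scan_inputs(n_snps=3, seed=10)
        renamed = pt.data.assign(sample_id=["zz" + s for s in pt.sample_ids])
        with pytest.raises(JoinError):
            run_scan(dm, PhenoTable(renamed), ScanConfig(model="kinship"))

    def test_boxcox_rank_stability_on_normal_phenotype(self):
        dm, pt, _ = _sim_scan_inputs(n_snps=60, seed=12)
        # shift phenotype positive so Box-Cox is a gentle power transform
        pt = PhenoTable(pt.data.assign(phenotype=pt.phenotype + 10.0))
        rep_raw = run_scan(dm, pt, ScanConfig(model="kinship", boxcox=False, seed=3))
        rep_bc = run_scan(dm, pt, ScanConfig(model="kinship", boxcox=True, seed=3))
        lp_raw = -np.log10([r.pvalue for r in rep_raw.results])
        lp_bc = -np.log10([r.pvalue for r in rep_bc.results])
        assert np.corrcoef(lp_raw, lp_bc)[0, 1] > 0.99

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            ScanConfig(model="anova")
        with pytest.raises(ConfigError):
            ScanConfig(gw_threshold=1e-3, suggestive_threshold=1e-5)
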