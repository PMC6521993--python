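"""Mixed-model scan: QC ordering, kinship estimator, OLS collapse with an
identity kinship, calibration under structured nulls, LD and PCA."""
import numpy as np
import pytest

from uasmap import gwas
from uasmap.synth import simulate_cohort

from conftest import geno_panel


class TestQCFilter:
    def test_maf_boundary_is_strict(self):
        # 10 samples = 20 alleles; 1 alt allele -> MAF 0.05 retained,
        # marker with zero alt alleles has MAF 0 -> removed
        d = np.zeros((10, 3))
        d[0, 0] = 1  # MAF 0.05 exactly
        d[:5, 1] = 1  # MAF 0.25
        filtered, report = gwas.qc_filter(geno_panel(d))
        assert list(filtered.markers["id"]) == ["m0", "m1"]
        assert report.removed_markers["id"].tolist() == ["m2"]

    def test_maf_just_below_boundary_removed(self):
        d = np.zeros((100, 2))
        d[:4, 0] = 1  # AF 0.02 < 0.05
        d[:50, 1] = 1
        filtered, _ = gwas.qc_filter(geno_panel(d))
        assert list(filtered.markers["id"]) == ["m1"]

    def test_sample_missingness_boundary_strict(self):
        d = np.ones((10, 10))
        d[:, 1] = [1, 1, 0, 0, 1, 1, 0, 0, 1, 1]
        d[0, 0] = np.nan  # 10% missing: retained ("> 0.1" is strict)
        d[1, 2:4] = np.nan  # 20% missing: removed
        panel = geno_panel(d)
        filtered, report = gwas.qc_filter(panel, maf_min=0.0)
        assert "dog001" in report.removed_samples["sample"].tolist()
        assert "dog000" not in report.removed_samples["sample"].tolist()

    def test_sample_removal_precedes_maf(self):
        # 11 samples, one alt het: MAF 1/22 < 0.05. The high-missingness
        # sample is removed first, lifting MAF to 1/20 = 0.05 -> retained.
        d = np.zeros((11, 10))
        d[0, 0] = 1
        d[10, 1:] = np.nan  # 90% missing, hom-ref at m0
        filtered, report = gwas.qc_filter(geno_panel(d))
        assert "m0" in filtered.markers["id"].tolist()
        assert report.removed_samples["sample"].tolist() == ["dog010"]

    def test_all_samples_removed_is_error(self):
        d = np.full((3, 4), np.nan)
        d[:, 0] = 1
        with pytest.raises(ValueError, match="every sample"):
            gwas.qc_filter(geno_panel(d), sample_missing_max=0.5)


class TestKinship:
    def test_identical_samples_share_diagonal_entry(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (6, 200)).astype(float)
        d[1] = d[0]
        k = gwas.kinship(geno_panel(d)).matrix
        assert k[0, 1] == pytest.approx(k[0, 0])
        assert k[0, 1] == pytest.approx(k[1, 1])

    def test_standardised_diagonal_near_one(self):
        rng = np.random.default_rng(1)
        af = rng.uniform(0.1, 0.9, 5000)
        d = rng.binomial(2, af, (200, 5000)).astype(float)
        k = gwas.kinship(geno_panel(d)).matrix
        assert 0.9 <= np.diag(k).mean() <= 1.1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, (12, 100)).astype(float)
        panel = geno_panel(d)
        k = gwas.kinship(panel).matrix
        perm = rng.permutation(12)
        k_perm = gwas.kinship(panel.subset(sample_idx=perm)).matrix
        assert np.allclose(k_perm, k[np.ix_(perm, perm)])

    def test_zero_variance_markers_excluded(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (10, 20)).astype(float)
        d[:, 4] = 2.0
        result = gwas.kinship(geno_panel(d))
        assert result.dropped_markers == ["m4"]
        assert result.n_markers_used == 19


class TestBonferroni:
    @pytest.mark.parametrize(
        "n, expected_mlog", [(105130, 6.32), (1, 1.30), (20, 2.60)]
    )
    def test_threshold_values(self, n, expected_mlog):
        p_thr, mlog = gwas.bonferroni_threshold(n, 0.05)
        assert mlog == expected_mlog
        assert p_thr == pytest.approx(0.05 / n)


def _ols_oracle(y, x, covs):
    """Independent OLS Wald p via statsmodels."""
    import statsmodels.api as sm

    design = np.column_stack([np.ones(len(y)), covs, x])
    fit = sm.OLS(y, design).fit()
    return fit.params[-1], fit.bse[-1], fit.pvalues[-1]


class TestLMMScan:
    def test_identity_kinship_collapses_to_ols(self):
        rng = np.random.default_rng(10)
        n, m = 100, 200
        d = rng.integers(0, 3, (n, m)).astype(float)
        covs = np.column_stack([rng.normal(size=n), rng.integers(0, 2, n)])
        y = rng.normal(size=n) + 0.3 * d[:, 5]
        panel = geno_panel(d)
        res = gwas.lmm_scan(panel, y, covs, np.eye(n)).table
        for j in [0, 5, 17, 100, 199]:
            beta, se, p = _ols_oracle(y, d[:, j], covs)
            assert res.loc[j, "beta"] == pytest.approx(beta, rel=1e-8)
            delta = abs(res.loc[j, "minus_log10_p"] - (-np.log10(p)))
            assert delta < 1e-6

    def test_perfect_signal_underflows_other_markers(self):
        rng = np.random.default_rng(11)
        n = 60
        d = rng.integers(0, 3, (n, 20)).astype(float)
        y = 2.0 + 1.5 * d[:, 7]  # exact linear function, zero noise
        res = gwas.lmm_scan(geno_panel(d), y, None, np.eye(n)).table
        top = res.loc[7, "minus_log10_p"]
        rest = res.drop(index=7)["minus_log10_p"].max()
        assert top - rest >= 10

    def test_null_type_one_error_calibrated(self):
        # structured null: polygenic liability over realised kinship,
        # zero causal effect, 2000 markers, one fixed seed
        from uasmap.phenotypes import total_airway_score
        from uasmap.synth import DiseaseModel

        cohort = simulate_cohort(
            n_dogs=300,
            n_markers=2000,
            seed=20250901,
            model=DiseaseModel(causal_marker_index=1000, beta=0.0, h2_polygenic=0.3),
        )
        panel, _ = gwas.qc_filter(cohort.genotypes)
        kin = gwas.kinship(panel)
        y = total_airway_score(cohort.phenotypes).to_numpy()
        covs = np.column_stack(
            [
                cohort.phenotypes["age_months"].to_numpy(float),
                (cohort.phenotypes["sex"] == "M").to_numpy(float),
            ]
        )
        res = gwas.lmm_scan(panel, y, covs, kin).table
        rate = float((res["p"] < 0.05).mean())
        assert 0.035 <= rate <= 0.065

    def test_mixed_model_beats_ols_under_confounded_null(self):
        # two subpopulations with shifted phenotype means and drifted
        # allele frequencies: kinship correction should pull the genomic
        # inflation factor toward 1 in nearly every replicate
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n_half, m = 100, 300
            af1 = rng.uniform(0.1, 0.9, m)
            af2 = np.clip(af1 + rng.normal(0, 0.18, m), 0.02, 0.98)
            d = np.vstack(
                [
                    rng.binomial(2, af1, (n_half, m)),
                    rng.binomial(2, af2, (n_half, m)),
                ]
            ).astype(float)
            y = np.concatenate(
                [rng.normal(0, 1, n_half), rng.normal(1.0, 1, n_half)]
            )
            panel = geno_panel(d)
            kin = gwas.kinship(panel)
            lmm_p = gwas.lmm_scan(panel, y, None, kin).table["p"]
            ols_p = gwas.ols_scan(panel, y).table["p"]
            lam_lmm = gwas.genomic_inflation(lmm_p)
            lam_ols = gwas.genomic_inflation(ols_p)
            if abs(lam_lmm - 1) < abs(lam_ols - 1):
                wins += 1
        assert wins >= 18

    def test_ml_criterion_also_collapses_to_ols_at_identity(self):
        rng = np.random.default_rng(22)
        n, m = 50, 30
        d = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(size=n)
        panel = geno_panel(d)
        reml = gwas.lmm_scan(panel, y, None, np.eye(n), criterion="reml").table
        ml = gwas.lmm_scan(panel, y, None, np.eye(n), criterion="ml").table
        assert np.allclose(reml["minus_log10_p"], ml["minus_log10_p"], atol=1e-8)

    def test_pvalues_monotone_in_wald_statistic(self):
        rng = np.random.default_rng(12)
        n = 80
        d = rng.integers(0, 3, (n, 50)).astype(float)
        y = rng.normal(size=n)
        res = gwas.lmm_scan(geno_panel(d), y, None, np.eye(n)).table
        order = res["wald"].abs().sort_values().index
        p_sorted = res.loc[order, "p"].to_numpy()
        assert (np.diff(p_sorted) <= 1e-12).all()

    def test_singular_covariates_rejected(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, (30, 10)).astype(float)
        covs = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="singular"):
            gwas.lmm_scan(geno_panel(d), rng.normal(size=30), covs, np.eye(30))

    def test_asymmetric_kinship_rejected(self):
        rng = np.random.default_rng(14)
        d = rng.integers(0, 3, (10, 5)).astype(float)
        k = np.eye(10)
        k[0, 1] = 0.3
        with pytest.raises(ValueError, match="symmetric"):
            gwas.lmm_scan(geno_panel(d), rng.normal(size=10), None, k)


class TestLD:
    def test_self_and_flipped_r2_are_one(self):
        rng = np.random.default_rng(15)
        d = rng.integers(0, 3, (50, 5)).astype(float)
        d[:, 1] = 2 - d[:, 0]
        ld = gwas.ld_r2(geno_panel(d), ["m0"], window=4)
        by_marker = ld.set_index("marker_id")["r2"]
        assert by_marker["m0"] == pytest.approx(1.0)
        assert by_marker["m1"] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(16)
        d = rng.integers(0, 3, (40, 10)).astype(float)
        panel = geno_panel(d)
        ld = gwas.ld_r2(panel, ["m2", "m7"], window=10)
        ab = ld.query("index_id == 'm2' and marker_id == 'm7'")["r2"].iloc[0]
        ba = ld.query("index_id == 'm7' and marker_id == 'm2'")["r2"].iloc[0]
        assert ab == ba

    def test_independent_markers_rarely_exceed_low_r2(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            d = rng.binomial(2, 0.5, (500, 2)).astype(float)
            ld = gwas.ld_r2(geno_panel(d), ["m0"], window=1)
            r2 = ld.set_index("marker_id").loc["m1", "r2"]
            if r2 < 0.05:
                hits += 1
        assert hits >= 95

    def test_zero_variance_flagged_nan(self):
        d = np.ones((20, 2))
        d[:, 1] = [0, 1] * 10
        ld = gwas.ld_r2(geno_panel(d), ["m1"], window=1)
        assert np.isnan(ld.set_index("marker_id").loc["m0", "r2"])


class TestPCA:
    def test_two_clusters_separated_by_pc1(self):
        rng = np.random.default_rng(17)
        a = rng.integers(0, 3, 50).astype(float)
        b = rng.integers(0, 3, 50).astype(float)
        d = np.vstack([np.tile(a, (10, 1)), np.tile(b, (10, 1))])
        scores, _ = gwas.genotype_pca(geno_panel(d))
        pc1 = scores[:, 0]
        assert (pc1[:10].max() < pc1[10:].min()) or (pc1[:10].min() > pc1[10:].max())

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(18)
        d = rng.integers(0, 3, (30, 80)).astype(float)
        _, explained = gwas.genotype_pca(geno_panel(d))
        assert (np.diff(explained) <= 1e-12).all()

    def test_scores_match_full_decomposition_oracle(self):
        rng = np.random.default_rng(19)
        d = rng.integers(0, 3, (20, 50)).astype(float)
        scores, explained = gwas.genotype_pca(geno_panel(d), n_components=20)
        centred = d - d.mean(axis=0)
        sv_oracle = np.linalg.svd(centred, compute_uv=False)
        norms = np.linalg.norm(scores, axis=0)
        assert np.allclose(norms, sv_oracle[: len(norms)], atol=1e-8)
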