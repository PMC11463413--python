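import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hdmediation import (
    HighDimensionalMediation,
    KernelMatrix,
    fit_hdma,
    linear_kernel,
    marker_set_test,
    normalize_features,
    partial_correlation,
    path_coefficient,
    variable_loadings,
    variance_explained,
)
from hdmediation.mediation import LoadingVector
from hdmediation.simulate import SimulationConfig, simulate_dataset

from conftest import make_omics


def random_kernel(rng, n, m=40, modality="k"):
    X = rng.standard_normal((n, m))
    return linear_kernel(make_omics(X, name=modality), modality=modality)


class TestPathCoefficient:
    def test_identical_vectors_give_one(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert path_coefficient(v, v, v) == pytest.approx(1.0)

    def test_anticorrelated_phenome_gives_minus_one(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert path_coefficient(v, v, -v) == pytest.approx(-1.0)

    def test_hand_worked_quadruple(self):
        # corr((1,2,3,4),(1,3,2,4)) = 0.8 and corr((1,3,2,4),(2,1,4,3)) = 0
        g = [1.0, 2.0, 3.0, 4.0]
        t = [1.0, 3.0, 2.0, 4.0]
        p = [2.0, 1.0, 4.0, 3.0]
        assert stats.pearsonr(g, t).statistic == pytest.approx(0.8)
        assert path_coefficient(g, t, p) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            path_coefficient([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_orthogonal_confounder_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        z = rng.standard_normal(30)
        z -= z.mean()
        for v in (x, y):
            v -= (v @ z / (z @ z)) * z
        assert partial_correlation(x, y, z) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-10
        )

    def test_degenerate_x_in_span_rejected(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="span"):
            partial_correlation(2 * z, np.array([1.0, 3.0, 2.0, 4.0]), z)

    def test_hand_worked_quadruple(self):
        # residual-regression oracle gives exactly -2/3
        x = np.array([1.0, 2.0, 4.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        z = np.array([1.0, 2.0, 3.0, 4.0])
        Z = np.column_stack([np.ones(4), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        oracle = rx @ ry / np.sqrt((rx @ rx) * (ry @ ry))
        assert oracle == pytest.approx(-2.0 / 3.0)
        assert partial_correlation(x, y, z) == pytest.approx(-2.0 / 3.0, abs=1e-12)


class TestFitHdma:
    def test_noiseless_mediation_chain_saturates_path(self):
        # latent genetic signal fully determines transcripts, which fully
        # determine the phenome
        rng = np.random.default_rng(1)
        G = rng.standard_normal((60, 20))
        T = G @ rng.standard_normal((20, 15))
        P = T @ rng.standard_normal((15, 5))
        fit = fit_hdma(
            linear_kernel(make_omics(G), "genome"),
            linear_kernel(make_omics(T), "transcriptome"),
            linear_kernel(make_omics(P), "phenome"),
        )
        assert fit.path_coefficient >= 0.99

    def test_mediation_constraint_exact_on_arbitrary_kernels(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            fit = fit_hdma(
                random_kernel(rng, 50, modality="genome"),
                random_kernel(rng, 50, modality="transcriptome"),
                random_kernel(rng, 50, modality="phenome"),
            )
            assert abs(fit.rho_gp_given_t) <= 1e-8
            assert fit.G_C.mean() == pytest.approx(0.0, abs=1e-10)
            assert fit.G_C.std() == pytest.approx(1.0, abs=1e-9)
            assert fit.rho_tp >= 0

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(3)
        K_G = random_kernel(rng, 40, modality="genome")
        K_T = random_kernel(rng, 40, modality="transcriptome")
        K_P = random_kernel(rng, 40, modality="phenome")
        f1 = fit_hdma(K_G, K_T, K_P, seed=5)
        f2 = fit_hdma(K_G, K_T, K_P, seed=5)
        np.testing.assert_array_equal(f1.T_C, f2.T_C)
        np.testing.assert_array_equal(f1.G_C, f2.G_C)
        np.testing.assert_array_equal(f1.P_C, f2.P_C)

    def test_single_perfect_transcript_recovered_at_full_rank(self):
        rng = np.random.default_rng(4)
        n = 50
        G = rng.standard_normal((n, 10))
        t_true = G @ rng.standard_normal(10)
        T = np.column_stack([t_true])
        P = np.column_stack([t_true + 0.1 * rng.standard_normal(n)])
        fit = fit_hdma(
            linear_kernel(make_omics(G), "genome"),
            linear_kernel(make_omics(T), "transcriptome"),
            linear_kernel(make_omics(P), "phenome"),
            rank=n - 1,
        )
        assert abs(np.corrcoef(fit.T_C, t_true)[0, 1]) >= 0.99

    def test_mismatched_individuals_rejected(self):
        rng = np.random.default_rng(5)
        K1 = random_kernel(rng, 30)
        K2 = random_kernel(rng, 30)
        K3 = KernelMatrix(individual_ids=[f"x{i}" for i in range(30)], K=K2.K)
        with pytest.raises(ValueError, match="same individuals"):
            fit_hdma(K1, K2, K3)

    def test_path_increases_with_planted_mediation_strength(self):
        # median fitted path over replicates is monotone in the mediated
        # share of trait variance (5-point noise grid)
        grid = [4.0, 2.0, 1.0, 0.5, 0.25]
        medians = []
        for noise in grid:
            paths = []
            for rep in range(8):
                cfg = SimulationConfig(
                    n_individuals=80, n_markers=100, n_transcripts=80,
                    n_core_transcripts=10, phenotype_noise_sd=noise,
                    n_traits=5, seed=1000 + rep,
                )
                dos, expr, pheno, _ = simulate_dataset(cfg)
                model = HighDimensionalMediation(random_state=rep).fit(
                    dos, normalize_features(expr), normalize_features(pheno)
                )
                paths.append(model.path_coefficient_)
            medians.append(np.median(paths))
        assert all(b >= a - 1e-6 for a, b in zip(medians, medians[1:]))


class TestLoadings:
    def test_feature_equal_and_opposite_to_score(self):
        rng = np.random.default_rng(6)
        s = rng.standard_normal(40)
        s = (s - s.mean()) / s.std()
        X = np.column_stack([s, -s, rng.standard_normal(40)])
        lv = variable_loadings(make_omics(X), s)
        assert lv.loadings.iloc[0] == pytest.approx(1.0)
        assert lv.loadings.iloc[1] == pytest.approx(-1.0)

    def test_orthogonal_features_have_null_scale_loadings(self):
        rng = np.random.default_rng(7)
        n = 100
        s = rng.standard_normal(n)
        s = (s - s.mean()) / s.std()
        X = rng.standard_normal((n, 100))
        lv = variable_loadings(make_omics(X), s)
        assert np.abs(lv.loadings).mean() <= 2 / np.sqrt(n)

    def test_constant_feature_flagged_with_zero_loading(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        lv = variable_loadings(make_omics(X), (s - s.mean()) / s.std())
        assert lv.table["constant"].iloc[0]
        assert lv.loadings.iloc[0] == 0.0

    def test_z_loadings_standardized_within_tissue(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(30)
        values = pd.DataFrame(
            rng.standard_normal((30, 6)),
            index=[f"i{k}" for k in range(30)],
            columns=[f"adipose:g{j}" for j in range(3)] + [f"liver:g{j}" for j in range(3)],
        )
        from hdmediation import OmicsMatrix

        lv = variable_loadings(OmicsMatrix(values=values), (s - s.mean()) / s.std())
        for tissue in ("adipose", "liver"):
            z = lv.table[lv.table["tissue"] == tissue]["z_loading"]
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestVarianceExplained:
    def test_single_matching_trait(self):
        rng = np.random.default_rng(10)
        s = rng.standard_normal(25)
        assert variance_explained(s, make_omics(s[:, None])) == pytest.approx(1.0)

    def test_mixture_of_perfect_and_half_correlated(self):
        rng = np.random.default_rng(11)
        n = 200
        s = rng.standard_normal(n)
        u = rng.standard_normal(n)
        s_c = (s - s.mean()) / s.std()
        u_c = u - u.mean()
        u_c -= (u_c @ s_c / (s_c @ s_c)) * s_c
        u_c /= u_c.std()
        t2 = 0.5 * s_c + np.sqrt(1 - 0.25) * u_c  # corr exactly 0.5 in-sample
        out = variance_explained(s_c, make_omics(np.column_stack([s_c, t2])))
        assert out == pytest.approx(0.625, abs=1e-10)


class TestMarkerSetTest:
    @staticmethod
    def _loadings(values, ids=None):
        ids = ids or [f"g{j}" for j in range(len(values))]
        table = pd.DataFrame(
            {"tissue": "all", "loading": values, "constant": False,
             "z_loading": stats.zscore(values)},
            index=pd.Index(ids, name="feature_id"),
        )
        return LoadingVector(table=table)

    def test_full_feature_set_gives_p_one(self):
        rng = np.random.default_rng(12)
        lv = self._loadings(rng.standard_normal(50))
        _, p = marker_set_test(lv, lv.feature_ids, n_perm=199, seed=0)
        assert p == 1.0

    def test_strongly_shifted_set_attains_minimum_p(self):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal(500) * 0.1
        vals[:20] += 3.0
        lv = self._loadings(vals)
        obs, p = marker_set_test(lv, lv.feature_ids[:20], n_perm=999, seed=0)
        assert obs > 2.5
        assert p == pytest.approx(1 / 1000)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(14)
        pvals = []
        for rep in range(200):
            vals = rng.standard_normal(80)
            lv = self._loadings(vals)
            ids = list(rng.choice(lv.feature_ids, size=10, replace=False))
            _, p = marker_set_test(lv, ids, n_perm=99, seed=rep)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_set_rejected(self):
        lv = self._loadings(np.arange(10.0))
        with pytest.raises(ValueError, match="empty"):
            marker_set_test(lv, [], n_perm=99)


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        model = HighDimensionalMediation(rank=12, tol=1e-6)
        assert model.get_params()["rank"] == 12
        model.set_params(max_iter=100)
        assert model.max_iter == 100

    def test_fit_exposes_scores_loadings_and_anchor(self, small_dataset):
        model = HighDimensionalMediation(random_state=0).fit(
            small_dataset["dosages"],
            small_dataset["expression_norm"],
            small_dataset["phenotypes_norm"],
        )
        assert set(model.scores_.columns) == {"G_C", "T_C", "P_C"}
        assert abs(model.rho_gp_given_t_) <= 1e-8
        assert 0 <= model.variance_explained_ <= 1
        # anchor convention: the trait with the largest |loading| is positive
        top = model.trait_loadings_.loadings.abs().idxmax()
        assert model.trait_loadings_.loadings.loc[top] > 0
        assert model.rho_tp_ >= 0
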