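import numpy as np
import pandas as pd
import pytest
from scipy.linalg import cho_factor, cho_solve, helmert

from hdmediation import (
    OmicsMatrix,
    fit_two_component,
    relevance_heritability_correlation,
    split_kinship,
    trait_relevance,
)
from hdmediation.heritability import TwoComponentHeritability
from hdmediation.kernels import _kernel_from_array
from hdmediation.simulate import SimulationConfig, simulate_mosaic_genomes

from conftest import make_dosages, make_omics


class TestSplitKinship:
    MARKERS = [("1", 45_000_000), ("1", 55_000_000), ("1", 70_000_000), ("2", 10_000_000)]

    def test_window_membership(self):
        rng = np.random.default_rng(0)
        dos = make_dosages(20, self.MARKERS, rng)
        K_local, _ = split_kinship(dos, ("1", 50_000_000), window_bp=10_000_000)
        manual = _kernel_from_array(dos.unfold(marker_idx=np.array([0, 1])),
                                    dos.individual_ids, "local")
        np.testing.assert_allclose(K_local.K, manual.K, atol=1e-12)

    def test_marker_sets_partition(self):
        rng = np.random.default_rng(1)
        dos = make_dosages(20, self.MARKERS, rng)
        local_idx = dos.marker_indices("1", 40_000_000, 60_000_000)
        distal_idx = np.setdiff1d(np.arange(4), local_idx)
        assert sorted(local_idx) == [0, 1]
        assert sorted(distal_idx) == [2, 3]

    def test_distal_matches_brute_force_complement(self):
        rng = np.random.default_rng(2)
        dos = make_dosages(20, self.MARKERS, rng)
        _, K_distal = split_kinship(dos, ("1", 50_000_000), window_bp=10_000_000)
        manual = _kernel_from_array(dos.unfold(marker_idx=np.array([2, 3])),
                                    dos.individual_ids, "distal")
        np.testing.assert_allclose(K_distal.K, manual.K, atol=1e-12)

    def test_empty_window_rejected(self):
        rng = np.random.default_rng(3)
        dos = make_dosages(10, self.MARKERS, rng)
        with pytest.raises(ValueError, match="no markers"):
            split_kinship(dos, ("2", 90_000_000), window_bp=1_000_000)


def _sim_kernels(n=200, seed=0, n_markers=200):
    cfg = SimulationConfig(n_individuals=n, n_markers=n_markers, n_transcripts=10,
                           n_core_transcripts=2, seed=seed)
    dos = simulate_mosaic_genomes(cfg)
    return split_kinship(dos, ("1", 50_000_000), window_bp=10_000_000)


def _draw_from_kernel(rng, K):
    w, U = np.linalg.eigh(K)
    g = U @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(len(w)))
    return g / g.std()


class TestTwoComponentREML:
    def test_agrees_with_dense_grid_oracle(self):
        # full 0.01-step simplex evaluation of the restricted likelihood,
        # written independently, must agree within one grid step
        rng = np.random.default_rng(4)
        Kl, Kd = _sim_kernels(n=50, seed=5, n_markers=100)
        Klk = Kl.K / np.mean(np.diag(Kl.K))
        Kdk = Kd.K / np.mean(np.diag(Kd.K))
        y = (0.6 * _draw_from_kernel(rng, Klk) + 0.2 * _draw_from_kernel(rng, Kdk)
             + 0.6 * rng.standard_normal(50))

        model = TwoComponentHeritability(rint=False).fit(y, Kl, Kd)

        L = helmert(50).T
        yt = L.T @ y
        Klt, Kdt = L.T @ Klk @ L, L.T @ Kdk @ L
        m = 49

        def oracle_nll(hl, hd):
            V = hl * Klt + hd * Kdt + (1 - hl - hd) * np.eye(m)
            try:
                c = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                return np.inf
            q = yt @ cho_solve(c, yt)
            return 0.5 * (m * np.log(2 * np.pi * q / m) + 2 * np.sum(np.log(np.diag(c[0]))) + m)

        best, arg = np.inf, None
        for hl in np.arange(0, 1.0001, 0.01):
            for hd in np.arange(0, 1.0001 - hl, 0.01):
                v = oracle_nll(hl, hd)
                if v < best:
                    best, arg = v, (hl, hd)
        assert model.h2_local_ == pytest.approx(arg[0], abs=0.0101)
        assert model.h2_distal_ == pytest.approx(arg[1], abs=0.0101)
        assert -model.loglik_ <= best + 1e-6

    def test_invariant_to_scaling_of_y(self):
        rng = np.random.default_rng(6)
        Kl, Kd = _sim_kernels(n=80, seed=6, n_markers=120)
        y = rng.standard_normal(80) + _draw_from_kernel(rng, Kd.K)
        e1 = fit_two_component(y, Kl, Kd)
        e2 = fit_two_component(7.3 * y + 2.0, Kl, Kd)
        assert e1.h2_local == pytest.approx(e2.h2_local, abs=1e-12)
        assert e1.h2_distal == pytest.approx(e2.h2_distal, abs=1e-12)

    def test_identical_kinships_flagged_non_identifiable(self):
        rng = np.random.default_rng(7)
        Kl, _ = _sim_kernels(n=60, seed=7, n_markers=100)
        y = _draw_from_kernel(rng, Kl.K) * 0.8 + 0.6 * rng.standard_normal(60)
        est = fit_two_component(y, Kl, Kl)
        assert est.boundary_flag == "non_identifiable"
        assert est.h2_local == pytest.approx(est.h2_distal)

    def test_constant_y_rejected(self):
        Kl, Kd = _sim_kernels(n=30, seed=8, n_markers=60)
        with pytest.raises(ValueError, match="constant"):
            fit_two_component(np.ones(30), Kl, Kd)

    def test_pure_noise_gives_near_zero_components(self):
        rng = np.random.default_rng(9)
        Kl, Kd = _sim_kernels(n=200, seed=9)
        hl, hd = [], []
        for _ in range(15):
            est = fit_two_component(rng.standard_normal(200), Kl, Kd)
            hl.append(est.h2_local)
            hd.append(est.h2_distal)
        assert np.mean(hl) <= 0.05
        assert np.mean(hd) <= 0.05

    def test_zero_distal_simulations_keep_distal_near_zero(self):
        rng = np.random.default_rng(10)
        Kl, Kd = _sim_kernels(n=200, seed=10)
        Klk = Kl.K / np.mean(np.diag(Kl.K))
        hd = []
        for _ in range(12):
            y = np.sqrt(0.5) * _draw_from_kernel(rng, Klk) + np.sqrt(0.5) * rng.standard_normal(200)
            hd.append(fit_two_component(y, Kl, Kd).h2_distal)
        assert np.median(hd) <= 0.05

    def test_total_heritability_ordering_detected(self):
        rng = np.random.default_rng(11)
        Kl, Kd = _sim_kernels(n=150, seed=11)
        Kdk = Kd.K / np.mean(np.diag(Kd.K))
        totals_null, totals_strong = [], []
        for _ in range(8):
            y0 = rng.standard_normal(150)
            y1 = np.sqrt(0.8) * _draw_from_kernel(rng, Kdk) + np.sqrt(0.2) * rng.standard_normal(150)
            e0 = fit_two_component(y0, Kl, Kd)
            e1 = fit_two_component(y1, Kl, Kd)
            totals_null.append(e0.h2_local + e0.h2_distal)
            totals_strong.append(e1.h2_local + e1.h2_distal)
        assert np.mean(totals_strong) > np.mean(totals_null)


class TestTraitRelevance:
    def test_transcript_equal_to_trait(self):
        rng = np.random.default_rng(12)
        t = rng.standard_normal(30)
        expr = make_omics(t[:, None], prefix="g")
        traits = make_omics(np.column_stack([t, rng.standard_normal(30)]), prefix="trait")
        assert trait_relevance(expr, traits).iloc[0] == pytest.approx(1.0)

    def test_maximum_of_absolute_correlations(self):
        # construct exact in-sample correlations 0.3 and -0.8
        rng = np.random.default_rng(13)
        n = 100
        u = rng.standard_normal(n)
        u = (u - u.mean()) / u.std()
        v = rng.standard_normal(n)
        v -= v.mean()
        v -= (v @ u / (u @ u)) * u
        v /= v.std()
        t1 = 0.3 * u + np.sqrt(1 - 0.09) * v
        t2 = -0.8 * u + 0.6 * v
        rel = trait_relevance(make_omics(u[:, None], prefix="g"),
                              make_omics(np.column_stack([t1, t2]), prefix="trait"))
        assert rel.iloc[0] == pytest.approx(0.8, abs=1e-10)

    def test_constant_transcript_flagged_zero(self):
        rng = np.random.default_rng(14)
        expr = make_omics(np.column_stack([np.ones(20), rng.standard_normal(20)]), prefix="g")
        traits = make_omics(rng.standard_normal((20, 3)), prefix="trait")
        with pytest.warns(UserWarning, match="constant"):
            rel = trait_relevance(expr, traits)
        assert rel.iloc[0] == 0.0

    def test_null_relevance_matches_direct_simulation(self):
        # mean over independent transcripts of max |corr| across 10 traits,
        # compared with a fresh Monte-Carlo estimate of the same functional
        rng = np.random.default_rng(15)
        n, n_traits = 200, 10
        traits = make_omics(rng.standard_normal((n, n_traits)), prefix="trait")
        expr = make_omics(rng.standard_normal((n, 300)), prefix="g")
        observed = trait_relevance(expr, traits).mean()
        mc = []
        for _ in range(300):
            x = rng.standard_normal(n)
            mc.append(max(abs(np.corrcoef(x, traits.array[:, j])[0, 1])
                          for j in range(n_traits)))
        assert observed == pytest.approx(np.mean(mc), abs=0.02)


class TestRelevanceCorrelation:
    @staticmethod
    def _table(h2_local, h2_distal, relevance):
        return pd.DataFrame(
            {"h2_local": h2_local, "h2_distal": h2_distal, "trait_relevance": relevance}
        )

    def test_identical_vectors_give_r_one(self):
        v = np.linspace(0.05, 0.9, 20)
        r, p = relevance_heritability_correlation(self._table(v, v[::-1], v), "local")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_shuffled_h2_uncorrelated_on_average(self):
        rng = np.random.default_rng(16)
        n = 100
        rs = []
        for _ in range(50):
            rel = rng.uniform(0, 1, n)
            h2 = rng.permutation(rel)
            r, _ = relevance_heritability_correlation(self._table(h2, h2, rel), "distal")
            rs.append(abs(r))
        assert np.mean(rs) <= 2 / np.sqrt(n)

    def test_too_few_transcripts_rejected(self):
        v = np.linspace(0.1, 0.9, 5)
        with pytest.raises(ValueError, match="10"):
            relevance_heritability_correlation(self._table(v, v, v), "local")
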