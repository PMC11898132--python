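import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as st

import parityrrm as prm
from parityrrm import _kernels as K
from parityrrm.gibbs import GibbsConfig, GibbsSampler, sample_invwishart


class TestTruncatedNormal:
    def test_inverse_cdf_matches_scipy(self):
        from scipy.special import ndtri as scipy_ndtri

        ps = np.concatenate(
            [np.linspace(1e-12, 1 - 1e-12, 2001), [1e-300, 1 - 1e-16]]
        )
        ours = np.array([K.ndtri(p) for p in ps])
        np.testing.assert_allclose(ours, scipy_ndtri(ps), atol=1e-13)

    def test_half_normal_mean(self, rng):
        u = rng.random(100_000)
        draws = np.array(
            [K.sample_truncnorm(0.0, 1.0, 0.0, np.inf, ui) for ui in u]
        )
        # E[X | X > 0] = sqrt(2/pi) = 0.7979
        assert draws.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_bounds_always_respected(self, rng):
        u = rng.random(2000)
        for lo, hi in [(-np.inf, 0.0), (0.0, 1.0), (1.0, np.inf)]:
            draws = np.array(
                [K.sample_truncnorm(0.3, 0.8, lo, hi, ui) for ui in u]
            )
            assert (draws >= lo).all() and (draws <= hi).all()

    def test_extreme_tail_does_not_hang_or_escape(self):
        # interval with negligible mass: pinned to the nearest bound
        val = K.sample_truncnorm(0.0, 1.0, 40.0, 41.0, 0.5)
        assert 40.0 <= val <= 41.0


class TestInverseWishart:
    def test_moments_match_scipy(self, rng):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        df = 10
        draws = np.stack(
            [sample_invwishart(rng, df, S) for _ in range(20_000)]
        )
        np.testing.assert_allclose(
            draws.mean(axis=0), st.invwishart(df, S).mean(), rtol=0.05
        )

    def test_always_positive_definite(self, rng):
        S = np.array([[0.5, 0.1], [0.1, 0.2]])
        for _ in range(200):
            draw = sample_invwishart(rng, 5, S)
            np.linalg.cholesky(draw)  # raises if not PD


def _toy_model(order=1, n_ewes=30, seed=5):
    scen = prm.line_scenario("conventional", n_ewes=n_ewes, seed=seed)
    ds = prm.simulate_dataset(scen)
    return ds, prm.ThresholdRRM(
        ds.records, ds.pedigree.to_dataframe(), "conventional", order=order
    )


class TestChainMechanics:
    def test_retained_draw_count(self, small_dataset):
        ds = small_dataset
        m = prm.ThresholdRRM(
            ds.records, ds.pedigree.to_dataframe(), "conventional", order=1
        )
        res = m.fit(n_iter=1000, burn_in=200, thin=10, seed=3)
        assert len(res.chain) == 80
        assert res.chain.iterations[0] == 210
        assert res.chain.iterations[-1] == 1000

    def test_same_seed_identical_chains(self, small_dataset):
        ds = small_dataset
        m = prm.ThresholdRRM(
            ds.records, ds.pedigree.to_dataframe(), "conventional", order=1
        )
        r1 = m.fit(n_iter=400, burn_in=100, thin=5, seed=9)
        r2 = m.fit(n_iter=400, burn_in=100, thin=5, seed=9)
        np.testing.assert_array_equal(r1.chain.G, r2.chain.G)
        np.testing.assert_array_equal(r1.chain.P, r2.chain.P)
        np.testing.assert_array_equal(r1.chain.sigma2_e, r2.chain.sigma2_e)

    def test_liabilities_respect_category_intervals(self, small_dataset):
        ds = small_dataset
        m = prm.ThresholdRRM(
            ds.records, ds.pedigree.to_dataframe(), "conventional", order=1
        )
        cfg = GibbsConfig(n_iter=50, burn_in=10, thin=1, seed=1)
        s = GibbsSampler(
            m.design, m.records.category, 2, m.a_inverse, cfg
        )
        for _ in range(30):
            s.sweep()
            cat1 = m.records.category == 1
            assert (s.liab[cat1] < 0).all()
            assert (s.liab[~cat1] > 0).all()

    def test_binary_residuals_stay_anchored(self, small_dataset):
        ds = small_dataset
        m = prm.ThresholdRRM(
            ds.records, ds.pedigree.to_dataframe(), "conventional", order=1
        )
        res = m.fit(n_iter=300, burn_in=100, thin=2, seed=4)
        np.testing.assert_array_equal(
            res.chain.sigma2_e, np.ones_like(res.chain.sigma2_e)
        )

    def test_three_category_middle_liability_in_unit_window(self):
        scen = prm.line_scenario("prolific", n_ewes=80, seed=6)
        ds = prm.simulate_dataset(scen)
        m = prm.ThresholdRRM(
            ds.records, ds.pedigree.to_dataframe(), "prolific", order=1
        )
        cfg = GibbsConfig(n_iter=50, burn_in=10, thin=1, seed=1)
        s = GibbsSampler(m.design, m.records.category, 3, m.a_inverse, cfg)
        for _ in range(20):
            s.sweep()
        mid = m.records.category == 2
        if mid.any():
            assert ((s.liab[mid] > 0) & (s.liab[mid] < 1)).all()

    def test_checkpoint_resume_is_exact(self, tmp_path, small_dataset):
        ds = small_dataset
        m = prm.ThresholdRRM(
            ds.records, ds.pedigree.to_dataframe(), "conventional", order=1
        )
        full = m.fit(n_iter=600, burn_in=100, thin=5, seed=12)
        ck = tmp_path / "ck.npz"
        # interrupted run: checkpoint at iteration 300, then resume
        m.fit(n_iter=300, burn_in=100, thin=5, seed=12,
              checkpoint_every=300, checkpoint_path=ck)
        resumed = m.fit(n_iter=600, burn_in=100, thin=5, seed=12,
                        resume_from=ck)
        np.testing.assert_array_equal(full.chain.G, resumed.chain.G)
        np.testing.assert_array_equal(
            full.chain.sigma2_e, resumed.chain.sigma2_e
        )
        np.testing.assert_array_equal(
            full.chain.deviance, resumed.chain.deviance
        )


class TestLocationAgainstMME:
    def test_chain_mean_matches_direct_solve(self, rng):
        """Gaussian response, fixed variances: the Gibbs average of
        (b, a, p) must match the sparse mixed-model-equations solution
        within Monte-Carlo error."""
        ds, m = _toy_model(order=1, n_ewes=30, seed=5)
        des = m.design
        y = rng.standard_normal(len(m.records)) * 0.5 + 1.0
        G = np.array([[0.5, 0.1], [0.1, 0.3]])
        P = np.array([[0.4, 0.0], [0.0, 0.2]])
        sig = np.array([1.0, 0.8, 1.2])
        cfg = GibbsConfig(n_iter=10, burn_in=1, thin=1, seed=7,
                          prior="flat", updates=("location",))
        s = GibbsSampler(des, m.records.category, 0, m.a_inverse, cfg,
                         observed_liability=y)
        s.G, s.P, s.sigma2_e = G, P, sig
        n_keep, n_burn = 12_000, 2_000
        a_draws = np.empty((n_keep, *s.a.shape))
        p_draws = np.empty((n_keep, *s.p.shape))
        fit_draws = np.empty((n_keep, des.X.shape[0]))
        for it in range(n_burn + n_keep):
            s.sweep()
            if it >= n_burn:
                k = it - n_burn
                a_draws[k] = s.a
                p_draws[k] = s.p
                fit_draws[k] = des.X @ np.concatenate(
                    [s.year_eff, s.month_eff, s.beta]
                )

        X, Z, W = des.X, des.Z, des.W
        Rinv = sp.diags(1.0 / sig[des.residual_class - 1])
        GA = sp.kron(m.a_inverse, np.linalg.inv(G))
        PI = sp.kron(sp.eye(des.n_ewes), np.linalg.inv(P))
        M = sp.bmat(
            [
                [X.T @ Rinv @ X, X.T @ Rinv @ Z, X.T @ Rinv @ W],
                [Z.T @ Rinv @ X, Z.T @ Rinv @ Z + GA, Z.T @ Rinv @ W],
                [W.T @ Rinv @ X, W.T @ Rinv @ Z, W.T @ Rinv @ W + PI],
            ]
        ).tocsc()
        rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y,
                              W.T @ Rinv @ y])
        sol = sp.linalg.lsqr(M, rhs, atol=1e-13, btol=1e-13,
                             iter_lim=50_000)[0]
        nf = des.n_fixed
        na = des.n_animals * des.n_coef
        a_mme = sol[nf:nf + na].reshape(-1, des.n_coef)
        p_mme = sol[nf + na:].reshape(-1, des.n_coef)

        def mc_se(draws):
            # batch-means standard error of the chain average
            nb = 40
            batches = draws[: (len(draws) // nb) * nb].reshape(
                nb, -1, *draws.shape[1:]
            ).mean(axis=1)
            return batches.std(axis=0, ddof=1) / np.sqrt(nb)

        for chain_draws, target in [
            (a_draws, a_mme), (p_draws, p_mme),
            (fit_draws, X @ sol[:nf]),
        ]:
            diff = np.abs(chain_draws.mean(axis=0) - target)
            tol = 3 * mc_se(chain_draws) + 1e-6
            assert (diff <= tol).mean() > 0.95  # 3-SE bound, allow ~5% slack

    def test_intercept_posterior_mean_is_data_mean(self, rng):
        """Single intercept, known liabilities, unit residual: the
        posterior mean of the overall level equals mean(l). The level is
        split between the single year dummy and the raw regression
        intercept of the repeatability design; their sum is identified."""
        ped = prm.Pedigree.from_dataframe(
            pd.DataFrame({"animal": ["e1", "e2"], "sire": ["0", "0"],
                          "dam": ["0", "0"], "sex": ["F", "F"]})
        )
        recs = pd.DataFrame(
            {"ewe": ["e1"] * 5 + ["e2"] * 5, "year": [2000] * 10,
             "month": ["Sep"] * 10, "parity": [1, 2, 3, 4, 5] * 2,
             "litter_size": [1] * 10}
        )
        m = prm.ThresholdRRM(recs, ped.to_dataframe(), "conventional",
                             model="repeatability")
        y = rng.standard_normal(10) + 1.7
        cfg = GibbsConfig(n_iter=10, burn_in=1, thin=1, seed=3,
                          prior="flat", updates=("location",))
        s = GibbsSampler(m.design, m.records.category, 0, m.a_inverse, cfg,
                         observed_liability=y)
        s.G = np.array([[1e-10]])
        s.P = np.array([[1e-10]])
        levels = []
        for it in range(6000):
            s.sweep()
            if it >= 1000:
                levels.append(s.year_eff[0] + s.beta[0])
        se = np.std(levels) / np.sqrt(len(levels) / 20)  # crude ESS deflate
        assert np.mean(levels) == pytest.approx(y.mean(), abs=3 * se + 0.02)

    def test_vanishing_shrinkage_limit(self, rng):
        """With an enormous genetic variance the animal effect for a
        recorded ewe approaches the within-ewe mean of the centred data
        (no shrinkage), here with fixed effects and PE switched off."""
        ped = prm.Pedigree.from_dataframe(
            pd.DataFrame({"animal": ["e1", "e2"], "sire": ["0", "0"],
                          "dam": ["0", "0"], "sex": ["F", "F"]})
        )
        recs = pd.DataFrame(
            {"ewe": ["e1"] * 6 + ["e2"] * 6, "year": [2000] * 12,
             "month": ["Sep"] * 12, "parity": [1, 2, 3, 4, 5, 6] * 2,
             "litter_size": [1] * 12}
        )
        m = prm.ThresholdRRM(recs, ped.to_dataframe(), "conventional",
                             model="repeatability")
        offsets = np.array([-1.3, 2.1])
        y = rng.standard_normal(12) * 0.1 + np.repeat(offsets, 6)
        cfg = GibbsConfig(n_iter=10, burn_in=1, thin=1, seed=3,
                          prior="weak", updates=("location",))
        s = GibbsSampler(m.design, m.records.category, 0, m.a_inverse, cfg,
                         observed_liability=y)
        s.G = np.array([[1e6]])
        s.P = np.array([[1e-10]])
        # the level and the unshrunk animal effects are only jointly
        # identified; their sum must match the within-ewe data means
        fits = []
        for it in range(4000):
            s.sweep()
            if it >= 1000:
                level = s.year_eff[0] + s.beta[0]
                fits.append(level + s.a.ravel())
        fbar = np.mean(fits, axis=0)
        within = [y[:6].mean(), y[6:].mean()]
        np.testing.assert_allclose(fbar, within, atol=0.25)


class TestVarianceConditionals:
    def test_genetic_covariance_recovered_from_known_coefficients(self, rng):
        """a simulated from a known G over a shallow pedigree: the
        inverse-Wishart conditional must center on G."""
        scen = prm.line_scenario("conventional", n_ewes=900, seed=13)
        ds = prm.simulate_dataset(scen)
        m = prm.ThresholdRRM(
            ds.records, ds.pedigree.to_dataframe(), "conventional", order=2
        )
        cfg = GibbsConfig(n_iter=10, burn_in=1, thin=1, seed=2, prior="weak")
        s = GibbsSampler(m.design, m.records.category, 2, m.a_inverse, cfg)
        # align the generator's breeding values to the model's pedigree order
        order = [m.pedigree.index_of(x) for x in ds.pedigree.ids]
        a_aligned = np.zeros_like(ds.a)
        a_aligned[order] = ds.a
        s.a = a_aligned
        draws = []
        for _ in range(300):
            s.sample_g()
            draws.append(s.G)
        G_hat = np.mean(draws, axis=0)
        np.testing.assert_allclose(
            np.diag(G_hat), np.diag(scen.true_G), rtol=0.15
        )

    def test_pe_covariance_recovered(self, rng):
        ds, m = _toy_model(order=2, n_ewes=2000, seed=14)
        cfg = GibbsConfig(n_iter=10, burn_in=1, thin=1, seed=2, prior="weak")
        s = GibbsSampler(m.design, m.records.category, 2, m.a_inverse, cfg)
        P0 = np.asarray(ds.scenario.true_P)
        L = np.linalg.cholesky(P0)
        s.p = (L @ rng.standard_normal((3, s.p.shape[0]))).T
        draws = []
        for _ in range(300):
            s.sample_p()
            draws.append(s.P)
        P_hat = np.mean(draws, axis=0)
        np.testing.assert_allclose(np.diag(P_hat), np.diag(P0), rtol=0.15)

    def test_residual_classes_recovered_gaussian(self, rng):
        """Gaussian mode, known zero location: class variances (0.8, 1.2)
        recovered within 10% at ~2000 records per class."""
        scen = prm.line_scenario("conventional", n_ewes=2500, seed=15)
        ds = prm.simulate_dataset(scen)
        m = prm.ThresholdRRM(
            ds.records, ds.pedigree.to_dataframe(), "conventional", order=1
        )
        des = m.design
        true_sig = np.array([0.8, 1.2, 1.0])
        y = rng.standard_normal(len(m.records)) * np.sqrt(
            true_sig[des.residual_class - 1]
        )
        cfg = GibbsConfig(n_iter=10, burn_in=1, thin=1, seed=2,
                          prior="weak", updates=("residual",))
        s = GibbsSampler(des, m.records.category, 0, m.a_inverse, cfg,
                         observed_liability=y)
        draws = []
        for _ in range(200):
            s.sweep()
            draws.append(s.sigma2_e.copy())
        sig_hat = np.mean(draws, axis=0)
        np.testing.assert_allclose(sig_hat, true_sig, rtol=0.10)
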