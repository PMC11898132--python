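"""Gibbs sampler for the threshold random-regression animal model.

The observed category of each record is linked to a latent Gaussian
liability; one Gibbs sweep updates, in order: liabilities (truncated
normal), fixed effects and fixed-regression coefficients (single site,
flat priors), genetic coefficients (blocked by animal against A^-1 x G^-1),
permanent-environment coefficients (blocked by ewe against P^-1), then G
and P (inverse-Wishart) and the per-class residual variances (scaled
inverse chi-square).

Identifiability anchoring: the first threshold is fixed at 0; with three
categories the second threshold is fixed at 1 and all residual classes are
free; with two categories the class-1 residual variance is fixed at 1.
Thresholds are therefore never sampled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from . import _kernels as K
from .design import DesignMatrices

__all__ = ["GibbsConfig", "PosteriorChain", "GibbsSampler", "run_chain",
           "sample_invwishart"]


@dataclass
class GibbsConfig:
    """Chain settings and priors.

    The chain-length defaults mirror a production run (500k samples, 100k
    burn-in, thinning 100, hence 4000 retained draws); tests and examples
    pass much shorter chains.

    prior="weak" uses proper, minimally informative priors
    (inverse-Wishart df = dim + 2, scale = ``prior_g_scale`` * I for G and P;
    scaled inverse chi-square df 4, scale 1 for residuals). prior="flat"
    drops the prior scale and degrees of freedom entirely.
    """

    n_iter: int = 500_000
    burn_in: int = 100_000
    thin: int = 100
    seed: int = 0
    prior: str = "weak"
    prior_g_scale: float = 0.1
    prior_b_sd: float = 5.0
    prior_resid_df: float = 4.0
    prior_resid_scale: float = 1.0
    store_effects: bool = False
    updates: tuple = ("liability", "location", "G", "P", "residual")
    checkpoint_every: int = 0
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior not in ("weak", "flat"):
            raise ValueError("prior must be 'weak' or 'flat'")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorChain:
    """Retained draws and everything needed to reproduce the run."""

    G: np.ndarray                # (S, q, q)
    P: np.ndarray                # (S, q, q)
    sigma2_e: np.ndarray         # (S, n_classes)
    thresholds: np.ndarray       # fixed tau vector
    deviance: np.ndarray         # (S,)
    eta_mean: np.ndarray         # posterior-mean linear predictor per record
    sigma2_mean: np.ndarray      # posterior-mean residual variance per class
    iterations: np.ndarray       # source iteration index of each draw
    seed: int
    config: dict
    n_animals: int = 0
    n_ewes: int = 0
    b: np.ndarray | None = None  # (S, n_fixed) if stored
    a: np.ndarray | None = None  # (S, n_animals, q) if stored

    def __len__(self) -> int:
        return self.G.shape[0]

    @property
    def n_coef(self) -> int:
        return self.G.shape[1]


def sample_invwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart(df, scale) draw via the Bartlett decomposition.

    Returns inv(W) with W ~ Wishart(df, inv(scale)). Requires df > dim - 1.
    """
    from scipy.linalg import solve_triangular

    q = scale.shape[0]
    if df <= q - 1:
        raise ValueError(f"inverse-Wishart needs df > dim-1, got {df}")
    scale = 0.5 * (scale + scale.T)
    # relative jitter keeps the factorization alive when the scale is
    # nearly singular (e.g. a covariance collapsing toward zero)
    eps = 1e-12 * max(np.trace(scale) / q, 1e-300)
    L = np.linalg.cholesky(scale + eps * np.eye(q))
    A = np.zeros((q, q))
    for i in range(q):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    # B = L^-T satisfies B B' = scale^-1, so W = (B A)(B A)' ~ Wishart
    BA = solve_triangular(L, A, lower=True, trans="T")
    W = BA @ BA.T
    out = np.linalg.inv(W)
    return 0.5 * (out + out.T)


def _category_bounds(category, thresholds):
    """Liability interval (lo, hi) per record from its category."""
    tau = np.concatenate(([-np.inf], thresholds, [np.inf]))
    cat = np.asarray(category, dtype=np.int64)
    return tau[cat - 1].copy(), tau[cat].copy()


def _group_by_owner(owner, n_owner):
    """CSR-style grouping of record indices by owner index."""
    order = np.argsort(owner, kind="stable")
    counts = np.bincount(owner, minlength=n_owner)
    ptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    return ptr, order.astype(np.int64)


class GibbsSampler:
    """Stateful Gibbs sampler over a :class:`DesignMatrices` layout.

    Parameters
    ----------
    design : DesignMatrices
    category : array of int
        Observed category (1..n_categories) per record.
    n_categories : int
        2 or 3.
    a_inverse : sparse matrix
        Inverse numerator relationship matrix over the design's animals.
    config : GibbsConfig
    observed_liability : array, optional
        If given, liabilities are treated as observed Gaussian data (no
        truncated-normal augmentation); used for linear-model checks.
    """

    def __init__(self, design: DesignMatrices, category, n_categories: int,
                 a_inverse: sp.spmatrix, config: GibbsConfig,
                 observed_liability=None):
        self.design = design
        self.config = config
        self.n_categories = int(n_categories)
        if self.n_categories not in (0, 2, 3):
            raise ValueError("n_categories must be 2 or 3")
        self.rng = np.random.default_rng(config.seed)

        d = design
        self.q = d.n_coef
        self.n_rec = d.phi_rec.shape[0]
        ainv = sp.csr_matrix(a_inverse)
        if ainv.shape[0] != d.n_animals:
            raise ValueError("A-inverse dimension does not match pedigree")
        self._ainv = ainv
        self._ainv_indptr = ainv.indptr.astype(np.int64)
        self._ainv_indices = ainv.indices.astype(np.int64)
        self._ainv_data = ainv.data.astype(np.float64)

        self._arec_ptr, self._arec_idx = _group_by_owner(
            d.animal_of, d.n_animals
        )
        self._prec_ptr, self._prec_idx = _group_by_owner(d.ewe_of, d.n_ewes)

        # thresholds and residual anchoring. With three categories the two
        # fixed thresholds (0 and 1) identify the liability scale of every
        # residual class, so all classes are free. With two categories no
        # threshold gap exists and a free class variance is a pure
        # multiplicative random walk (its truncated-normal residual SS
        # scales with the current variance), so every class is fixed at 1.
        self.n_classes = int(d.residual_class.max())
        if self.n_categories == 3:
            self.thresholds = np.array([0.0, 1.0])
            self._fixed_resid_classes = ()
        elif self.n_categories == 2:
            self.thresholds = np.array([0.0])
            self._fixed_resid_classes = tuple(range(1, self.n_classes + 1))
        else:  # Gaussian mode
            self.thresholds = np.array([])
            self._fixed_resid_classes = ()

        self._class0 = d.residual_class.astype(np.int64) - 1

        # state
        self.year_eff = np.zeros(d.n_years)
        self.month_eff = np.zeros(d.n_months - 1)
        self.beta = np.zeros(self.q)
        self.a = np.zeros((d.n_animals, self.q))
        self.p = np.zeros((d.n_ewes, self.q))
        self.G = 0.2 * np.eye(self.q)
        self.P = 0.2 * np.eye(self.q)
        self.sigma2_e = np.ones(self.n_classes)
        self.iteration = 0

        self.category = np.asarray(category, dtype=np.int64)
        if observed_liability is not None:
            self.liab = np.asarray(observed_liability, dtype=float).copy()
            self._augment = False
            self._lo = np.full(self.n_rec, -np.inf)
            self._hi = np.full(self.n_rec, np.inf)
        else:
            self._augment = True
            self._lo, self._hi = _category_bounds(
                self.category, self.thresholds
            )
            self.liab = self._initial_liabilities()
        self.e = self.liab - self._fitted()

        self._year_levels = np.asarray(
            np.argmax(d.X[:, :d.n_years].toarray(), axis=1)
        ).ravel().astype(np.int64)
        # month level per record: -1 for reference month
        month_block = d.X[:, d.n_years:d.n_years + d.n_months - 1].toarray()
        self._month_levels = np.where(
            month_block.any(axis=1), np.argmax(month_block, axis=1), -1
        ).astype(np.int64)
        self._phi = np.ascontiguousarray(d.phi_rec, dtype=np.float64)

    # ---------------------------------------------------------------- #
    # pieces of one sweep
    # ---------------------------------------------------------------- #

    def _initial_liabilities(self):
        mid = np.concatenate(
            ([self.thresholds[0] - 0.7],
             0.5 * (self.thresholds[:-1] + self.thresholds[1:]),
             [self.thresholds[-1] + 0.7])
        )
        return mid[self.category - 1].copy()

    def _fitted(self):
        d = self.design
        eta = np.zeros(self.n_rec)
        yl = np.asarray(
            np.argmax(d.X[:, :d.n_years].toarray(), axis=1)
        ).ravel()
        eta += self.year_eff[yl]
        month_block = d.X[:, d.n_years:d.n_years + d.n_months - 1].toarray()
        has_m = month_block.any(axis=1)
        eta[has_m] += self.month_eff[np.argmax(month_block[has_m], axis=1)]
        eta += d.phi_rec @ self.beta
        eta += np.einsum("rk,rk->r", d.phi_rec, self.a[d.animal_of])
        eta += np.einsum("rk,rk->r", d.phi_rec, self.p[d.ewe_of])
        return eta

    @property
    def _w_rec(self):
        return 1.0 / self.sigma2_e[self._class0]

    def sample_liabilities(self):
        """Truncated-normal draw of every record's liability."""
        if not self._augment:
            return
        u = self.rng.random(self.n_rec)
        K.update_liabilities(
            self.liab, self.e, self._lo, self._hi, self._w_rec, u
        )

    @property
    def _b_prec(self) -> float:
        """Prior precision on fixed effects: N(0, prior_b_sd^2) under the
        weakly-informative default, flat (0) otherwise. A proper prior on
        the location block breaks the separation ray a probit model with
        flexible per-ewe trajectories otherwise drifts along."""
        if self.config.prior == "flat":
            return 0.0
        return 1.0 / self.config.prior_b_sd ** 2

    def sample_location(self):
        """Update fixed effects, fixed regressions, a and p in one sweep."""
        w = self._w_rec
        bp = self._b_prec
        K.update_factor(
            self._year_levels, self.year_eff, self.e, w, bp,
            self.rng.standard_normal(self.year_eff.shape[0]),
        )
        K.update_factor(
            self._month_levels, self.month_eff, self.e, w, bp,
            self.rng.standard_normal(self.month_eff.shape[0]),
        )
        K.update_regression(
            self._phi, self.beta, self.e, w, bp,
            self.rng.standard_normal(self.q),
        )
        Ginv = np.linalg.inv(self.G)
        K.update_genetic(
            self.a, Ginv, self._ainv_indptr, self._ainv_indices,
            self._ainv_data, self._arec_ptr, self._arec_idx, self._phi,
            self.e, w, self.rng.standard_normal((self.a.shape[0], self.q)),
        )
        Pinv = np.linalg.inv(self.P)
        K.update_permanent(
            self.p, Pinv, self._prec_ptr, self._prec_idx, self._phi,
            self.e, w, self.rng.standard_normal((self.p.shape[0], self.q)),
        )

    def _iw_posterior(self, S, n):
        q = self.q
        if self.config.prior == "weak":
            df = n + q + 2
            scale = S + self.config.prior_g_scale * np.eye(q)
        else:
            df = n
            scale = S
        return df, scale

    def sample_g(self):
        """Inverse-Wishart draw of the genetic coefficient covariance."""
        Sa = self.a.T @ (self._ainv @ self.a)
        df, scale = self._iw_posterior(Sa, self.a.shape[0])
        for attempt in range(5):
            G = sample_invwishart(self.rng, df, scale)
            try:
                np.linalg.cholesky(G)
                self.G = G
                return
            except np.linalg.LinAlgError:
                warnings.warn("non-PD G draw; resampling", stacklevel=2)
        raise RuntimeError("could not draw a positive definite G")

    def sample_p(self):
        """Inverse-Wishart draw of the permanent-environment covariance."""
        Sp = self.p.T @ self.p
        df, scale = self._iw_posterior(Sp, self.p.shape[0])
        for attempt in range(5):
            P = sample_invwishart(self.rng, df, scale)
            try:
                np.linalg.cholesky(P)
                self.P = P
                return
            except np.linalg.LinAlgError:
                warnings.warn("non-PD P draw; resampling", stacklevel=2)
        raise RuntimeError("could not draw a positive definite P")

    def sample_residuals(self):
        """Scaled inverse chi-square draw per free residual class."""
        cfg = self.config
        for c in range(self.n_classes):
            if (c + 1) in self._fixed_resid_classes:
                self.sigma2_e[c] = 1.0
                continue
            mask = self._class0 == c
            n_c = int(mask.sum())
            if n_c == 0:
                warnings.warn(
                    f"residual class {c + 1} has no records; prior draw",
                    stacklevel=2,
                )
                if cfg.prior == "weak":
                    ss = cfg.prior_resid_df * cfg.prior_resid_scale
                    self.sigma2_e[c] = ss / self.rng.chisquare(
                        cfg.prior_resid_df
                    )
                continue
            ss = float(np.sum(self.e[mask] ** 2))
            if cfg.prior == "weak":
                df = n_c + cfg.prior_resid_df
                ss = ss + cfg.prior_resid_df * cfg.prior_resid_scale
            else:
                df = n_c
            self.sigma2_e[c] = ss / self.rng.chisquare(df)

    def sweep(self):
        """One full Gibbs sweep in the documented update order."""
        upd = self.config.updates
        if "liability" in upd:
            self.sample_liabilities()
        if "location" in upd:
            self.sample_location()
        if "G" in upd:
            self.sample_g()
        if "P" in upd:
            self.sample_p()
        if "residual" in upd:
            self.sample_residuals()
        self.iteration += 1

    # ---------------------------------------------------------------- #
    # deviance (for DIC / AIC-analogue model comparison)
    # ---------------------------------------------------------------- #

    def deviance(self, eta=None, sigma2=None):
        """-2 log likelihood of the observed categories given eta, sigma2."""
        from scipy.special import ndtr as phi_cdf

        if self.n_categories == 0:
            raise ValueError("deviance undefined in Gaussian mode")
        eta = self.liab - self.e if eta is None else eta
        sd = np.sqrt(
            (self.sigma2_e if sigma2 is None else sigma2)[self._class0]
        )
        z_hi = np.where(np.isinf(self._hi), np.inf, (self._hi - eta) / sd)
        z_lo = np.where(np.isinf(self._lo), -np.inf, (self._lo - eta) / sd)
        prob = phi_cdf(z_hi) - phi_cdf(z_lo)
        return -2.0 * float(np.sum(np.log(np.clip(prob, 1e-300, None))))

    # ---------------------------------------------------------------- #
    # chain driver with checkpointing
    # ---------------------------------------------------------------- #

    def state_dict(self):
        return {
            "iteration": self.iteration,
            "liab": self.liab, "e": self.e,
            "year_eff": self.year_eff, "month_eff": self.month_eff,
            "beta": self.beta, "a": self.a, "p": self.p,
            "G": self.G, "P": self.P, "sigma2_e": self.sigma2_e,
            "rng_state": json.dumps(self.rng.bit_generator.state),
        }

    def load_state(self, state):
        self.iteration = int(state["iteration"])
        for name in ("liab", "e", "year_eff", "month_eff", "beta",
                     "a", "p", "G", "P", "sigma2_e"):
            getattr(self, name)[...] = state[name]
        self.rng.bit_generator.state = json.loads(str(state["rng_state"]))

    def run(self, resume_from=None) -> PosteriorChain:
        cfg = self.config
        S = cfg.n_retained
        out_G = np.empty((S, self.q, self.q))
        out_P = np.empty((S, self.q, self.q))
        out_s2 = np.empty((S, self.n_classes))
        out_dev = np.empty(S)
        out_iter = np.empty(S, dtype=np.int64)
        out_b = (
            np.empty((S, self.design.n_fixed)) if cfg.store_effects else None
        )
        out_a = (
            np.empty((S, self.a.shape[0], self.q))
            if cfg.store_effects else None
        )
        eta_sum = np.zeros(self.n_rec)
        s2_sum = np.zeros(self.n_classes)

        start = 0
        kept = 0
        if resume_from is not None:
            ck = np.load(resume_from, allow_pickle=False)
            self.load_state(ck)
            start = self.iteration
            kept = int(ck["kept"])
            out_G[:kept] = ck["out_G"][:kept]
            out_P[:kept] = ck["out_P"][:kept]
            out_s2[:kept] = ck["out_s2"][:kept]
            out_dev[:kept] = ck["out_dev"][:kept]
            out_iter[:kept] = ck["out_iter"][:kept]
            eta_sum[...] = ck["eta_sum"]
            s2_sum[...] = ck["s2_sum"]
            if cfg.store_effects:
                out_b[:kept] = ck["out_b"][:kept]
                out_a[:kept] = ck["out_a"][:kept]

        try:
            for it in range(start + 1, cfg.n_iter + 1):
                self.sweep()
                if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                    out_G[kept] = self.G
                    out_P[kept] = self.P
                    out_s2[kept] = self.sigma2_e
                    out_dev[kept] = (
                        self.deviance() if self.n_categories else np.nan
                    )
                    out_iter[kept] = it
                    eta_sum += self.liab - self.e
                    s2_sum += self.sigma2_e
                    if cfg.store_effects:
                        out_b[kept] = np.concatenate(
                            [self.year_eff, self.month_eff, self.beta]
                        )
                        out_a[kept] = self.a
                    kept += 1
                if (
                    cfg.checkpoint_every
                    and cfg.checkpoint_path
                    and it % cfg.checkpoint_every == 0
                ):
                    self._write_checkpoint(
                        kept, out_G, out_P, out_s2, out_dev, out_iter,
                        eta_sum, s2_sum, out_b, out_a,
                    )
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as err:
            if cfg.checkpoint_path:
                self._write_checkpoint(
                    kept, out_G, out_P, out_s2, out_dev, out_iter,
                    eta_sum, s2_sum, out_b, out_a,
                )
            raise RuntimeError(
                f"numerical failure at iteration {self.iteration}: {err}"
            ) from err

        n = max(kept, 1)
        return PosteriorChain(
            G=out_G[:kept], P=out_P[:kept], sigma2_e=out_s2[:kept],
            thresholds=self.thresholds, deviance=out_dev[:kept],
            eta_mean=eta_sum / n, sigma2_mean=s2_sum / n,
            iterations=out_iter[:kept], seed=cfg.seed, config=asdict(cfg),
            n_animals=self.a.shape[0], n_ewes=self.p.shape[0],
            b=out_b[:kept] if out_b is not None else None,
            a=out_a[:kept] if out_a is not None else None,
        )

    def _write_checkpoint(self, kept, out_G, out_P, out_s2, out_dev,
                          out_iter, eta_sum, s2_sum, out_b, out_a):
        payload = dict(self.state_dict())
        payload.update(
            kept=kept, out_G=out_G, out_P=out_P, out_s2=out_s2,
            out_dev=out_dev, out_iter=out_iter, eta_sum=eta_sum,
            s2_sum=s2_sum,
        )
        if out_b is not None:
            payload.update(out_b=out_b, out_a=out_a)
        np.savez(self.config.checkpoint_path, **payload)


def run_chain(design: DesignMatrices, category, n_categories: int,
              a_inverse, config: GibbsConfig,
              observed_liability=None, resume_from=None) -> PosteriorChain:
    """Build a sampler and run the configured chain."""
    sampler = GibbsSampler(
        design, category, n_categories, a_inverse, config,
        observed_liability=observed_liability,
    )
    return sampler.run(resume_from=resume_from)
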