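"""Model and results objects for threshold litter-size trajectory analysis.

`ThresholdRRM` assembles the pedigree, the lambing records and the
Legendre trajectory design, and its :meth:`fit` runs the Gibbs sampler,
returning a :class:`ThresholdRRMResults` with the retained draws, the
posterior genetic-parameter trajectories and report tables.

The repeatability animal model is the degenerate configuration with a
single raw intercept covariate per random effect (constant genetic and
permanent-environment effects, one residual class), which forces
parity-constant h2 and unit genetic correlations.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import LegendreBasis
from .design import (
    N_CATEGORIES, RESIDUAL_CLASSES, RecordSet, build_design, read_records,
)
from .gibbs import GibbsConfig, GibbsSampler, PosteriorChain
from .pedigree import Pedigree
from .trajectory import trajectory_summary

__all__ = ["ThresholdRRM", "ThresholdRRMResults"]


class _InterceptBasis:
    """Constant covariate over the parity grid (repeatability model)."""

    def __init__(self, t_min: int = 1, t_max: int = 6):
        self.order = 0
        self.t_min, self.t_max = t_min, t_max
        self.phi = np.ones((t_max - t_min + 1, 1))

    @property
    def n_coef(self):
        return 1

    @property
    def parities(self):
        return np.arange(self.t_min, self.t_max + 1)

    def row(self, t):
        return np.ones(1)


class ThresholdRRM:
    """Threshold random-regression (or repeatability) animal model.

    Parameters
    ----------
    records : RecordSet or pandas.DataFrame or path
        Lambing records (columns ewe, year, month, parity, litter_size).
    pedigree : Pedigree or pandas.DataFrame or path
    line : str
        'prolific' (3 liability categories) or 'conventional' (2).
    order : int
        Legendre order of the genetic and permanent-environment
        trajectories (default 2).
    model : str
        'random_regression' or 'repeatability'.
    use_inbreeding : bool
        Account for inbreeding in A^-1 (default True).
    """

    def __init__(self, records, pedigree, line: str, order: int = 2,
                 model: str = "random_regression",
                 use_inbreeding: bool = True):
        if model not in ("random_regression", "repeatability"):
            raise ValueError(
                "model must be 'random_regression' or 'repeatability'"
            )
        if isinstance(pedigree, Pedigree):
            self.pedigree = pedigree
        elif isinstance(pedigree, pd.DataFrame):
            self.pedigree = Pedigree.from_dataframe(pedigree)
        else:
            self.pedigree = Pedigree.from_file(pedigree)
        if isinstance(records, RecordSet):
            self.records = records
        else:
            self.records = read_records(records, line)
        self.line = self.records.line
        self.model = model
        self.order = int(order)
        self.use_inbreeding = use_inbreeding
        self.repeatability = model == "repeatability"
        self.basis = (
            _InterceptBasis() if self.repeatability
            else LegendreBasis(order=self.order)
        )
        self.design = build_design(
            self.records, self.pedigree,
            None if self.repeatability else self.basis,
            repeatability=self.repeatability,
        )
        self.a_inverse = self.pedigree.a_inverse(use_inbreeding)
        self.n_categories = N_CATEGORIES[self.line]

    @classmethod
    def from_files(cls, records_path, pedigree_path, line: str, **kwargs):
        return cls(records_path, pedigree_path, line, **kwargs)

    @property
    def class_map(self) -> dict:
        """Parity -> 1-based residual class for this configuration."""
        if self.repeatability:
            return {t: 1 for t in range(1, 7)}
        return dict(RESIDUAL_CLASSES[self.line])

    def fit(self, n_iter: int = 500_000, burn_in: int = 100_000,
            thin: int = 100, seed: int = 0, prior: str = "weak",
            store_effects: bool = False, checkpoint_every: int = 0,
            checkpoint_path=None, resume_from=None,
            **config_kwargs) -> "ThresholdRRMResults":
        """Run the Gibbs chain and return the results object."""
        config = GibbsConfig(
            n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed,
            prior=prior, store_effects=store_effects,
            checkpoint_every=checkpoint_every,
            checkpoint_path=(
                str(checkpoint_path) if checkpoint_path else None
            ),
            **config_kwargs,
        )
        sampler = GibbsSampler(
            self.design, self.records.category, self.n_categories,
            self.a_inverse, config,
        )
        chain = sampler.run(resume_from=resume_from)
        return ThresholdRRMResults(self, chain, sampler)


class ThresholdRRMResults:
    """Posterior results of a fitted threshold trajectory model.

    Carries the retained draws (`chain`), exposes the per-parity genetic
    parameters (posterior means with HPD / exceedance-probability /
    credible-limit summaries), the genetic and phenotypic correlation
    matrices, and deviance-based model-comparison criteria.
    """

    def __init__(self, model: ThresholdRRM, chain: PosteriorChain,
                 sampler: GibbsSampler | None = None):
        self.model = model
        self.chain = chain
        self._sampler = sampler
        self._trajectory = None

    # -------------------------------------------------------------- #
    # derived parameters
    # -------------------------------------------------------------- #

    def trajectory(self, cutoff: float = 0.10, mass: float = 0.95) -> dict:
        """Per-draw trajectory parameters, summarized (cached)."""
        if self._trajectory is None:
            self._trajectory = trajectory_summary(
                self.chain, self.model.basis, self.model.class_map,
                cutoff=cutoff, mass=mass,
            )
        return self._trajectory

    def summary(self) -> pd.DataFrame:
        """Genetic-parameter table: one row per parity (one row total for
        the repeatability model), with posterior-mean variance components,
        h2 with HPD / P(h2 > 0.10) / lower 95% credible limit, and c2."""
        tr = self.trajectory()
        nt = 1 if self.model.repeatability else len(tr["parities"])
        rows = []
        for i in range(nt):
            h2 = tr["h2"][i]
            rows.append(
                {
                    "model": (
                        "repeatability" if self.model.repeatability
                        else "random_regression"
                    ),
                    "parity": "-" if self.model.repeatability
                    else int(tr["parities"][i]),
                    "sigma2_a": tr["sigma2_a"][i].mean,
                    "sigma2_p": tr["sigma2_p"][i].mean,
                    "sigma2_e": tr["sigma2_e"][i].mean,
                    "h2": h2.mean,
                    "hpd_low": h2.hpd_low,
                    "hpd_high": h2.hpd_high,
                    "P": h2.p_exceed,
                    "k": h2.k_limit,
                    "c2": tr["c2"][i].mean,
                }
            )
        return pd.DataFrame(rows)

    def genetic_correlations(self) -> np.ndarray:
        return self.trajectory()["rg_mean"]

    def phenotypic_correlations(self) -> np.ndarray:
        return self.trajectory()["rp_mean"]

    def correlation_table(self, decimals: int = 2) -> pd.DataFrame:
        """Combined table: genetic correlations above the diagonal,
        phenotypic below, '-' on the diagonal."""
        rg = self.genetic_correlations()
        rp = self.phenotypic_correlations()
        nt = rg.shape[0]
        parities = self.trajectory()["parities"]
        out = pd.DataFrame(
            "-", index=parities, columns=parities, dtype=object
        )
        for i in range(nt):
            for j in range(nt):
                if i < j:
                    out.iloc[i, j] = round(float(rg[i, j]), decimals)
                elif i > j:
                    out.iloc[i, j] = round(float(rp[i, j]), decimals)
        return out

    # -------------------------------------------------------------- #
    # model comparison
    # -------------------------------------------------------------- #

    @property
    def n_parameters(self) -> int:
        q = self.chain.n_coef
        n_free_resid = self.chain.sigma2_e.shape[1]
        if self.model.n_categories == 2:
            n_free_resid -= 1  # class 1 anchored at 1
        return self.model.design.n_fixed + q * (q + 1) + n_free_resid

    def deviance_at_mean(self) -> float:
        return self._sampler.deviance(
            eta=self.chain.eta_mean, sigma2=self.chain.sigma2_mean
        )

    def dic(self) -> float:
        """Deviance information criterion: mean(D) + pD."""
        dbar = float(np.mean(self.chain.deviance))
        return 2.0 * dbar - self.deviance_at_mean()

    def aic_analogue(self) -> float:
        """Plug-in criterion: deviance at the posterior mean + 2 * #params."""
        return self.deviance_at_mean() + 2.0 * self.n_parameters

    # -------------------------------------------------------------- #
    # persistence
    # -------------------------------------------------------------- #

    def draws_frame(self) -> pd.DataFrame:
        """Flattened retained draws (G, P, residual variances) per row."""
        q = self.chain.n_coef
        data = {"iteration": self.chain.iterations}
        for i in range(q):
            for j in range(i, q):
                data[f"G_{i}{j}"] = self.chain.G[:, i, j]
        for i in range(q):
            for j in range(i, q):
                data[f"P_{i}{j}"] = self.chain.P[:, i, j]
        for c in range(self.chain.sigma2_e.shape[1]):
            data[f"sigma2_e_{c + 1}"] = self.chain.sigma2_e[:, c]
        data["deviance"] = self.chain.deviance
        return pd.DataFrame(data)

    def save(self, outdir) -> dict:
        """Write draws, summary and correlation tables plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        draws_path = outdir / "draws.csv"
        self.draws_frame().to_csv(draws_path, index=False)
        self.summary().round(6).to_csv(outdir / "summary.csv", index=False)
        self.correlation_table(6).to_csv(outdir / "correlations.csv")
        np.savetxt(outdir / "rg_full.csv", self.genetic_correlations(),
                   delimiter=",")
        np.savetxt(outdir / "rp_full.csv", self.phenotypic_correlations(),
                   delimiter=",")
        manifest = {
            "seed": self.chain.seed,
            "config": self.chain.config,
            "line": self.model.line,
            "model": self.model.model,
            "order": self.model.order,
            "n_records": len(self.model.records),
            "n_animals": self.chain.n_animals,
            "n_ewes": self.chain.n_ewes,
            "n_retained": len(self.chain),
            "draws_sha256": hashlib.sha256(
                draws_path.read_bytes()
            ).hexdigest(),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
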