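"""Post-Gibbs scalar summaries.

Posterior mean, 95% highest-posterior-density interval, exceedance
probability above a cutoff (default 0.10, the reporting convention for
liability-scale heritability), the lower 95% credible limit k such that
P(value >= k) = 0.95, and an autocorrelation-based effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "hpd_interval",
    "prob_exceeds",
    "lower_credible_limit",
    "effective_sample_size",
    "ScalarSummary",
    "summarize",
]


def hpd_interval(samples, mass: float = 0.95):
    """Shortest contiguous interval containing ceil(mass * n) sorted draws.

    Ties between equally short windows are broken by the lowest left
    endpoint. Requires at least 20 draws.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError(f"need >= 20 draws for an HPD interval, got {n}")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    j = int(np.argmin(widths))  # argmin returns the first (lowest-left) tie
    return float(x[j]), float(x[j + m - 1])


def prob_exceeds(samples, cutoff: float = 0.10) -> float:
    """Fraction of draws strictly greater than the cutoff."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draw vector")
    return float(np.mean(x > cutoff))


def lower_credible_limit(samples, mass: float = 0.95) -> float:
    """k with P(value >= k) = mass: the (1 - mass) type-7 quantile."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty draw vector")
    return float(np.quantile(x, 1.0 - mass, method="linear"))


def effective_sample_size(samples) -> float:
    """Autocorrelation-based ESS (arviz 'bulk' estimator)."""
    import arviz

    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 4 or np.allclose(x, x[0]):
        return float(x.size)
    return float(arviz.ess(x, method="mean"))


@dataclass
class ScalarSummary:
    """Posterior summary of one derived quantity."""

    mean: float
    hpd_low: float
    hpd_high: float
    p_exceed: float
    k_limit: float
    ess: float

    def as_dict(self):
        return {
            "mean": self.mean,
            "hpd_low": self.hpd_low,
            "hpd_high": self.hpd_high,
            "p_exceed": self.p_exceed,
            "k": self.k_limit,
            "ess": self.ess,
        }


def summarize(samples, cutoff: float = 0.10, mass: float = 0.95,
              compute_ess: bool = True) -> ScalarSummary:
    """Full scalar summary of a draw vector.

    Derived quantities must be computed per draw *before* calling this —
    never summarize a plug-in of posterior means.
    """
    x = np.asarray(samples, dtype=float).ravel()
    lo, hi = hpd_interval(x, mass)
    return ScalarSummary(
        mean=float(np.mean(x)),
        hpd_low=lo,
        hpd_high=hi,
        p_exceed=prob_exceeds(x, cutoff),
        k_limit=lower_credible_limit(x, mass),
        ess=effective_sample_size(x) if compute_ess else float("nan"),
    )
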