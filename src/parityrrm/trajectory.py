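"""Trajectory genetic parameters from random-regression covariances.

Given the coefficient covariances G (genetic) and P (permanent
environment) and the per-class residual variances, the variance of the
trait at parity t is the quadratic form phi(t)' M phi(t) and the
covariance between parities t and s is phi(t)' M phi(s) (the covariance-
function expressions of random-regression methodology). Residuals are
independent across parities, so they enter phenotypic variances only on
the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import LegendreBasis
from .summaries import ScalarSummary, summarize

__all__ = [
    "variance_at",
    "heritability_at",
    "pe_fraction_at",
    "genetic_correlation",
    "phenotypic_correlation",
    "TrajectoryParams",
    "params_from_components",
    "trajectory_summary",
]


def variance_at(M: np.ndarray, phi_t: np.ndarray) -> float:
    """Quadratic form phi' M phi — trait variance at one parity."""
    M = np.asarray(M, dtype=float)
    phi_t = np.asarray(phi_t, dtype=float)
    if M.shape != (phi_t.size, phi_t.size):
        raise ValueError(
            f"dimension mismatch: M {M.shape} vs phi {phi_t.shape}"
        )
    return float(phi_t @ M @ phi_t)


def heritability_at(sigma2_a: float, sigma2_p: float, sigma2_e: float) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_p + sigma2_e)."""
    total = sigma2_a + sigma2_p + sigma2_e
    if total <= 0:
        raise ValueError("total phenotypic variance must be positive")
    return sigma2_a / total


def pe_fraction_at(sigma2_a: float, sigma2_p: float, sigma2_e: float) -> float:
    """c2 = sigma2_p / (sigma2_a + sigma2_p + sigma2_e)."""
    total = sigma2_a + sigma2_p + sigma2_e
    if total <= 0:
        raise ValueError("total phenotypic variance must be positive")
    return sigma2_p / total


def genetic_correlation(G, phi_t, phi_s) -> float:
    """rg(t, s) = phi_t' G phi_s / sqrt(var(t) var(s))."""
    vt = variance_at(G, phi_t)
    vs = variance_at(G, phi_s)
    if vt <= 0 or vs <= 0:
        return float("nan")
    cov = float(np.asarray(phi_t) @ np.asarray(G) @ np.asarray(phi_s))
    return cov / np.sqrt(vt * vs)


def phenotypic_correlation(G, P, sigma2_by_class, phi_t, phi_s,
                           class_t: int, class_s: int) -> float:
    """rp(t, s) with genetic + PE covariance and class residuals on the
    diagonal; residuals are uncorrelated across parities."""
    sigma2_by_class = np.asarray(sigma2_by_class, dtype=float)
    vt = (variance_at(G, phi_t) + variance_at(P, phi_t)
          + sigma2_by_class[class_t - 1])
    vs = (variance_at(G, phi_s) + variance_at(P, phi_s)
          + sigma2_by_class[class_s - 1])
    if vt <= 0 or vs <= 0:
        return float("nan")
    phi_t = np.asarray(phi_t)
    phi_s = np.asarray(phi_s)
    cov = float(phi_t @ np.asarray(G) @ phi_s + phi_t @ np.asarray(P) @ phi_s)
    return cov / np.sqrt(vt * vs)


@dataclass
class TrajectoryParams:
    """Per-parity variances, ratios and 6x6 correlation matrices."""

    parities: np.ndarray
    sigma2_a: np.ndarray
    sigma2_p: np.ndarray
    sigma2_e: np.ndarray
    h2: np.ndarray
    c2: np.ndarray
    rg: np.ndarray
    rp: np.ndarray


def params_from_components(G, P, sigma2_by_class, basis: LegendreBasis,
                           class_map: dict) -> TrajectoryParams:
    """Evaluate the full trajectory parameter set for one draw.

    ``class_map`` maps parity (t_min..t_max) to its 1-based residual
    class; the repeatability model maps every parity to class 1.
    """
    ts = basis.parities
    nt = ts.size
    sigma2_by_class = np.asarray(sigma2_by_class, dtype=float)
    sa = np.array([variance_at(G, basis.row(t)) for t in ts])
    sp_ = np.array([variance_at(P, basis.row(t)) for t in ts])
    se = np.array([sigma2_by_class[class_map[int(t)] - 1] for t in ts])
    tot = sa + sp_ + se
    h2 = sa / tot
    c2 = sp_ / tot
    rg = np.eye(nt)
    rp = np.eye(nt)
    for i in range(nt):
        for j in range(i + 1, nt):
            rg[i, j] = rg[j, i] = genetic_correlation(
                G, basis.row(ts[i]), basis.row(ts[j])
            )
            rp[i, j] = rp[j, i] = phenotypic_correlation(
                G, P, sigma2_by_class, basis.row(ts[i]), basis.row(ts[j]),
                class_map[int(ts[i])], class_map[int(ts[j])],
            )
    return TrajectoryParams(ts, sa, sp_, se, h2, c2, rg, rp)


def trajectory_summary(chain, basis: LegendreBasis, class_map: dict,
                       cutoff: float = 0.10, mass: float = 0.95) -> dict:
    """Posterior summaries of every trajectory parameter.

    Each derived quantity is evaluated on every retained draw and then
    summarized (mean, HPD, exceedance probability, lower credible limit) —
    never on the posterior-mean covariances.

    Returns a dict with per-parity ScalarSummary tables for sigma2_a,
    sigma2_p, sigma2_e, h2 and c2, and posterior-mean rg / rp matrices.
    """
    S = len(chain)
    ts = basis.parities
    nt = ts.size
    draws = {
        name: np.empty((S, nt))
        for name in ("sigma2_a", "sigma2_p", "sigma2_e", "h2", "c2")
    }
    rg_sum = np.zeros((nt, nt))
    rp_sum = np.zeros((nt, nt))
    for s in range(S):
        tp = params_from_components(
            chain.G[s], chain.P[s], chain.sigma2_e[s], basis, class_map
        )
        draws["sigma2_a"][s] = tp.sigma2_a
        draws["sigma2_p"][s] = tp.sigma2_p
        draws["sigma2_e"][s] = tp.sigma2_e
        draws["h2"][s] = tp.h2
        draws["c2"][s] = tp.c2
        rg_sum += tp.rg
        rp_sum += tp.rp
    out: dict = {"parities": ts, "draws": draws}
    for name, per_parity in draws.items():
        out[name] = [
            summarize(per_parity[:, i], cutoff=cutoff, mass=mass)
            for i in range(nt)
        ]
    out["rg_mean"] = rg_sum / S
    out["rp_mean"] = rp_sum / S
    return out
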