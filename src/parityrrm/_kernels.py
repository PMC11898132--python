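"""Numba kernels for the Gibbs sweeps.

All kernels mutate their state arrays in place and consume pre-drawn
uniform/normal variates supplied by the driver, which keeps the random
stream owned by a single numpy Generator (reproducible, checkpointable).

The residual vector ``e`` is maintained as liability minus fitted value;
every update keeps it consistent incrementally.
"""

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def ndtr(x):
    """Standard normal CDF."""
    return 0.5 * (1.0 + math.erf(x / SQRT2))


@njit(cache=True)
def ndtri(p):
    """Inverse standard normal CDF (Wichura's AS241, double precision)."""
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
                    + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
                  + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
                + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
                    + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
                  + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
                + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    r = p if q < 0.0 else 1.0 - p
    if r <= 0.0:
        return -math.inf if q < 0.0 else math.inf
    r = math.sqrt(-math.log(r))
    if r <= 5.0:
        r -= 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
                    + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
                  + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
                + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
                    + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
                  + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
                + 2.05319162663775882187e0) * r + 1.0)
    else:
        r -= 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
                    + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
                  + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
                + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
                    + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
                  + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
                + 5.99832206555887937690e-1) * r + 1.0)
    val = num / den
    return -val if q < 0.0 else val


@njit(cache=True)
def sample_truncnorm(mean, sd, lo, hi, u):
    """One truncated-normal draw by inverse-CDF; safe in extreme tails."""
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    ua = ndtr(a) if a > -math.inf else 0.0
    ub = ndtr(b) if b < math.inf else 1.0
    span = ub - ua
    if span <= 1e-300:
        # negligible mass: pin to the nearest finite bound
        z = a if a > -math.inf else b
    else:
        uu = ua + u * span
        if uu < 1e-300:
            uu = 1e-300
        elif uu > 1.0 - 1e-16:
            uu = 1.0 - 1e-16
        z = ndtri(uu)
        if z < a:
            z = a
        elif z > b:
            z = b
    return mean + sd * z


@njit(cache=True)
def update_liabilities(liab, e, lo, hi, w_rec, u):
    """Draw each liability from its truncated-normal full conditional."""
    for r in range(liab.shape[0]):
        mean = liab[r] - e[r]
        sd = 1.0 / math.sqrt(w_rec[r])
        liab[r] = sample_truncnorm(mean, sd, lo[r], hi[r], u[r])
        e[r] = liab[r] - mean


@njit(cache=True)
def update_factor(level_of, coef, e, w_rec, prior_prec, z):
    """Gibbs update of a categorical fixed effect.

    ``prior_prec`` is the precision of an independent N(0, .) prior per
    level (0 for a flat prior). Levels partition the records, so all
    levels of one factor have mutually independent full conditionals and
    are drawn in one pass. ``level_of`` may contain -1 for a dropped
    reference level.
    """
    n_levels = coef.shape[0]
    prec = np.full(n_levels, prior_prec)
    rhs = np.zeros(n_levels)
    for r in range(level_of.shape[0]):
        c = level_of[r]
        if c < 0:
            continue
        w = w_rec[r]
        prec[c] += w
        rhs[c] += w * (e[r] + coef[c])
    delta = np.zeros(n_levels)
    for c in range(n_levels):
        if prec[c] > 0.0:
            new = rhs[c] / prec[c] + z[c] / math.sqrt(prec[c])
            delta[c] = new - coef[c]
            coef[c] = new
    for r in range(level_of.shape[0]):
        c = level_of[r]
        if c >= 0:
            e[r] -= delta[c]


@njit(cache=True)
def update_regression(xcols, coef, e, w_rec, prior_prec, z):
    """Single-site Gibbs update of dense regression columns with an
    independent N(0, 1/prior_prec) prior (0 = flat)."""
    n, q = xcols.shape
    for k in range(q):
        prec = prior_prec
        rhs = 0.0
        for r in range(n):
            x = xcols[r, k]
            w = w_rec[r]
            prec += w * x * x
            rhs += w * x * (e[r] + x * coef[k])
        if prec <= 0.0:
            continue
        new = rhs / prec + z[k] / math.sqrt(prec)
        d = new - coef[k]
        coef[k] = new
        for r in range(n):
            e[r] -= d * xcols[r, k]


@njit(cache=True)
def _chol_small(C, L):
    """In-place Cholesky of a small SPD matrix; returns False if it fails."""
    q = C.shape[0]
    for i in range(q):
        for j in range(i + 1):
            s = C[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def _draw_block(C, rhs, z, out):
    """out <- N(C^-1 rhs, C^-1) using a pre-drawn standard-normal z."""
    q = C.shape[0]
    L = np.zeros((q, q))
    ok = _chol_small(C, L)
    if not ok:
        raise ValueError("singular conditional covariance in block update")
    y = np.zeros(q)
    for i in range(q):          # L y = rhs
        s = rhs[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    for i in range(q - 1, -1, -1):  # L^T mu = y  -> out holds mu
        s = y[i]
        for k in range(i + 1, q):
            s -= L[k, i] * out[k]
        out[i] = s / L[i, i]
    v = np.zeros(q)             # L^T v = z, then out += v

    for i in range(q - 1, -1, -1):
        s = z[i]
        for k in range(i + 1, q):
            s -= L[k, i] * v[k]
        v[i] = s / L[i, i]
    for i in range(q):
        out[i] += v[i]


@njit(cache=True)
def update_genetic(a, Ginv, indptr, indices, data, rec_ptr, rec_idx,
                   phi, e, w_rec, z):
    """Blocked-by-animal Gibbs update of the genetic coefficients.

    The prior precision of animal i's block is A^-1[i,i] * G^-1 with a mean
    shifted by the A^-1 off-diagonal couplings to relatives; records add
    phi phi' / sigma2_e terms.
    """
    n, q = a.shape
    C = np.zeros((q, q))
    rhs = np.zeros(q)
    new = np.zeros(q)
    for i in range(n):
        aii = 0.0
        for k in range(q):
            rhs[k] = 0.0
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            v = data[ptr]
            if j == i:
                aii = v
            else:
                for k in range(q):
                    s = 0.0
                    for m in range(q):
                        s += Ginv[k, m] * a[j, m]
                    rhs[k] -= v * s
        for k in range(q):
            for m in range(q):
                C[k, m] = aii * Ginv[k, m]
        for ptr in range(rec_ptr[i], rec_ptr[i + 1]):
            r = rec_idx[ptr]
            w = w_rec[r]
            fit_i = 0.0
            for k in range(q):
                fit_i += phi[r, k] * a[i, k]
            resid_full = e[r] + fit_i
            for k in range(q):
                pk = phi[r, k]
                rhs[k] += w * pk * resid_full
                for m in range(q):
                    C[k, m] += w * pk * phi[r, m]
        _draw_block(C, rhs, z[i], new)
        for ptr in range(rec_ptr[i], rec_ptr[i + 1]):
            r = rec_idx[ptr]
            d = 0.0
            for k in range(q):
                d += phi[r, k] * (new[k] - a[i, k])
            e[r] -= d
        for k in range(q):
            a[i, k] = new[k]


@njit(cache=True)
def update_permanent(p, Pinv, rec_ptr, rec_idx, phi, e, w_rec, z):
    """Blocked-by-ewe Gibbs update of permanent-environment coefficients."""
    n, q = p.shape
    C = np.zeros((q, q))
    rhs = np.zeros(q)
    new = np.zeros(q)
    for i in range(n):
        for k in range(q):
            rhs[k] = 0.0
            for m in range(q):
                C[k, m] = Pinv[k, m]
        for ptr in range(rec_ptr[i], rec_ptr[i + 1]):
            r = rec_idx[ptr]
            w = w_rec[r]
            fit_i = 0.0
            for k in range(q):
                fit_i += phi[r, k] * p[i, k]
            resid_full = e[r] + fit_i
            for k in range(q):
                pk = phi[r, k]
                rhs[k] += w * pk * resid_full
                for m in range(q):
                    C[k, m] += w * pk * phi[r, m]
        _draw_block(C, rhs, z[i], new)
        for ptr in range(rec_ptr[i], rec_ptr[i + 1]):
            r = rec_idx[ptr]
            d = 0.0
            for k in range(q):
                d += phi[r, k] * (new[k] - p[i, k])
            e[r] -= d
        for k in range(q):
            p[i, k] = new[k]
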