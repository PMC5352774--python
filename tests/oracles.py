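"""Independent oracles used by the test suite.

Everything here is deliberately implemented by brute force (closed forms,
grid quadrature, sort-and-interpolate) and never calls the code paths it is
used to check.
"""

import numpy as np
from scipy import integrate, stats


# ---------------------------------------------------------------------------
# diffusion closed forms
# ---------------------------------------------------------------------------


def absorption_probability_upper(v: float, a: float, z: float) -> float:
    """P(hit a before 0 | drift v, start z), unit diffusion coefficient."""
    if abs(v) < 1e-12:
        return z / a
    return (1 - np.exp(-2 * v * z)) / (1 - np.exp(-2 * v * a))


def mean_decision_time_symmetric(v: float, a: float) -> float:
    """Unconditional mean first-passage time from z = a/2, unit noise."""
    return (a / (2 * v)) * np.tanh(v * a / 2)


# ---------------------------------------------------------------------------
# quantiles and correlations
# ---------------------------------------------------------------------------


def quantile_sort_interpolate(values, level: float) -> float:
    """Linear order-statistic quantile, written out longhand."""
    xs = sorted(values)
    n = len(xs)
    pos = level * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def pearson_longhand(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    cov = np.sum((x - mx) * (y - my))
    return cov / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))


def decile_groups_sort_and_cut(values) -> np.ndarray:
    """Ten caution groups by rank against the .1-.9 empirical quantiles.

    Right-closed convention: a value lying exactly on the q-th cut belongs
    to the group below the cut.
    """
    v = np.asarray(values, dtype=float)
    cuts = [quantile_sort_interpolate(v, q / 10) for q in range(1, 10)]
    out = np.zeros(len(v), dtype=int)
    for i, x in enumerate(v):
        g = 0
        for c in cuts:
            if x > c:
                g += 1
        out[i] = g
    return out


# ---------------------------------------------------------------------------
# H1 / H2 marginal-likelihood quadrature
# ---------------------------------------------------------------------------


def h1_bf10_quadrature(r, n, levels, constrained=True, grid=1600):
    """BF10 for the linear WPR slope by direct 2-D grid integration."""
    levels = np.asarray(levels, dtype=float)
    z = np.arctanh(np.asarray(r, dtype=float))
    sd = 1.0 / np.sqrt(n - 3)
    lo, hi = (-1.0, 0.0) if constrained else (-1.0, 1.0)
    b0 = np.linspace(lo, hi, grid)
    b1 = np.linspace(lo, hi, grid + 1)
    B0, B1 = np.meshgrid(b0, b1, indexing="ij")
    RHO = B0[:, :, None] + B1[:, :, None] * levels
    adm = np.all(np.abs(RHO) < 1, axis=2)
    RHO = np.clip(RHO, -1 + 1e-12, 1 - 1e-12)
    LL = np.where(
        adm,
        np.exp(-0.5 * np.sum(((z - np.arctanh(RHO)) / sd) ** 2, axis=2)),
        0.0,
    )
    area = np.trapezoid(np.trapezoid(adm.astype(float), b1, axis=1), b0)
    m1 = np.trapezoid(np.trapezoid(LL, b1, axis=1), b0) / area
    rho0 = np.clip(b0[:, None] * np.ones(len(levels)), -1 + 1e-12, 1 - 1e-12)
    ll0 = np.exp(-0.5 * np.sum(((z - np.arctanh(rho0)) / sd) ** 2, axis=1))
    m0 = np.trapezoid(ll0, b0) / (hi - lo)
    return m1 / m0


def h2_bf10_quadrature(r_e, n_e, r_d, n_d, levels,
                       n_mu=361, n_de=241, n_b0=801):
    """BF10 for the probit difficulty difference by direct grid integration.

    Exploits that, given (mu, delta), the likelihood factorises over the two
    conditions, each with its own beta0 integral on its admissible range.
    """
    levels = np.asarray(levels, dtype=float)
    lmax = levels.max()
    data = {
        "e": (np.arctanh(np.asarray(r_e, float)), 1 / np.sqrt(n_e - 3)),
        "d": (np.arctanh(np.asarray(r_d, float)), 1 / np.sqrt(n_d - 3)),
    }

    def cond_integral(bstar, cond):
        """integral over beta0 in (-1+lmax*bstar, 0) of the likelihood."""
        z, sd = data[cond]
        lo = -1 + lmax * bstar
        out = np.empty_like(np.atleast_1d(bstar), dtype=float)
        bs = np.atleast_1d(bstar)
        los = np.atleast_1d(lo)
        for i, (b, l0) in enumerate(zip(bs, los)):
            b0 = np.linspace(l0 + 1e-9, -1e-9, n_b0)
            rho = b0[:, None] - b * levels
            rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
            ll = np.exp(-0.5 * np.sum(((z - np.arctanh(rho)) / sd) ** 2, axis=1))
            out[i] = np.trapezoid(ll, b0)
        return out

    mu = np.linspace(-5, 5, n_mu)
    de = np.linspace(0, 6, n_de)

    # alternative: integrate over (mu, delta)
    m1_rows = np.empty((n_mu, n_de))
    adm_rows = np.empty((n_mu, n_de))
    for j, d in enumerate(de):
        bs_e = stats.norm.cdf(mu - d / 2)
        bs_d = stats.norm.cdf(mu + d / 2)
        m1_rows[:, j] = cond_integral(bs_e, "e") * cond_integral(bs_d, "d")
        adm_rows[:, j] = (1 - lmax * bs_e) * (1 - lmax * bs_d)
    w = stats.norm.pdf(mu)[:, None] * (2 * stats.norm.pdf(de))[None, :]
    B = np.trapezoid(np.trapezoid(w * m1_rows, de, axis=1), mu)
    Z = np.trapezoid(np.trapezoid(w * adm_rows, de, axis=1), mu)

    # null slice delta = 0
    bs0 = stats.norm.cdf(mu)
    s0 = np.trapezoid(
        stats.norm.pdf(mu) * cond_integral(bs0, "e") * cond_integral(bs0, "d"), mu
    )
    t0 = np.trapezoid(stats.norm.pdf(mu) * (1 - lmax * bs0) ** 2, mu)
    m1 = B / Z
    m0 = s0 / t0
    return m1 / m0


# ---------------------------------------------------------------------------
# JZS mixture-of-g marginal likelihood
# ---------------------------------------------------------------------------


def jzs_bf10_bruteforce(x, y, rscale, n_g=250, n_beta=600, n_sig=700):
    """Mixture-of-g BF by quadrature over g of a per-g Bayes factor that is
    itself computed by brute-force integration of the Gaussian likelihood
    over (slope, error SD) against the g-prior and the 1/sigma^2 reference
    prior.  The mixing density on g is InverseGamma(1/2, n*rscale^2/2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()  # flat intercept prior integrates out to centering
    sxx = np.sum(xc ** 2)
    syy = np.sum(yc ** 2)
    sxy = np.sum(xc * yc)

    sig = np.linspace(1e-3 * np.std(y), 6 * np.std(y), n_sig)
    # reference prior p(sigma^2) ~ 1/sigma^2, i.e. p(sigma) ~ 1/sigma
    ll0 = -0.5 * syy / sig ** 2 - (n - 1) * np.log(sig) - np.log(sig)
    mx0 = ll0.max()
    m0 = np.trapezoid(np.exp(ll0 - mx0), sig)

    def bf_given_g(g):
        prior_sd = np.sqrt(g / sxx)  # slope prior SD per unit sigma
        bhat = sxy / sxx
        # integrand support: prior (small g) and likelihood (large g) widths
        like_w = 6 * np.std(y) / np.sqrt(sxx)
        half = 8 * min(prior_sd * 6 * np.std(y), like_w) + 8 * like_w + 2 * abs(bhat)
        beta = np.linspace(bhat - half, bhat + half, n_beta)
        B, S = np.meshgrid(beta, sig, indexing="ij")
        rss = syy - 2 * B * sxy + B ** 2 * sxx
        ll = (
            -0.5 * rss / S ** 2
            - (n - 1) * np.log(S)
            - 0.5 * B ** 2 / (prior_sd ** 2 * S ** 2)
            - np.log(prior_sd * S)
            - 0.5 * np.log(2 * np.pi)
            - np.log(S)
        )
        mx = ll.max()
        m1 = np.trapezoid(np.trapezoid(np.exp(ll - mx), sig, axis=1), beta)
        return (m1 / m0) * np.exp(mx - mx0)

    a = n * rscale ** 2 / 2
    # log-spaced g grid; integrand ~ g^{-3/2} in the tail
    gs = np.logspace(-4, 5, n_g)
    ig = np.exp(0.5 * np.log(a) - 1.5 * np.log(gs) - a / gs) / np.sqrt(np.pi)
    bfs = np.array([bf_given_g(g) for g in gs])
    return np.trapezoid(bfs * ig, gs)
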