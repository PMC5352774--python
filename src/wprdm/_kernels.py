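"""Numba kernels for the Wiener first-passage problem.

All kernels work on the unit-noise scale: callers rescale drift and boundary
by the diffusion coefficient before dispatching.  Decision times are in
seconds; densities are per second.
"""

import numpy as np
from numba import njit

_SQRT_2PI = np.sqrt(2.0 * np.pi)

# Broadie-Glasserman-Kou barrier-shift constant (zeta(1/2)/sqrt(2*pi)).
BGK_BETA = 0.5826


@njit(cache=True)
def _std_fpt_density(u, w, eps):
    """Density of standardized (drift 0, boundary 1) lower-bound FPT at time u.

    Switches between the small-time and large-time series, keeping whichever
    needs fewer terms for truncation error below ``eps``.
    """
    if u <= 0.0:
        return 0.0
    # terms needed by the small-time expansion
    if 2.0 * _SQRT_2PI * np.sqrt(u) * eps < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * u * np.log(2.0 * eps * _SQRT_2PI * np.sqrt(u)))
        if ks < np.sqrt(u) + 1.0:
            ks = np.sqrt(u) + 1.0
    else:
        ks = 2.0
    # terms needed by the large-time expansion
    if np.pi * u * eps < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * u * eps) / (np.pi * np.pi * u))
        if kl < 1.0 / (np.pi * np.sqrt(u)):
            kl = 1.0 / (np.pi * np.sqrt(u))
    else:
        kl = 1.0 / (np.pi * np.sqrt(u))

    if ks < kl:  # small-time series
        K = int(np.ceil(ks))
        lo = -(K - 1) // 2
        hi = (K - 1) // 2 + (K - 1) % 2
        acc = 0.0
        for k in range(lo, hi + 1):
            wk = w + 2.0 * k
            acc += wk * np.exp(-wk * wk / (2.0 * u))
        dens = acc / np.sqrt(2.0 * np.pi * u ** 3)
    else:  # large-time series
        K = int(np.ceil(kl))
        acc = 0.0
        for k in range(1, K + 1):
            acc += k * np.exp(-k * k * np.pi * np.pi * u / 2.0) * np.sin(k * np.pi * w)
        dens = np.pi * acc
    if dens < 0.0:
        dens = 0.0  # truncation can leave a tiny negative residue in the far tail
    return dens


@njit(cache=True)
def wiener_logpdf_scalar(t_dec, v, a, w, upper, eps):
    """Log FPT density at decision time ``t_dec`` for the named boundary.

    ``upper`` selects the absorbing bound; unit within-trial noise.
    Returns -inf for non-positive decision times.
    """
    if t_dec <= 0.0:
        return -np.inf
    if upper:
        v = -v
        w = 1.0 - w
    u = t_dec / (a * a)
    dens = _std_fpt_density(u, w, eps)
    if dens <= 0.0:
        return -745.0 - v * a * w - v * v * t_dec / 2.0  # log of ~5e-324 guard
    return np.log(dens) - 2.0 * np.log(a) - v * a * w - v * v * t_dec / 2.0


@njit(cache=True)
def wiener_logpdf_arr(t_dec, v, a, w, upper, eps):
    n = t_dec.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = wiener_logpdf_scalar(t_dec[i], v[i], a[i], w[i], upper[i], eps)
    return out


@njit(cache=True)
def participant_loglik(rt, upper, pidx, n_p, v, a, tau, w, eps):
    """Summed Wiener log-likelihood per participant.

    ``rt``, ``upper``, ``pidx`` are trial-level arrays; ``v``, ``a``, ``tau``
    are per-participant arrays indexed by ``pidx``; ``w`` is the common start
    fraction.  A trial with rt <= tau drives its participant to -inf.
    """
    out = np.zeros(n_p)
    for i in range(rt.shape[0]):
        p = pidx[i]
        if not np.isfinite(out[p]):
            continue
        t_dec = rt[i] - tau[p]
        if t_dec <= 0.0:
            out[p] = -np.inf
            continue
        out[p] += wiener_logpdf_scalar(t_dec, v[p], a[p], w, upper[i], eps)
    return out


@njit(cache=True)
def simulate_paths(n, v, a, w, tau, sv, noise_sd, dt, seed, t_max):
    """Euler-Maruyama first-passage simulation with BGK barrier correction.

    Discrete monitoring of a continuous barrier systematically under-detects
    crossings; shifting both barriers inward by ``BGK_BETA * noise_sd *
    sqrt(dt)`` removes the O(sqrt(dt)) bias.  Returns (rt, upper, timed_out).
    """
    np.random.seed(seed)
    rt = np.empty(n)
    upper = np.empty(n, dtype=np.bool_)
    timed_out = np.zeros(n, dtype=np.bool_)
    c = BGK_BETA * noise_sd * np.sqrt(dt)
    hi = a - c
    lo = c
    sq = noise_sd * np.sqrt(dt)
    for i in range(n):
        vi = v
        if sv > 0.0:
            vi = v + sv * np.random.normal()
        x = w * a
        t = 0.0
        while True:
            x += vi * dt + sq * np.random.normal()
            t += dt
            if x >= hi:
                rt[i] = t + tau
                upper[i] = True
                break
            if x <= lo:
                rt[i] = t + tau
                upper[i] = False
                break
            if t >= t_max:
                rt[i] = t + tau
                upper[i] = x >= w * a
                timed_out[i] = True
                break
    return rt, upper, timed_out
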