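"""Bayesian tests of the worst performance rule on quantile correlations.

The observed quantities are sample Pearson correlations r_i between WMC and
the RT quantile at level I_i.  On Fisher's z scale these are treated as
independent normals: atanh(r_i) ~ N(atanh(rho_i), 1/(n-3)), with the linear
WPR model rho_i = beta0 + beta1 * I_i.  The confirmatory (constrained) prior
puts beta0, beta1 ~ U(-1, 0) independently; the exploratory variant releases
both to U(-1, 1).  In either mode the joint prior is truncated to parameter
pairs whose implied rho_i all stay inside (-1, 1).  Evidence for a zero
slope is quantified by the Savage-Dickey ratio at beta1 = 0 with a
truncation-aware prior ordinate; since 0 is an edge of the constrained
support, posterior ordinates use the reflected kernel estimator.

The difficulty-difference model couples the easy and hard curves: the slope
magnitudes beta1*_c in (0, 1) are probit-orthogonalized,
Phi^-1(beta1*_hard) = mu + delta/2 and Phi^-1(beta1*_easy) = mu - delta/2,
with mu ~ N(0, 1) and delta a folded standard normal, so a single parameter
delta carries the "harder shows a stronger WPR" hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import special, stats

from .bayes_eval import BayesFactorResult
from .data_io import CorrelationCurve, QuantileMatrix, correlation_curve

__all__ = [
    "MCMCConfig",
    "WPRPosterior",
    "ProbitDiffPosterior",
    "DiagnosticsError",
    "fit_wpr_h1",
    "fit_wpr_h2",
    "caution_subgroup_wpr",
    "h1_prior_slope_ordinate",
    "h2_prior_delta_ordinate",
]


class DiagnosticsError(RuntimeError):
    """MCMC did not pass its convergence gate."""


@dataclass(frozen=True)
class MCMCConfig:
    """Ensemble-sampler settings; defaults sized for the 2-4-dim WPR models.

    ``ensembles`` independent affine-invariant ensembles are run from
    different seeds; the convergence gate computes R-hat across ensembles,
    treating each ensemble's pooled draws as one chain.
    """

    walkers: int = 16
    steps: int = 1000  # kept steps per walker
    burn: int = 750
    ensembles: int = 4
    seed: int = 0
    rhat_threshold: float = 1.01
    check_convergence: bool = True


@dataclass(frozen=True)
class WPRPosterior:
    """Posterior for the linear WPR model on one correlation curve."""

    levels: tuple[float, ...]
    beta0: np.ndarray
    beta1: np.ndarray
    bf_slope: BayesFactorResult
    constrained: bool
    n: int
    rhat: dict
    curve: CorrelationCurve | None = None

    def implied_rho(self) -> np.ndarray:
        """Posterior samples of rho_i per level (samples x levels)."""
        I = np.asarray(self.levels)
        return self.beta0[:, None] + self.beta1[:, None] * I[None, :]

    def summary(self) -> dict:
        return {
            "beta0_mean": float(np.mean(self.beta0)),
            "beta1_mean": float(np.mean(self.beta1)),
            "beta1_ci95": [
                float(np.quantile(self.beta1, 0.025)),
                float(np.quantile(self.beta1, 0.975)),
            ],
            "p_beta1_negative": float(np.mean(self.beta1 < 0)),
            "bf10": self.bf_slope.bf10,
            "bf01": self.bf_slope.bf01,
            "constrained": self.constrained,
            "n": self.n,
            "rhat": self.rhat,
        }


@dataclass(frozen=True)
class ProbitDiffPosterior:
    """Posterior for the probit-orthogonalized difficulty difference."""

    mu: np.ndarray
    delta: np.ndarray
    beta0_easy: np.ndarray
    beta0_hard: np.ndarray
    bf_delta: BayesFactorResult
    rhat: dict

    @property
    def beta1_star_hard(self) -> np.ndarray:
        return stats.norm.cdf(self.mu + self.delta / 2)

    @property
    def beta1_star_easy(self) -> np.ndarray:
        return stats.norm.cdf(self.mu - self.delta / 2)

    def summary(self) -> dict:
        return {
            "mu_mean": float(np.mean(self.mu)),
            "delta_mean": float(np.mean(self.delta)),
            "delta_ci95": [
                float(np.quantile(self.delta, 0.025)),
                float(np.quantile(self.delta, 0.975)),
            ],
            "bf10": self.bf_delta.bf10,
            "bf01": self.bf_delta.bf01,
            "rhat": self.rhat,
        }


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def _box(constrained: bool) -> tuple[float, float]:
    """Support of beta0 and beta1 (same box for both)."""
    return (-1.0, 0.0) if constrained else (-1.0, 1.0)


def _admissible_beta0_interval(beta1: float, levels, box) -> tuple[float, float]:
    """beta0 range keeping every rho_i = beta0 + beta1*I_i inside (-1, 1)."""
    lo, hi = box
    for I in levels:
        lo = max(lo, -1.0 - beta1 * I)
        hi = min(hi, 1.0 - beta1 * I)
    return lo, hi


def h1_prior_slope_ordinate(
    levels=(1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6), constrained: bool = True,
    grid: int = 20001,
) -> float:
    """Marginal prior density of beta1 at 0 under the truncated uniform prior.

    Computed by quadrature of the admissible region: for the default five
    levels and the constrained box this equals 12/7.
    """
    box = _box(constrained)
    b1 = np.linspace(box[0], box[1], grid)
    lengths = np.array(
        [max(0.0, np.subtract(*_admissible_beta0_interval(b, levels, box)[::-1]))
         for b in b1]
    )
    area = np.trapezoid(lengths, b1)
    len0 = max(0.0, np.subtract(*_admissible_beta0_interval(0.0, levels, box)[::-1]))
    return float(len0 / area)


def h2_prior_delta_ordinate(levels=(1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6)) -> float:
    """Truncation-aware marginal prior density of delta at 0.

    Without the admissibility truncation this is the folded-normal mode
    2*phi(0) ~= 0.7979; the truncation (each beta0_c must keep all rho_ic
    above -1, shrinking its admissible length to 1 - max(I)*beta1*_c)
    reweights the (mu, delta) prior slightly.  Evaluated by 2-D quadrature.
    """
    if len(levels) == 0:  # no likelihood, no truncation
        return float(2 * stats.norm.pdf(0.0))
    lmax = max(levels)
    mu = np.linspace(-8, 8, 1601)
    de = np.linspace(0, 8, 801)
    M, D = np.meshgrid(mu, de, indexing="ij")
    G = (1 - lmax * stats.norm.cdf(M + D / 2)) * (1 - lmax * stats.norm.cdf(M - D / 2))
    w = stats.norm.pdf(M) * 2 * stats.norm.pdf(D)
    Z = np.trapezoid(np.trapezoid(w * G, de, axis=1), mu)
    num = np.trapezoid(
        stats.norm.pdf(mu) * (1 - lmax * stats.norm.cdf(mu)) ** 2, mu
    ) * 2 * stats.norm.pdf(0.0)
    return float(num / Z)


# ---------------------------------------------------------------------------
# Rao-Blackwellised posterior ordinates
# ---------------------------------------------------------------------------


def _thin(x: np.ndarray, k: int) -> np.ndarray:
    if len(x) <= k:
        return x
    idx = np.linspace(0, len(x) - 1, k).astype(int)
    return x[idx]


def _decorrelation_slope(other: np.ndarray, test: np.ndarray) -> float:
    """Coefficient k such that other - k*test is uncorrelated with test."""
    v = np.var(test)
    if v == 0:
        return 0.0
    return float(np.cov(other, test)[0, 1] / v)


def _h1_posterior_slope_ordinate(
    samples, levels, z, sd, box, n_thin=2000, n_grid=1601
) -> float:
    """Posterior density of beta1 at 0 by Rao-Blackwellisation.

    The 1-D conditional density of beta1 is integrated on a grid and its
    normalised ordinate at 0 averaged over posterior draws.  Conditioning is
    on the linear combination u = beta0 + k*beta1 that is uncorrelated with
    beta1 in the posterior, so the conditional ordinate varies little across
    draws and the estimate is low-variance and free of boundary bias.
    """
    b0s, b1s = samples[:, 0], samples[:, 1]
    k = _decorrelation_slope(b0s, b1s)
    u = _thin(b0s - k * b1s, n_thin)
    b1 = np.linspace(box[0], box[1], n_grid)
    b0 = u[:, None] + k * b1[None, :]
    levels = np.asarray(levels, dtype=float)
    adm = (b0 > box[0]) & (b0 < box[1])
    if levels.size:
        rho = b0[:, :, None] + b1[None, :, None] * levels[None, None, :]
        adm &= np.all(np.abs(rho) < 1, axis=2)
        rho_c = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
        ll = -0.5 * np.sum(((z - np.arctanh(rho_c)) / sd) ** 2, axis=2)
        ll -= ll.max(axis=1, keepdims=True)
        w = np.where(adm, np.exp(ll), 0.0)
    else:
        w = adm.astype(float)
    norm = np.trapezoid(w, b1, axis=1)
    i0 = int(np.argmin(np.abs(b1)))
    cond = w[:, i0] / norm
    return float(np.mean(cond))


def _h2_posterior_delta_ordinate(
    samples, levels, data, n_thin=1500, n_grid=901, d_max=6.0
) -> float:
    """Posterior density of delta at 0, Rao-Blackwellised over draws.

    Conditions on linear combinations of (mu, beta0_easy, beta0_hard) made
    uncorrelated with delta, as in the slope ordinate.
    """
    keep = _thin(samples, n_thin)
    de_s = keep[:, 1]
    ks = [_decorrelation_slope(keep[:, j], de_s) for j in (0, 2, 3)]
    us = [keep[:, j] - ks[i] * de_s for i, j in enumerate((0, 2, 3))]
    de = np.linspace(0.0, d_max, n_grid)
    mu = us[0][:, None] + ks[0] * de[None, :]
    b0e = us[1][:, None] + ks[1] * de[None, :]
    b0d = us[2][:, None] + ks[2] * de[None, :]
    levels = np.asarray(levels, dtype=float)
    lw = -0.5 * mu ** 2 - 0.5 * de[None, :] ** 2  # N(0,1) x folded-N(0,1)
    adm = (b0e > -1) & (b0e < 0) & (b0d > -1) & (b0d < 0)
    if levels.size:
        for b0, sign, cond in ((b0e, -1.0, 0), (b0d, +1.0, 1)):
            z, sd = data[cond]
            bstar = special.ndtr(mu + sign * de[None, :] / 2)
            rho = b0[:, :, None] - bstar[:, :, None] * levels[None, None, :]
            adm &= np.all(np.abs(rho) < 1, axis=2)
            rho_c = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
            lw += -0.5 * np.sum(((z - np.arctanh(rho_c)) / sd) ** 2, axis=2)
    lw -= lw.max(axis=1, keepdims=True)
    w = np.where(adm, np.exp(lw), 0.0)
    norm = np.trapezoid(w, de, axis=1)
    ok = norm > 0
    cond_dens = w[ok, 0] / norm[ok]
    return float(np.mean(cond_dens))


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _run_emcee(log_prob, ndim, draw, cfg: MCMCConfig, param_names):
    chains = []
    for e in range(cfg.ensembles):
        seed = (cfg.seed * 1009 + e) % (2**32 - 1)
        init = _init_in_region(seed, cfg.walkers, ndim, log_prob, draw)
        sampler = emcee.EnsembleSampler(cfg.walkers, ndim, log_prob)
        sampler.random_state = np.random.RandomState(seed).get_state()
        sampler.run_mcmc(init, cfg.burn + cfg.steps, progress=False)
        chain = sampler.get_chain(discard=cfg.burn)  # (steps, walkers, ndim)
        # flatten step-major so early/late halves stay distinct for split-Rhat
        chains.append(chain.reshape(-1, ndim))
    stacked = np.stack(chains)  # (ensembles, draws, ndim)
    rhat = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(param_names):
            rhat[name] = float(az.rhat(az.convert_to_dataset(stacked[:, :, j]))["x"])
    if cfg.check_convergence:
        bad = {k: v for k, v in rhat.items() if not (v < cfg.rhat_threshold)}
        if bad:
            raise DiagnosticsError(f"R-hat above {cfg.rhat_threshold}: {bad}")
    return stacked.reshape(-1, ndim), rhat


def _init_in_region(seed, walkers, ndim, log_prob, draw, max_tries=100000):
    rng = np.random.default_rng(seed + 10007)
    init = np.empty((walkers, ndim))
    k = 0
    for _ in range(max_tries):
        x = draw(rng)
        if np.isfinite(log_prob(x)):
            # tiny jitter breaks ties between identical draws
            xj = x + rng.normal(scale=1e-4, size=ndim)
            init[k] = xj if np.isfinite(log_prob(xj)) else x
            k += 1
            if k == walkers:
                return init
    raise RuntimeError("could not initialise walkers inside the prior support")


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------


def fit_wpr_h1(
    curve: CorrelationCurve,
    constrained: bool = True,
    mcmc_config: MCMCConfig | None = None,
) -> WPRPosterior:
    """Fit the linear WPR model to one correlation curve.

    With an empty curve the likelihood is flat and the posterior reproduces
    the prior, so the slope Bayes factor is 1 up to kernel error.
    """
    cfg = mcmc_config or MCMCConfig()
    levels = np.asarray(curve.levels, dtype=float)
    has_data = levels.size > 0
    if has_data:
        r = np.asarray(curve.r, dtype=float)
        if np.any(np.abs(r) >= 1):
            raise ValueError("Fisher transform undefined for |r| = 1")
        if curve.n < 10:
            raise ValueError(f"need n >= 10 participants, have {curve.n}")
        z = np.arctanh(r)
        sd = 1.0 / np.sqrt(curve.n - 3)
    box = _box(constrained)

    def log_prob(theta):
        b0, b1 = theta
        if not (box[0] < b0 < box[1] and box[0] < b1 < box[1]):
            return -np.inf
        rho = b0 + b1 * levels
        if np.any(np.abs(rho) >= 1):
            return -np.inf
        if not has_data:
            return 0.0
        return float(-0.5 * np.sum(((z - np.arctanh(rho)) / sd) ** 2))

    def draw(rng):
        return rng.uniform(box[0], box[1], size=2)

    samples, rhat = _run_emcee(log_prob, 2, draw, cfg, ["beta0", "beta1"])
    prior_ord = h1_prior_slope_ordinate(tuple(levels), constrained=constrained)
    post_ord = _h1_posterior_slope_ordinate(
        samples, levels,
        z if has_data else None, sd if has_data else None, box,
    )
    bf = BayesFactorResult(
        bf10=prior_ord / post_ord,
        prior_ordinate=prior_ord,
        posterior_ordinate=post_ord,
        estimator="rao-blackwell-conditional-density",
        n_samples=len(samples),
    )
    return WPRPosterior(
        levels=tuple(levels),
        beta0=samples[:, 0],
        beta1=samples[:, 1],
        bf_slope=bf,
        constrained=constrained,
        n=int(curve.n),
        rhat=rhat,
        curve=curve,
    )


def fit_wpr_h2(
    curve_easy: CorrelationCurve,
    curve_hard: CorrelationCurve,
    mcmc_config: MCMCConfig | None = None,
) -> ProbitDiffPosterior:
    """Joint fit of both curves with the probit-orthogonalized difference.

    Parameters: theta = (mu, delta, beta0_easy, beta0_hard) with slopes
    beta1_c = -Phi(mu -/+ delta/2) (minus for easy).  BF01 for delta = 0 via
    Savage-Dickey with the truncation-aware prior ordinate.
    """
    cfg = mcmc_config or MCMCConfig()
    if tuple(curve_easy.levels) != tuple(curve_hard.levels):
        raise ValueError("easy and hard curves must share quantile levels")
    levels = np.asarray(curve_easy.levels, dtype=float)
    has_data = levels.size > 0
    if has_data:
        data = []
        for c in (curve_easy, curve_hard):
            r = np.asarray(c.r, dtype=float)
            if np.any(np.abs(r) >= 1):
                raise ValueError("Fisher transform undefined for |r| = 1")
            data.append((np.arctanh(r), 1.0 / np.sqrt(c.n - 3)))

    def log_prob(theta):
        mu, delta, b0e, b0d = theta
        if delta < 0 or not (-1 < b0e < 0 and -1 < b0d < 0):
            return -np.inf
        lp = -0.5 * (mu * mu + delta * delta)  # N(0,1) x folded-N(0,1), up to consts
        b1 = (-special.ndtr(mu - delta / 2), -special.ndtr(mu + delta / 2))
        ll = 0.0
        for (b0, b1c), cond_idx in zip(((b0e, b1[0]), (b0d, b1[1])), (0, 1)):
            rho = b0 + b1c * levels
            if np.any(np.abs(rho) >= 1):
                return -np.inf
            if has_data:
                zc, sdc = data[cond_idx]
                ll += -0.5 * np.sum(((zc - np.arctanh(rho)) / sdc) ** 2)
        return float(lp + ll)

    def draw(rng):
        return np.array(
            [
                rng.normal(),
                abs(rng.normal()),
                rng.uniform(-1, 0),
                rng.uniform(-1, 0),
            ]
        )

    samples, rhat = _run_emcee(
        log_prob, 4, draw, cfg, ["mu", "delta", "beta0_easy", "beta0_hard"]
    )
    prior_ord = h2_prior_delta_ordinate(tuple(levels))
    post_ord = _h2_posterior_delta_ordinate(
        samples, levels, data if has_data else None
    )
    bf = BayesFactorResult(
        bf10=prior_ord / post_ord,
        prior_ordinate=prior_ord,
        posterior_ordinate=post_ord,
        estimator="rao-blackwell-conditional-density",
        n_samples=len(samples),
    )
    return ProbitDiffPosterior(
        mu=samples[:, 0],
        delta=samples[:, 1],
        beta0_easy=samples[:, 2],
        beta0_hard=samples[:, 3],
        bf_delta=bf,
        rhat=rhat,
    )


# ---------------------------------------------------------------------------
# caution subgroups
# ---------------------------------------------------------------------------


def assign_caution_deciles(boundary_estimates: pd.Series) -> pd.Series:
    """Split participants into 10 groups at the .1-.9 quantiles of caution.

    Group g contains participants whose boundary estimate falls between the
    g/10 and (g+1)/10 empirical quantiles (right-closed cuts).
    """
    est = boundary_estimates.astype(float)
    cuts = np.quantile(est.to_numpy(), np.arange(1, 10) / 10)
    groups = np.searchsorted(cuts, est.to_numpy(), side="left")
    return pd.Series(groups, index=est.index, name="caution_group")


def caution_subgroup_wpr(
    qm_easy: QuantileMatrix,
    qm_hard: QuantileMatrix,
    wmc: pd.DataFrame,
    boundary_estimates: pd.Series,
    constrained: bool = True,
    mcmc_config: MCMCConfig | None = None,
    min_group_size: int = 10,
) -> tuple[dict, pd.DataFrame, list[str]]:
    """Rerun the H1 test within ten homogeneous-caution subgroups.

    Returns ``(fits, summary, warnings)`` where ``fits[(group, condition)]``
    holds each subgroup's WPRPosterior and ``summary`` tabulates slopes and
    Bayes factors.  Groups smaller than ``min_group_size`` are skipped.
    """
    cfg = mcmc_config or MCMCConfig()
    missing = [
        p for qm in (qm_easy, qm_hard) for p in qm.values.index
        if p not in boundary_estimates.index
    ]
    if missing:
        raise ValueError(
            f"boundary estimates missing for participants: {sorted(set(missing))[:10]}"
        )
    groups = assign_caution_deciles(boundary_estimates)
    fits: dict = {}
    rows = []
    warns: list[str] = []
    for g in range(10):
        members = groups.index[groups == g]
        if len(members) < min_group_size:
            warns.append(f"caution group {g} skipped ({len(members)} participants)")
            continue
        for cond, qm in (("easy", qm_easy), ("hard", qm_hard)):
            keep = [p for p in qm.values.index if p in set(members)]
            sub = QuantileMatrix(
                levels=qm.levels,
                values=qm.values.loc[keep],
                condition=qm.condition,
                n_trials_used=qm.n_trials_used.reindex(keep),
            )
            try:
                curve = correlation_curve(sub, wmc)
                fit = fit_wpr_h1(curve, constrained=constrained, mcmc_config=cfg)
            except (ValueError, DiagnosticsError) as err:
                warns.append(f"group {g} {cond}: {err}")
                continue
            fits[(g, cond)] = fit
            rows.append(
                {
                    "group": g,
                    "condition": cond,
                    "n": curve.n,
                    "beta1_mean": float(np.mean(fit.beta1)),
                    "bf10": fit.bf_slope.bf10,
                    "bf01": fit.bf_slope.bf01,
                }
            )
    summary = pd.DataFrame(rows)
    return fits, summary, warns
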