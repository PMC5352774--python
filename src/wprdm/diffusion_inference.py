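"""Hierarchical Bayesian diffusion fits with WMC in the population model.

The fitted likelihood is the 4-parameter Wiener first-passage density
(drift, boundary separation, start fraction fixed at 0.5, non-decision
time).  Easy/hard trials are accuracy-coded: the upper boundary is the
correct response and the participant's drift for that difficulty points
toward it.  Undoable 50/50 trials, which carry no correct answer, are
response-coded with their own drift centred near zero; they share the
participant's boundary and non-decision time and thereby sharpen those
estimates.

WMC enters as an observed variable in the population model: for the
single-condition fit, (nu_p, WMC_p) is bivariate normal with correlation
rho ~ U(0, 1) under the alternative, which makes the per-participant drift
prior the conditional normal
    nu_p | w_p ~ N(mu_nu + rho * sigma_nu * w_p, sigma_nu^2 (1 - rho^2)),
with WMC standardized within the analysis.  The joint fit models
(nu_easy, nu_hard, WMC) as trivariate normal with the two drift-WMC
correlations probit-orthogonalized, rho_hard = Phi(mu + delta/2) and
rho_easy = Phi(mu - delta/2), a free drift-drift correlation, and
positive-definiteness enforced by rejection.

Sampling is adaptive Metropolis-within-Gibbs: per-participant random-walk
updates vectorised across participants (drift; a joint boundary/ndt block),
then random-walk updates of the group-level parameters.  Proposal scales
adapt toward standard acceptance targets during warmup and are frozen
afterwards.  Savage-Dickey Bayes factors use the reflected-KDE posterior
ordinate at the boundary of the correlation support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import special, stats

from ._kernels import participant_loglik
from .bayes_eval import BayesFactorResult, savage_dickey_bf
from .data_io import validate_trials, validate_wmc
from .wiener_core import SERIES_EPS
from .wpr_inference import DiagnosticsError

__all__ = [
    "DiffusionMCMCConfig",
    "HierarchicalDiffusionPosterior",
    "JointDiffusionPosterior",
    "fit_hierarchical_diffusion",
    "fit_joint_diffusion",
    "joint_prior_delta_ordinate",
]


@dataclass(frozen=True)
class DiffusionMCMCConfig:
    """Gibbs-sampler settings for the hierarchical diffusion models."""

    chains: int = 2
    warmup: int = 600
    draws: int = 1000
    group_reps: int = 3  # group-level update repetitions per sweep
    seed: int = 0
    rhat_threshold: float = 1.05
    check_convergence: bool = True


# group-level prior hyperparameters (documented defaults)
_PRIOR = {
    "mu_nu": (2.0, 3.0),  # normal
    "sigma_nu": 2.0,  # half-normal scale
    "mu_alpha": (1.5, 1.0),  # normal truncated > 0
    "sigma_alpha": 1.0,
    "mu_tau": (0.3, 0.3),  # normal truncated > 0
    "sigma_tau": 0.5,
    "mu_nu_u": (0.0, 1.0),
    "sigma_nu_u": 1.0,
}

_ALPHA_FLOOR = 0.05
_TAU_FLOOR = 0.005


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class _TrialBlock:
    rt: np.ndarray
    upper: np.ndarray
    pidx: np.ndarray

    @property
    def n(self) -> int:
        return len(self.rt)


def _prepare(trials: pd.DataFrame, wmc: pd.DataFrame, conditions: list[str]):
    """Validated arrays for the sampler; returns (ids, w_std, blocks, min_rt)."""
    trials = validate_trials(trials)
    wmc = validate_wmc(wmc)
    trials = trials[~trials["censored"]]
    if (trials["rt"] <= 0).any():
        raise ValueError("non-positive RT after validation")
    used = trials[trials["condition"].isin(conditions + ["undoable"])]
    ids = sorted(set(used["participant_id"]) & set(wmc["participant_id"]))
    if len(ids) < 4:
        raise ValueError(f"need >= 4 participants with trials and WMC, have {len(ids)}")
    id_index = {p: i for i, p in enumerate(ids)}
    used = used[used["participant_id"].isin(id_index)]

    w = wmc.set_index("participant_id")["wmc"].reindex(ids).to_numpy(dtype=float)
    w_mean, w_sd = float(np.mean(w)), float(np.std(w, ddof=1))
    if w_sd == 0:
        raise ValueError("zero variance in WMC")
    w_std = (w - w_mean) / w_sd

    blocks: dict[str, _TrialBlock] = {}
    for cond in conditions + ["undoable"]:
        sub = used[used["condition"] == cond]
        if len(sub) == 0:
            continue
        if cond == "undoable":
            upper = (sub["response_side"] == "right").to_numpy()
        else:
            corr = sub["correct"]
            if corr.isna().any():
                raise ValueError(f"missing correct flags in condition {cond}")
            upper = corr.to_numpy(dtype=bool)
        blocks[cond] = _TrialBlock(
            rt=sub["rt"].to_numpy(dtype=float),
            upper=upper,
            pidx=sub["participant_id"].map(id_index).to_numpy(dtype=np.int64),
        )
    for cond in conditions:
        if cond not in blocks:
            raise ValueError(f"no usable trials in condition {cond!r}")
    min_rt = np.full(len(ids), np.inf)
    np.minimum.at(
        min_rt,
        used["participant_id"].map(id_index).to_numpy(dtype=np.int64),
        used["rt"].to_numpy(dtype=float),
    )
    if not np.all(np.isfinite(min_rt)):
        raise ValueError("some participants have no usable trials")
    return ids, w_std, (w_mean, w_sd), blocks, min_rt


def _ez_init(block: _TrialBlock, n_p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EZ-style moment estimates of (drift, boundary, ndt) per participant."""
    v = np.full(n_p, 1.0)
    a = np.full(n_p, 1.5)
    ter = np.full(n_p, 0.25)
    for p in range(n_p):
        sel = block.pidx == p
        if not sel.any():
            continue
        rts = block.rt[sel]
        pc = (block.upper[sel].sum() + 0.5) / (sel.sum() + 1.0)
        pc = min(max(pc, 0.52), 0.98)
        vrt = np.var(rts[block.upper[sel]]) if block.upper[sel].sum() > 2 else np.var(rts)
        vrt = max(vrt, 1e-3)
        L = np.log(pc / (1 - pc))
        x = L * (pc * pc * L - pc * L + pc - 0.5) / vrt
        if x > 0:
            v[p] = np.sign(pc - 0.5) * x ** 0.25
            a[p] = L / v[p]
            ex = np.exp(-v[p] * a[p])
            mdt = (a[p] / (2 * v[p])) * (1 - ex) / (1 + ex)
            ter[p] = np.mean(rts) - mdt
    a = np.clip(a, 0.3, 4.0)
    v = np.clip(v, -6.0, 8.0)
    return v, a, ter


# ---------------------------------------------------------------------------
# random-walk helpers
# ---------------------------------------------------------------------------


class _StepAdapter:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, scale: float, target: float):
        self.scale = scale
        self.target = target
        self.t = 0

    def update(self, acc_rate: float) -> None:
        self.t += 1
        gamma = min(0.25, 2.0 / self.t ** 0.6)
        self.scale *= float(np.exp(gamma * (acc_rate - self.target)))


def _half_normal_lp(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2 if x > 0 else -np.inf


def _trunc_normal_lp(x: float, mean: float, sd: float, positive: bool = True) -> float:
    if positive and x <= 0:
        return -np.inf
    return -0.5 * ((x - mean) / sd) ** 2


# ---------------------------------------------------------------------------
# single-condition hierarchical fit (H3)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HierarchicalDiffusionPosterior:
    """Posterior of the single-condition hierarchical diffusion model."""

    condition: str
    participant_ids: tuple[str, ...]
    group_samples: dict  # name -> (chains, draws) array
    bf_rho: BayesFactorResult
    alpha_mean: pd.Series
    alpha_sd: pd.Series
    nu_mean: pd.Series
    tau_mean: pd.Series
    rhat: dict
    wmc_standardization: tuple[float, float]

    @property
    def rho_samples(self) -> np.ndarray:
        return self.group_samples["rho"].ravel()

    def rho_interval(self, level: float = 0.95) -> tuple[float, float]:
        q = (1 - level) / 2
        s = self.rho_samples
        return float(np.quantile(s, q)), float(np.quantile(s, 1 - q))

    def summary(self) -> dict:
        s = self.rho_samples
        return {
            "condition": self.condition,
            "n_participants": len(self.participant_ids),
            "rho_mean": float(np.mean(s)),
            "rho_ci95": list(self.rho_interval()),
            "bf10": self.bf_rho.bf10,
            "bf01": self.bf_rho.bf01,
            "rhat": self.rhat,
            "group_means": {
                k: float(np.mean(v)) for k, v in self.group_samples.items()
            },
        }


def fit_hierarchical_diffusion(
    trials: pd.DataFrame,
    wmc: pd.DataFrame,
    condition: str,
    mcmc_config: DiffusionMCMCConfig | None = None,
) -> HierarchicalDiffusionPosterior:
    """Fit one difficulty condition with the drift-WMC correlation model.

    Undoable trials, when present, are included response-coded and inform
    each participant's boundary and non-decision time.
    """
    if condition not in ("easy", "hard"):
        raise ValueError("condition must be 'easy' or 'hard'")
    cfg = mcmc_config or DiffusionMCMCConfig()
    ids, w, w_ms, blocks, min_rt = _prepare(trials, wmc, [condition])
    n_p = len(ids)
    cond_block = blocks[condition]
    und_block = blocks.get("undoable")

    chains_out: list[dict] = []
    acc_alpha = np.zeros(n_p)
    acc_alpha_sq = np.zeros(n_p)
    acc_nu = np.zeros(n_p)
    acc_tau = np.zeros(n_p)
    n_acc = 0
    for chain in range(cfg.chains):
        rng = np.random.default_rng([cfg.seed, 7919, chain])
        state = _init_state(cond_block, und_block, n_p, w, min_rt, rng)
        draws = _run_single_chain(state, cond_block, und_block, w, min_rt, cfg, rng)
        chains_out.append(draws)
        acc_alpha += draws.pop("_alpha_sum")
        acc_alpha_sq += draws.pop("_alpha_sumsq")
        acc_nu += draws.pop("_nu_sum")
        acc_tau += draws.pop("_tau_sum")
        n_acc += cfg.draws

    group_samples = {
        k: np.stack([c[k] for c in chains_out])
        for k in ("mu_nu", "sigma_nu", "rho", "mu_alpha", "sigma_alpha",
                  "mu_tau", "sigma_tau")
        if k in chains_out[0]
    }
    rhat = _group_rhat(group_samples)
    if cfg.check_convergence:
        bad = {k: v for k, v in rhat.items() if not (v < cfg.rhat_threshold)}
        if bad:
            raise DiagnosticsError(
                f"R-hat above {cfg.rhat_threshold} for group parameters: {bad}"
            )
    rho_flat = group_samples["rho"].ravel()
    bf = savage_dickey_bf(rho_flat, 1.0, point=0.0, support=(0.0, 1.0))
    alpha_mean = acc_alpha / n_acc
    alpha_var = np.maximum(acc_alpha_sq / n_acc - alpha_mean ** 2, 0.0)
    return HierarchicalDiffusionPosterior(
        condition=condition,
        participant_ids=tuple(ids),
        group_samples=group_samples,
        bf_rho=bf,
        alpha_mean=pd.Series(alpha_mean, index=ids, name="alpha_mean"),
        alpha_sd=pd.Series(np.sqrt(alpha_var), index=ids, name="alpha_sd"),
        nu_mean=pd.Series(acc_nu / n_acc, index=ids, name="nu_mean"),
        tau_mean=pd.Series(acc_tau / n_acc, index=ids, name="tau_mean"),
        rhat=rhat,
        wmc_standardization=w_ms,
    )


def _init_state(cond_block, und_block, n_p, w, min_rt, rng) -> dict:
    v0, a0, t0 = _ez_init(cond_block, n_p)
    tau_hi = 0.95 * min_rt
    tau0 = np.clip(t0, _TAU_FLOOR * 2, tau_hi - 1e-4)
    state = {
        "nu": v0 + rng.normal(0, 0.1, n_p),
        "alpha": np.clip(a0 + rng.normal(0, 0.05, n_p), _ALPHA_FLOOR * 2, None),
        "tau": np.clip(tau0 + rng.normal(0, 0.01, n_p), _TAU_FLOOR, tau_hi - 1e-5),
        "nu_u": rng.normal(0, 0.1, n_p) if und_block is not None else None,
    }
    state["mu_nu"] = float(np.mean(state["nu"]))
    state["sigma_nu"] = float(np.std(state["nu"]) + 0.2)
    state["rho"] = float(rng.uniform(0.2, 0.8))
    state["mu_alpha"] = float(np.mean(state["alpha"]))
    state["sigma_alpha"] = float(np.std(state["alpha"]) + 0.1)
    state["mu_tau"] = float(np.mean(state["tau"]))
    state["sigma_tau"] = float(np.std(state["tau"]) + 0.03)
    if und_block is not None:
        state["mu_nu_u"] = 0.0
        state["sigma_nu_u"] = 0.5
    return state


def _loglik(block, v, a, tau, n_p):
    return participant_loglik(
        block.rt, block.upper, block.pidx, n_p, v, a, tau, 0.5, SERIES_EPS
    )


def _run_single_chain(state, cond_block, und_block, w, min_rt, cfg, rng) -> dict:
    n_p = len(w)
    tau_hi = 0.95 * min_rt
    steps = {
        "nu": _StepAdapter(0.25, 0.44),
        "nu_u": _StepAdapter(0.25, 0.44),
        "at": _StepAdapter(0.08, 0.3),
    }
    g_steps = {
        k: _StepAdapter(s, 0.44)
        for k, s in (
            ("mu_nu", 0.1), ("sigma_nu", 0.1), ("rho", 0.1),
            ("mu_alpha", 0.05), ("sigma_alpha", 0.05),
            ("mu_tau", 0.01), ("sigma_tau", 0.01),
            ("mu_nu_u", 0.1), ("sigma_nu_u", 0.1),
        )
    }

    ll_cond = _loglik(cond_block, state["nu"], state["alpha"], state["tau"], n_p)
    ll_und = (
        _loglik(und_block, state["nu_u"], state["alpha"], state["tau"], n_p)
        if und_block is not None
        else np.zeros(n_p)
    )

    total = cfg.warmup + cfg.draws
    out = {
        k: np.empty(cfg.draws)
        for k in ("mu_nu", "sigma_nu", "rho", "mu_alpha", "sigma_alpha",
                  "mu_tau", "sigma_tau")
    }
    a_sum = np.zeros(n_p)
    a_sumsq = np.zeros(n_p)
    nu_sum = np.zeros(n_p)
    tau_sum = np.zeros(n_p)

    def nu_prior_mean_var():
        m = state["mu_nu"] + state["rho"] * state["sigma_nu"] * w
        s2 = state["sigma_nu"] ** 2 * (1 - state["rho"] ** 2)
        return m, s2

    for sweep in range(total):
        warming = sweep < cfg.warmup

        # --- per-participant drift -------------------------------------
        m, s2 = nu_prior_mean_var()
        prop = state["nu"] + rng.normal(0, steps["nu"].scale, n_p)
        llp = _loglik(cond_block, prop, state["alpha"], state["tau"], n_p)
        dlp = (
            llp - ll_cond
            - 0.5 * ((prop - m) ** 2 - (state["nu"] - m) ** 2) / s2
        )
        acc = np.log(rng.random(n_p)) < dlp
        state["nu"][acc] = prop[acc]
        ll_cond[acc] = llp[acc]
        if warming:
            steps["nu"].update(float(np.mean(acc)))

        # --- undoable drift ---------------------------------------------
        if und_block is not None:
            prop = state["nu_u"] + rng.normal(0, steps["nu_u"].scale, n_p)
            llp = _loglik(und_block, prop, state["alpha"], state["tau"], n_p)
            dlp = (
                llp - ll_und
                - 0.5
                * ((prop - state["mu_nu_u"]) ** 2 - (state["nu_u"] - state["mu_nu_u"]) ** 2)
                / state["sigma_nu_u"] ** 2
            )
            acc = np.log(rng.random(n_p)) < dlp
            state["nu_u"][acc] = prop[acc]
            ll_und[acc] = llp[acc]
            if warming:
                steps["nu_u"].update(float(np.mean(acc)))

        # --- joint boundary / non-decision block ------------------------
        sc = steps["at"].scale
        prop_a = state["alpha"] + rng.normal(0, sc, n_p)
        prop_t = state["tau"] + rng.normal(0, sc * 0.25, n_p)
        ok = (prop_a > _ALPHA_FLOOR) & (prop_t > _TAU_FLOOR) & (prop_t < tau_hi)
        prop_a = np.where(ok, prop_a, state["alpha"])
        prop_t = np.where(ok, prop_t, state["tau"])
        llp_c = _loglik(cond_block, state["nu"], prop_a, prop_t, n_p)
        if und_block is not None:
            llp_u = _loglik(und_block, state["nu_u"], prop_a, prop_t, n_p)
        else:
            llp_u = np.zeros(n_p)
        dlp = (
            llp_c - ll_cond + llp_u - ll_und
            - 0.5
            * ((prop_a - state["mu_alpha"]) ** 2 - (state["alpha"] - state["mu_alpha"]) ** 2)
            / state["sigma_alpha"] ** 2
            - 0.5
            * ((prop_t - state["mu_tau"]) ** 2 - (state["tau"] - state["mu_tau"]) ** 2)
            / state["sigma_tau"] ** 2
        )
        acc = ok & (np.log(rng.random(n_p)) < dlp)
        state["alpha"][acc] = prop_a[acc]
        state["tau"][acc] = prop_t[acc]
        ll_cond[acc] = llp_c[acc]
        ll_und[acc] = llp_u[acc]
        if warming:
            steps["at"].update(float(np.mean(acc)))

        # --- group level -------------------------------------------------
        for _ in range(cfg.group_reps):
            _update_nu_group(state, w, g_steps, rng, warming)
            _update_pos_group(
                state, state["alpha"], "mu_alpha", "sigma_alpha",
                _PRIOR["mu_alpha"], _PRIOR["sigma_alpha"],
                np.zeros(n_p), np.full(n_p, np.inf), g_steps, rng, warming,
            )
            _update_pos_group(
                state, state["tau"], "mu_tau", "sigma_tau",
                _PRIOR["mu_tau"], _PRIOR["sigma_tau"],
                np.zeros(n_p), tau_hi, g_steps, rng, warming,
            )
            if und_block is not None:
                _update_plain_group(state, g_steps, rng, warming)

        if not warming:
            i = sweep - cfg.warmup
            for k in out:
                out[k][i] = state[k]
            a_sum += state["alpha"]
            a_sumsq += state["alpha"] ** 2
            nu_sum += state["nu"]
            tau_sum += state["tau"]

    out["_alpha_sum"] = a_sum
    out["_alpha_sumsq"] = a_sumsq
    out["_nu_sum"] = nu_sum
    out["_tau_sum"] = tau_sum
    return out


def _update_nu_group(state, w, g_steps, rng, warming) -> None:
    """Metropolis updates of (mu_nu, sigma_nu, rho) given latent drifts."""
    nu = state["nu"]

    def logp(mu, sig, rho):
        if sig <= 0 or not (0.0 <= rho < 1.0):
            return -np.inf
        s2 = sig * sig * (1 - rho * rho)
        m = mu + rho * sig * w
        lp = -0.5 * np.sum((nu - m) ** 2) / s2 - len(nu) / 2 * np.log(s2)
        lp += -0.5 * ((mu - _PRIOR["mu_nu"][0]) / _PRIOR["mu_nu"][1]) ** 2
        lp += _half_normal_lp(sig, _PRIOR["sigma_nu"])
        return lp

    cur = [state["mu_nu"], state["sigma_nu"], state["rho"]]
    cur_lp = logp(*cur)
    for j, name in enumerate(("mu_nu", "sigma_nu", "rho")):
        prop = list(cur)
        prop[j] = cur[j] + rng.normal(0, g_steps[name].scale)
        new_lp = logp(*prop)
        accepted = np.log(rng.random()) < new_lp - cur_lp
        if accepted:
            cur, cur_lp = prop, new_lp
        if warming:
            g_steps[name].update(1.0 if accepted else 0.0)
    state["mu_nu"], state["sigma_nu"], state["rho"] = cur


def _update_pos_group(
    state, x, mu_name, sig_name, mu_prior, sig_prior, lo, hi, g_steps, rng, warming
) -> None:
    """Group mean/SD of a truncated-normal latent (boundary or ndt)."""

    def logp(mu, sig):
        if mu <= 0 or sig <= 0:
            return -np.inf
        z_lo = (lo - mu) / sig
        z_hi = (hi - mu) / sig
        norm = special.ndtr(z_hi) - special.ndtr(z_lo)
        if np.any(norm <= 0):
            return -np.inf
        lp = -0.5 * np.sum(((x - mu) / sig) ** 2) - len(x) * np.log(sig)
        lp -= np.sum(np.log(norm))
        lp += _trunc_normal_lp(mu, mu_prior[0], mu_prior[1])
        lp += _half_normal_lp(sig, sig_prior)
        return lp

    cur = [state[mu_name], state[sig_name]]
    cur_lp = logp(*cur)
    for j, name in enumerate((mu_name, sig_name)):
        prop = list(cur)
        prop[j] = cur[j] + rng.normal(0, g_steps[name].scale)
        new_lp = logp(*prop)
        accepted = np.log(rng.random()) < new_lp - cur_lp
        if accepted:
            cur, cur_lp = prop, new_lp
        if warming:
            g_steps[name].update(1.0 if accepted else 0.0)
    state[mu_name], state[sig_name] = cur


def _update_plain_group(state, g_steps, rng, warming) -> None:
    """Group mean/SD of the undoable drift (plain normal latent)."""
    x = state["nu_u"]

    def logp(mu, sig):
        if sig <= 0:
            return -np.inf
        lp = -0.5 * np.sum(((x - mu) / sig) ** 2) - len(x) * np.log(sig)
        lp += -0.5 * ((mu - _PRIOR["mu_nu_u"][0]) / _PRIOR["mu_nu_u"][1]) ** 2
        lp += _half_normal_lp(sig, _PRIOR["sigma_nu_u"])
        return lp

    cur = [state["mu_nu_u"], state["sigma_nu_u"]]
    cur_lp = logp(*cur)
    for j, name in enumerate(("mu_nu_u", "sigma_nu_u")):
        prop = list(cur)
        prop[j] = cur[j] + rng.normal(0, g_steps[name].scale)
        new_lp = logp(*prop)
        accepted = np.log(rng.random()) < new_lp - cur_lp
        if accepted:
            cur, cur_lp = prop, new_lp
        if warming:
            g_steps[name].update(1.0 if accepted else 0.0)
    state["mu_nu_u"], state["sigma_nu_u"] = cur


def _group_rhat(group_samples: dict) -> dict:
    rhat = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, v in group_samples.items():
            if v.shape[0] < 2:
                rhat[k] = float("nan")
            else:
                rhat[k] = float(az.rhat(az.convert_to_dataset(v))["x"])
    return rhat


# ---------------------------------------------------------------------------
# joint two-condition fit (H4)
# ---------------------------------------------------------------------------


def joint_prior_delta_ordinate() -> float:
    """Truncation-aware prior ordinate of delta at 0 for the joint model.

    The free drift-drift correlation must keep the 3x3 correlation matrix
    positive definite; integrating that admissibility region against the
    (mu, delta, r) prior reweights the folded-normal ordinate 2*phi(0).
    """
    mu = np.linspace(-8, 8, 1601)
    de = np.linspace(0, 8, 801)
    M, D = np.meshgrid(mu, de, indexing="ij")
    rho_d = special.ndtr(M + D / 2)
    rho_e = special.ndtr(M - D / 2)
    # admissible r-length is 2*sqrt((1-rho_e^2)(1-rho_d^2)); r prior density 1/2
    G = np.sqrt((1 - rho_e ** 2) * (1 - rho_d ** 2))
    w = stats.norm.pdf(M) * 2 * stats.norm.pdf(D)
    Z = np.trapezoid(np.trapezoid(w * G, de, axis=1), mu)
    # at delta = 0: integral of phi(mu) * (1 - Phi(mu)^2) dmu = 2/3
    num = 2 * stats.norm.pdf(0.0) * (2.0 / 3.0)
    return float(num / Z)


@dataclass(frozen=True)
class JointDiffusionPosterior:
    """Posterior of the joint (nu_easy, nu_hard, WMC) diffusion model."""

    participant_ids: tuple[str, ...]
    group_samples: dict
    bf_delta: BayesFactorResult
    alpha_mean: pd.Series
    alpha_sd: pd.Series
    nu_easy_mean: pd.Series
    nu_hard_mean: pd.Series
    rhat: dict
    wmc_standardization: tuple[float, float]

    @property
    def rho_easy_samples(self) -> np.ndarray:
        g = self.group_samples
        return special.ndtr(g["mu"].ravel() - g["delta"].ravel() / 2)

    @property
    def rho_hard_samples(self) -> np.ndarray:
        g = self.group_samples
        return special.ndtr(g["mu"].ravel() + g["delta"].ravel() / 2)

    def boundary_export(self) -> pd.DataFrame:
        """Per-participant boundary posterior means for the caution analysis."""
        return pd.DataFrame(
            {
                "participant_id": list(self.participant_ids),
                "alpha_mean": self.alpha_mean.to_numpy(),
                "alpha_sd": self.alpha_sd.to_numpy(),
            }
        )

    def summary(self) -> dict:
        g = self.group_samples
        return {
            "n_participants": len(self.participant_ids),
            "rho_easy_mean": float(np.mean(self.rho_easy_samples)),
            "rho_hard_mean": float(np.mean(self.rho_hard_samples)),
            "delta_mean": float(np.mean(g["delta"])),
            "delta_median": float(np.median(g["delta"])),
            "r_drift_drift_mean": float(np.mean(g["r_ed"])),
            "bf10": self.bf_delta.bf10,
            "bf01": self.bf_delta.bf01,
            "rhat": self.rhat,
        }


def fit_joint_diffusion(
    trials: pd.DataFrame,
    wmc: pd.DataFrame,
    mcmc_config: DiffusionMCMCConfig | None = None,
) -> JointDiffusionPosterior:
    """Fit both difficulties jointly with probit-orthogonalized correlations."""
    cfg = mcmc_config or DiffusionMCMCConfig()
    ids, w, w_ms, blocks, min_rt = _prepare(trials, wmc, ["easy", "hard"])
    n_p = len(ids)
    easy, hard = blocks["easy"], blocks["hard"]
    und_block = blocks.get("undoable")

    chains_out: list[dict] = []
    acc = {k: np.zeros(n_p) for k in ("alpha", "alpha_sq", "nu_e", "nu_d")}
    n_acc = 0
    for chain in range(cfg.chains):
        rng = np.random.default_rng([cfg.seed, 104729, chain])
        draws = _run_joint_chain(easy, hard, und_block, n_p, w, min_rt, cfg, rng)
        chains_out.append(draws)
        acc["alpha"] += draws.pop("_alpha_sum")
        acc["alpha_sq"] += draws.pop("_alpha_sumsq")
        acc["nu_e"] += draws.pop("_nu_e_sum")
        acc["nu_d"] += draws.pop("_nu_d_sum")
        n_acc += cfg.draws

    keys = ("mu_e", "mu_d", "sig_e", "sig_d", "mu", "delta", "r_ed",
            "mu_alpha", "sigma_alpha", "mu_tau", "sigma_tau")
    group_samples = {
        k: np.stack([c[k] for c in chains_out]) for k in keys if k in chains_out[0]
    }
    rhat = _group_rhat(group_samples)
    if cfg.check_convergence:
        bad = {k: v for k, v in rhat.items() if not (v < cfg.rhat_threshold)}
        if bad:
            raise DiagnosticsError(
                f"R-hat above {cfg.rhat_threshold} for group parameters: {bad}"
            )
    bf = savage_dickey_bf(
        group_samples["delta"].ravel(),
        joint_prior_delta_ordinate(),
        point=0.0,
        support=(0.0, np.inf),
    )
    alpha_mean = acc["alpha"] / n_acc
    alpha_var = np.maximum(acc["alpha_sq"] / n_acc - alpha_mean ** 2, 0.0)
    return JointDiffusionPosterior(
        participant_ids=tuple(ids),
        group_samples=group_samples,
        bf_delta=bf,
        alpha_mean=pd.Series(alpha_mean, index=ids, name="alpha_mean"),
        alpha_sd=pd.Series(np.sqrt(alpha_var), index=ids, name="alpha_sd"),
        nu_easy_mean=pd.Series(acc["nu_e"] / n_acc, index=ids, name="nu_easy_mean"),
        nu_hard_mean=pd.Series(acc["nu_d"] / n_acc, index=ids, name="nu_hard_mean"),
        rhat=rhat,
        wmc_standardization=w_ms,
    )


def _joint_cond_moments(state, w):
    """Conditional mean/covariance of (nu_e, nu_d) given WMC under the prior."""
    rho_e = special.ndtr(state["mu"] - state["delta"] / 2)
    rho_d = special.ndtr(state["mu"] + state["delta"] / 2)
    r = state["r_ed"]
    se, sd_ = state["sig_e"], state["sig_d"]
    c_off = r - rho_e * rho_d
    det_ok = (1 - rho_e ** 2) * (1 - rho_d ** 2) - c_off ** 2
    if det_ok <= 1e-12:
        return None
    m_e = state["mu_e"] + rho_e * se * w
    m_d = state["mu_d"] + rho_d * sd_ * w
    S = np.array(
        [
            [se * se * (1 - rho_e ** 2), se * sd_ * c_off],
            [se * sd_ * c_off, sd_ * sd_ * (1 - rho_d ** 2)],
        ]
    )
    return m_e, m_d, S


def _bvn_quad(d_e, d_d, S):
    """Quadratic-form log-density terms of a bivariate normal (no consts)."""
    det = S[0, 0] * S[1, 1] - S[0, 1] ** 2
    inv00 = S[1, 1] / det
    inv11 = S[0, 0] / det
    inv01 = -S[0, 1] / det
    quad = inv00 * d_e ** 2 + 2 * inv01 * d_e * d_d + inv11 * d_d ** 2
    return -0.5 * quad, -0.5 * np.log(det)


def _run_joint_chain(easy, hard, und_block, n_p, w, min_rt, cfg, rng) -> dict:
    tau_hi = 0.95 * min_rt
    v_e0, a_e0, t_e0 = _ez_init(easy, n_p)
    v_d0, a_d0, t_d0 = _ez_init(hard, n_p)
    a0 = np.clip((a_e0 + a_d0) / 2, _ALPHA_FLOOR * 2, None)
    tau0 = np.clip(
        np.minimum(t_e0, t_d0), _TAU_FLOOR * 2, tau_hi - 1e-4
    )
    state = {
        "nu_e": v_e0 + rng.normal(0, 0.1, n_p),
        "nu_d": v_d0 + rng.normal(0, 0.1, n_p),
        "alpha": a0 + rng.normal(0, 0.05, n_p),
        "tau": np.clip(tau0 + rng.normal(0, 0.01, n_p), _TAU_FLOOR, tau_hi - 1e-5),
        "nu_u": rng.normal(0, 0.1, n_p) if und_block is not None else None,
        "mu_e": float(np.mean(v_e0)),
        "mu_d": float(np.mean(v_d0)),
        "sig_e": float(np.std(v_e0) + 0.2),
        "sig_d": float(np.std(v_d0) + 0.2),
        "mu": float(rng.normal(0, 0.3)),
        "delta": float(abs(rng.normal(0, 0.3))),
        "r_ed": float(rng.uniform(0.2, 0.6)),
        "mu_alpha": float(np.mean(a0)),
        "sigma_alpha": float(np.std(a0) + 0.1),
        "mu_tau": float(np.mean(tau0)),
        "sigma_tau": float(np.std(tau0) + 0.03),
    }
    if und_block is not None:
        state["mu_nu_u"] = 0.0
        state["sigma_nu_u"] = 0.5

    steps = {
        "nu": _StepAdapter(0.25, 0.44),
        "nu_u": _StepAdapter(0.25, 0.44),
        "at": _StepAdapter(0.08, 0.3),
    }
    g_steps = {
        k: _StepAdapter(s, 0.44)
        for k, s in (
            ("mu_e", 0.1), ("mu_d", 0.1), ("sig_e", 0.1), ("sig_d", 0.1),
            ("mu", 0.1), ("delta", 0.1), ("r_ed", 0.1),
            ("mu_alpha", 0.05), ("sigma_alpha", 0.05),
            ("mu_tau", 0.01), ("sigma_tau", 0.01),
            ("mu_nu_u", 0.1), ("sigma_nu_u", 0.1),
        )
    }

    ll_e = _loglik(easy, state["nu_e"], state["alpha"], state["tau"], n_p)
    ll_d = _loglik(hard, state["nu_d"], state["alpha"], state["tau"], n_p)
    ll_u = (
        _loglik(und_block, state["nu_u"], state["alpha"], state["tau"], n_p)
        if und_block is not None
        else np.zeros(n_p)
    )

    total = cfg.warmup + cfg.draws
    keys = ("mu_e", "mu_d", "sig_e", "sig_d", "mu", "delta", "r_ed",
            "mu_alpha", "sigma_alpha", "mu_tau", "sigma_tau")
    out = {k: np.empty(cfg.draws) for k in keys}
    a_sum = np.zeros(n_p)
    a_sumsq = np.zeros(n_p)
    nu_e_sum = np.zeros(n_p)
    nu_d_sum = np.zeros(n_p)

    for sweep in range(total):
        warming = sweep < cfg.warmup
        mom = _joint_cond_moments(state, w)
        m_e, m_d, S = mom  # state always kept admissible

        # --- drifts (joint 2-D proposal per participant) -----------------
        prop_e = state["nu_e"] + rng.normal(0, steps["nu"].scale, n_p)
        prop_d = state["nu_d"] + rng.normal(0, steps["nu"].scale, n_p)
        llp_e = _loglik(easy, prop_e, state["alpha"], state["tau"], n_p)
        llp_d = _loglik(hard, prop_d, state["alpha"], state["tau"], n_p)
        q_new, _ = _bvn_quad(prop_e - m_e, prop_d - m_d, S)
        q_old, _ = _bvn_quad(state["nu_e"] - m_e, state["nu_d"] - m_d, S)
        dlp = llp_e - ll_e + llp_d - ll_d + q_new - q_old
        acc = np.log(rng.random(n_p)) < dlp
        state["nu_e"][acc] = prop_e[acc]
        state["nu_d"][acc] = prop_d[acc]
        ll_e[acc] = llp_e[acc]
        ll_d[acc] = llp_d[acc]
        if warming:
            steps["nu"].update(float(np.mean(acc)))

        # --- undoable drift ----------------------------------------------
        if und_block is not None:
            prop = state["nu_u"] + rng.normal(0, steps["nu_u"].scale, n_p)
            llp = _loglik(und_block, prop, state["alpha"], state["tau"], n_p)
            dlp = (
                llp - ll_u
                - 0.5
                * ((prop - state["mu_nu_u"]) ** 2 - (state["nu_u"] - state["mu_nu_u"]) ** 2)
                / state["sigma_nu_u"] ** 2
            )
            acc = np.log(rng.random(n_p)) < dlp
            state["nu_u"][acc] = prop[acc]
            ll_u[acc] = llp[acc]
            if warming:
                steps["nu_u"].update(float(np.mean(acc)))

        # --- boundary / ndt ----------------------------------------------
        sc = steps["at"].scale
        prop_a = state["alpha"] + rng.normal(0, sc, n_p)
        prop_t = state["tau"] + rng.normal(0, sc * 0.25, n_p)
        ok = (prop_a > _ALPHA_FLOOR) & (prop_t > _TAU_FLOOR) & (prop_t < tau_hi)
        prop_a = np.where(ok, prop_a, state["alpha"])
        prop_t = np.where(ok, prop_t, state["tau"])
        llp_e2 = _loglik(easy, state["nu_e"], prop_a, prop_t, n_p)
        llp_d2 = _loglik(hard, state["nu_d"], prop_a, prop_t, n_p)
        if und_block is not None:
            llp_u2 = _loglik(und_block, state["nu_u"], prop_a, prop_t, n_p)
        else:
            llp_u2 = np.zeros(n_p)
        dlp = (
            llp_e2 - ll_e + llp_d2 - ll_d + llp_u2 - ll_u
            - 0.5
            * ((prop_a - state["mu_alpha"]) ** 2 - (state["alpha"] - state["mu_alpha"]) ** 2)
            / state["sigma_alpha"] ** 2
            - 0.5
            * ((prop_t - state["mu_tau"]) ** 2 - (state["tau"] - state["mu_tau"]) ** 2)
            / state["sigma_tau"] ** 2
        )
        acc = ok & (np.log(rng.random(n_p)) < dlp)
        state["alpha"][acc] = prop_a[acc]
        state["tau"][acc] = prop_t[acc]
        ll_e[acc] = llp_e2[acc]
        ll_d[acc] = llp_d2[acc]
        ll_u[acc] = llp_u2[acc]
        if warming:
            steps["at"].update(float(np.mean(acc)))

        # --- group level ---------------------------------------------------
        for _ in range(cfg.group_reps):
            _update_joint_drift_group(state, w, g_steps, rng, warming)
            _update_pos_group(
                state, state["alpha"], "mu_alpha", "sigma_alpha",
                _PRIOR["mu_alpha"], _PRIOR["sigma_alpha"],
                np.zeros(n_p), np.full(n_p, np.inf), g_steps, rng, warming,
            )
            _update_pos_group(
                state, state["tau"], "mu_tau", "sigma_tau",
                _PRIOR["mu_tau"], _PRIOR["sigma_tau"],
                np.zeros(n_p), tau_hi, g_steps, rng, warming,
            )
            if und_block is not None:
                _update_plain_group(state, g_steps, rng, warming)

        if not warming:
            i = sweep - cfg.warmup
            for k in keys:
                out[k][i] = state[k]
            a_sum += state["alpha"]
            a_sumsq += state["alpha"] ** 2
            nu_e_sum += state["nu_e"]
            nu_d_sum += state["nu_d"]

    out["_alpha_sum"] = a_sum
    out["_alpha_sumsq"] = a_sumsq
    out["_nu_e_sum"] = nu_e_sum
    out["_nu_d_sum"] = nu_d_sum
    return out


def _update_joint_drift_group(state, w, g_steps, rng, warming) -> None:
    """Metropolis updates of the trivariate population parameters."""
    nu_e, nu_d = state["nu_e"], state["nu_d"]
    names = ("mu_e", "mu_d", "sig_e", "sig_d", "mu", "delta", "r_ed")

    def logp(vals):
        st = dict(zip(names, vals))
        if st["sig_e"] <= 0 or st["sig_d"] <= 0:
            return -np.inf
        if st["delta"] < 0 or not (-1 < st["r_ed"] < 1):
            return -np.inf
        tmp = dict(state)
        tmp.update(st)
        mom = _joint_cond_moments(tmp, w)
        if mom is None:  # correlation matrix not positive definite
            return -np.inf
        m_e, m_d, S = mom
        quad, logdet = _bvn_quad(nu_e - m_e, nu_d - m_d, S)
        lp = float(np.sum(quad)) + len(w) * logdet
        lp += -0.5 * st["mu"] ** 2 - 0.5 * st["delta"] ** 2
        lp += -0.5 * ((st["mu_e"] - _PRIOR["mu_nu"][0]) / _PRIOR["mu_nu"][1]) ** 2
        lp += -0.5 * ((st["mu_d"] - _PRIOR["mu_nu"][0]) / _PRIOR["mu_nu"][1]) ** 2
        lp += _half_normal_lp(st["sig_e"], _PRIOR["sigma_nu"])
        lp += _half_normal_lp(st["sig_d"], _PRIOR["sigma_nu"])
        return lp

    cur = [state[k] for k in names]
    cur_lp = logp(cur)
    for j, name in enumerate(names):
        prop = list(cur)
        prop[j] = cur[j] + rng.normal(0, g_steps[name].scale)
        new_lp = logp(prop)
        accepted = np.log(rng.random()) < new_lp - cur_lp
        if accepted:
            cur, cur_lp = prop, new_lp
        if warming:
            g_steps[name].update(1.0 if accepted else 0.0)
    for k, v in zip(names, cur):
        state[k] = v
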