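"""Synthetic populations for the blinded WPR workflow.

Each participant owns a drift rate per difficulty, a boundary separation, a
non-decision time, and a working-memory-capacity (WMC) score.  These are
drawn jointly from a multivariate normal on a latent scale: drifts and WMC
enter untransformed, boundary and non-decision time enter through their
logarithms so positivity is guaranteed.  Configured correlations are
correlations on that latent scale.

The default configuration mirrors the study conditions the analyses assume:
916 participants, 90 easy + 90 hard trials (dot proportions 60/40 vs 55/45)
plus 45 "undoable" 50/50 trials, a 3.5-s too-slow cutoff, and WMC positively
correlated with drift rate.  The ``caution_confound`` preset instead couples
WMC to boundary separation, which is the mechanism that produces positive,
increasing quantile correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .wiener_core import DiffusionParams, simulate_rt_choice

__all__ = [
    "ScenarioConfig",
    "TruthRecord",
    "ConfigError",
    "generate_population",
    "apply_contamination_and_censoring",
    "scenario_config",
    "SCENARIO_PRESETS",
]


class ConfigError(ValueError):
    """Raised for inadmissible scenario configurations."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Population and task design for one synthetic scenario."""

    n_participants: int = 916
    trials_easy: int = 90
    trials_hard: int = 90
    trials_undoable: int = 45
    #: latent-scale correlation of WMC with drift, per difficulty
    rho_drift_wmc_easy: float = 0.4
    rho_drift_wmc_hard: float = 0.5
    #: latent-scale correlation of WMC with log boundary separation
    rho_boundary_wmc: float = 0.0
    #: latent-scale correlation between easy and hard drift rates
    rho_drift_drift: float = 0.6
    # population means/SDs; boundary and ndt are (mean, sd) of the log
    mean_nu_easy: float = 3.0
    sd_nu_easy: float = 1.0
    mean_nu_hard: float = 1.5
    sd_nu_hard: float = 0.8
    mean_nu_undoable: float = 0.0
    sd_nu_undoable: float = 0.3
    mean_log_alpha: float = float(np.log(1.4))
    sd_log_alpha: float = 0.25
    mean_log_tau: float = float(np.log(0.3))
    sd_log_tau: float = 0.2
    mean_wmc: float = 0.0
    sd_wmc: float = 1.0
    contamination_rate: float = 0.0
    rt_cutoff: float = 3.5
    prob_student: float = 0.75
    prob_student_missing: float = 0.016
    sv: float = 0.0
    dt: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "trials_easy", "trials_hard", "trials_undoable"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_participants == 0:
            raise ConfigError("need at least one participant")
        if not (0.0 <= self.contamination_rate < 1.0):
            raise ConfigError("contamination_rate must lie in [0, 1)")
        if self.rt_cutoff <= 0:
            raise ConfigError("rt_cutoff must be > 0")
        for name in (
            "rho_drift_wmc_easy",
            "rho_drift_wmc_hard",
            "rho_boundary_wmc",
            "rho_drift_drift",
        ):
            if abs(getattr(self, name)) > 1:
                raise ConfigError(f"{name} must lie in [-1, 1]")
        # fail before any simulation if the implied correlation matrix is not PSD
        self.latent_correlation()

    def latent_correlation(self) -> np.ndarray:
        """6x6 latent correlation over (nu_e, nu_h, nu_u, log_a, log_t, wmc)."""
        R = np.eye(6)
        idx = {"nu_e": 0, "nu_h": 1, "nu_u": 2, "log_a": 3, "log_t": 4, "wmc": 5}

        def put(a: str, b: str, r: float) -> None:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r

        put("nu_e", "nu_h", self.rho_drift_drift)
        put("nu_e", "wmc", self.rho_drift_wmc_easy)
        put("nu_h", "wmc", self.rho_drift_wmc_hard)
        put("log_a", "wmc", self.rho_boundary_wmc)
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ConfigError(
                "configured correlations imply a non-PSD latent covariance"
            )
        return R


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for parameter-recovery bookkeeping."""

    participants: pd.DataFrame  # one row per participant, true parameters
    correlations: dict


#: scenario presets shipped as YAML config files under ``wprdm/scenarios/``
SCENARIO_PRESETS = ("wpr_true", "caution_confound", "null")


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """Named scenario preset loaded from its config file, with overrides."""
    if name not in SCENARIO_PRESETS:
        raise ConfigError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIO_PRESETS)}"
        )
    text = resources.files("wprdm").joinpath(f"scenarios/{name}.yaml").read_text()
    kwargs = yaml.safe_load(text) or {}
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def _draw_participants(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    R = config.latent_correlation()
    means = np.array(
        [
            config.mean_nu_easy,
            config.mean_nu_hard,
            config.mean_nu_undoable,
            config.mean_log_alpha,
            config.mean_log_tau,
            config.mean_wmc,
        ]
    )
    sds = np.array(
        [
            config.sd_nu_easy,
            config.sd_nu_hard,
            config.sd_nu_undoable,
            config.sd_log_alpha,
            config.sd_log_tau,
            config.sd_wmc,
        ]
    )
    cov = R * np.outer(sds, sds)
    lat = rng.multivariate_normal(means, cov, size=config.n_participants, method="svd")
    ids = [f"p{i:04d}" for i in range(1, config.n_participants + 1)]
    df = pd.DataFrame(
        {
            "participant_id": ids,
            "nu_easy": lat[:, 0],
            "nu_hard": lat[:, 1],
            "nu_undoable": lat[:, 2],
            "alpha": np.exp(lat[:, 3]),
            "tau": np.exp(lat[:, 4]),
            "wmc": lat[:, 5],
        }
    )
    return df


def _balanced_sides(n: int, rng: np.random.Generator) -> np.ndarray:
    sides = np.array(["left", "right"])[np.arange(n) % 2]
    rng.shuffle(sides)
    return sides


def generate_population(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Draw a participant population and simulate its trial table.

    Returns ``(trials, wmc_table, truth)``.  Easy/hard trials are
    accuracy-coded (upper boundary = correct response); undoable 50/50 trials
    are response-coded (upper = "right") with their own drift centred near 0.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0x5EED])
    truth_df = _draw_participants(config, rng)

    cond_plan = [
        ("easy", config.trials_easy, "nu_easy"),
        ("hard", config.trials_hard, "nu_hard"),
        ("undoable", config.trials_undoable, "nu_undoable"),
    ]
    frames = []
    for _, row in truth_df.iterrows():
        for cond, n_trials, nu_col in cond_plan:
            if n_trials == 0:
                continue
            params = DiffusionParams(
                drift=float(row[nu_col]),
                boundary=float(row["alpha"]),
                start_frac=0.5,
                ndt=float(row["tau"]),
                sv=config.sv,
            )
            sim_seed = int(rng.integers(0, 2**31 - 1))
            rt, upper, timed_out = simulate_rt_choice(
                params, n_trials, seed=sim_seed, dt=config.dt
            )
            sides = _balanced_sides(n_trials, rng)
            if cond == "undoable":
                # response coding: upper boundary is the "right" response
                response = np.where(upper, "right", "left")
                correct = pd.array([pd.NA] * n_trials, dtype="boolean")
            else:
                # accuracy coding: upper boundary is the correct response
                response = np.where(upper, sides, np.where(sides == "left", "right", "left"))
                correct = pd.array(upper, dtype="boolean")
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": row["participant_id"],
                        "condition": cond,
                        "stimulus_side": sides,
                        "response_side": response,
                        "correct": correct,
                        "rt": rt,
                        "censored": timed_out,
                    }
                )
            )
    trials = pd.concat(frames, ignore_index=True)

    student_u = rng.random(config.n_participants)
    student = pd.array(
        [
            pd.NA if u < config.prob_student_missing
            else u < config.prob_student_missing + config.prob_student * (1 - config.prob_student_missing)
            for u in student_u
        ],
        dtype="boolean",
    )
    wmc_table = pd.DataFrame(
        {
            "participant_id": truth_df["participant_id"],
            "wmc": truth_df["wmc"],
            "student": student,
        }
    )
    truth = TruthRecord(
        participants=truth_df,
        correlations={
            "rho_drift_wmc_easy": config.rho_drift_wmc_easy,
            "rho_drift_wmc_hard": config.rho_drift_wmc_hard,
            "rho_boundary_wmc": config.rho_boundary_wmc,
            "rho_drift_drift": config.rho_drift_drift,
        },
    )
    return trials, wmc_table, truth


def apply_contamination_and_censoring(
    trials: pd.DataFrame, config: ScenarioConfig
) -> pd.DataFrame:
    """Inject uniform-RT contaminants and flag trials at or beyond the cutoff.

    A ``config.contamination_rate`` fraction of rows (Bernoulli per trial) is
    replaced by a contaminant with RT uniform on [0.1 s, cutoff] and a random
    response; rows with ``rt >= rt_cutoff`` are flagged censored (the cutoff
    is treated as censoring, closed at the boundary).  Row count preserved.
    """
    if config.rt_cutoff <= 0:
        raise ConfigError("rt_cutoff must be > 0")
    out = trials.copy()
    rng = np.random.default_rng([config.seed, 0xC0])
    n = len(out)
    is_cont = rng.random(n) < config.contamination_rate
    if is_cont.any():
        k = int(is_cont.sum())
        hi = config.rt_cutoff if np.isfinite(config.rt_cutoff) else 10.0
        out.loc[is_cont, "rt"] = rng.uniform(0.1, hi, size=k)
        flip = rng.random(k) < 0.5
        resp = np.where(flip, "left", "right")
        out.loc[is_cont, "response_side"] = resp
        doable = out.loc[is_cont, "condition"].to_numpy() != "undoable"
        new_correct = pd.array(
            resp == out.loc[is_cont, "stimulus_side"].to_numpy(), dtype="boolean"
        )
        new_correct[~doable] = pd.NA
        out.loc[is_cont, "correct"] = new_correct
    out["is_contaminant"] = is_cont
    out["censored"] = out["censored"].to_numpy() | (
        out["rt"].to_numpy() >= config.rt_cutoff
    )
    return out
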