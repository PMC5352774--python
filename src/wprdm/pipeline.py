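"""Two-stage blinded workflow orchestration.

Stage one operates on a trial table paired with a *blinded* WMC table (key
column permuted, permutation sealed in a BlindingRecord): every modeling
decision can be made freely because the drift-WMC and quantile-WMC
associations are meaningless by construction.  Stage two unblinds the key
variable and reruns the identical, frozen pipeline.  The blinding gate is
enforced, not advisory: a confirmatory run in blinded mode refuses to start
unless a valid, non-identity blinding record accompanies the key table.

All randomness flows from one master seed through named substreams per
stage, so a rerun with the same configuration is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes_eval import jzs_slope_bf
from .data_io import (
    DEFAULT_LEVELS,
    BlindingRecord,
    FilterConfig,
    compute_quantile_matrix,
    correlation_curve,
    load_tables,
    preprocess_trials,
    unblind,
    validate_trials,
    validate_wmc,
)
from .diffusion_inference import (
    DiffusionMCMCConfig,
    fit_hierarchical_diffusion,
    fit_joint_diffusion,
)
from .wpr_inference import MCMCConfig, caution_subgroup_wpr, fit_wpr_h1, fit_wpr_h2

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "BlindingGateError",
    "run_confirmatory",
    "run_exploratory",
    "render_report",
]

_STAGES = (
    "preprocess",
    "h1a",
    "h1b",
    "h2",
    "h3a",
    "h3b",
    "h4",
    "exploratory_h1",
    "caution",
    "students",
)


class BlindingGateError(RuntimeError):
    """Confirmatory analysis attempted without a valid blinding setup."""


def stage_seed(master: int, stage: str) -> int:
    """Named, stable substream seed below 2**31."""
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class AnalysisConfig:
    """Frozen configuration of one two-stage analysis run."""

    trial_path: str | None = None
    wmc_path: str | None = None
    blinding: str = "unblinded"  # "blinded" | "unblinded"
    blinding_record_path: str | None = None
    levels: tuple[float, ...] = DEFAULT_LEVELS
    quantile_mode: str = "quantile"
    filters: FilterConfig = field(default_factory=FilterConfig)
    run_h1: bool = True
    run_h2: bool = True
    run_h3: bool = True
    run_h4: bool = True
    wpr_mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    diffusion_mcmc: DiffusionMCMCConfig = field(default_factory=DiffusionMCMCConfig)
    min_subgroup_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blinding not in ("blinded", "unblinded"):
            raise ValueError("blinding must be 'blinded' or 'unblinded'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("filters", FilterConfig),
                         ("wpr_mcmc", MCMCConfig),
                         ("diffusion_mcmc", DiffusionMCMCConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "levels" in raw:
            raw["levels"] = tuple(raw["levels"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, with provenance."""

    results: dict  # hypothesis label -> summary dict
    fits: dict  # hypothesis label -> posterior object
    exclusion_report: dict
    panel_data: dict  # condition -> per-participant DataFrame
    panel_bfs: dict  # condition -> panel label -> BF10
    meaningless: bool
    provenance: dict
    boundary_estimates: pd.DataFrame | None = None

    def summary(self) -> dict:
        return {
            "meaningless_blinded": self.meaningless,
            "results": self.results,
            "panel_bf10": self.panel_bfs,
            "exclusion_report": self.exclusion_report,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True, default=float)


def _load_inputs(config, trials, wmc):
    if trials is None or wmc is None:
        if config.trial_path is None or config.wmc_path is None:
            raise ValueError("provide tables in memory or via config paths")
        trials, wmc = load_tables(config.trial_path, config.wmc_path)
    else:
        trials = validate_trials(trials)
        wmc = validate_wmc(wmc)
    return trials, wmc


def _enforce_blinding_gate(config, wmc, blinding_record):
    if config.blinding != "blinded":
        return None
    record = blinding_record
    if record is None and config.blinding_record_path:
        record = BlindingRecord.from_json(config.blinding_record_path)
    if record is None:
        raise BlindingGateError(
            "blinded mode requires a BlindingRecord; refusing to analyse "
            "what might be the true key variable"
        )
    perm = np.asarray(record.permutation)
    if len(perm) != len(wmc):
        raise BlindingGateError("blinding record does not match the key table")
    if np.array_equal(perm, np.arange(len(perm))):
        raise BlindingGateError(
            "blinding record holds the identity permutation: key variable "
            "is not blinded"
        )
    return record


def _flag(summary: dict, meaningless: bool) -> dict:
    if meaningless:
        summary = dict(summary)
        summary["blinded"] = "meaningless by construction (key variable permuted)"
    return summary


def _panel_data(filtered, qm, wmc):
    acc = (
        filtered[filtered["condition"] == qm.condition]
        .groupby("participant_id", observed=True)["correct"]
        .mean()
        .astype(float)
    )
    df = qm.values.copy()
    df.columns = [f"q{i+1}" for i in range(len(qm.levels))]
    df = df.join(wmc.set_index("participant_id")["wmc"], how="inner")
    df["accuracy"] = acc.reindex(df.index)
    return df.dropna()


def _panel_bfs(panel: pd.DataFrame, levels) -> dict:
    out = {}
    for i in range(len(levels)):
        out[f"wmc_q{i+1}"] = jzs_slope_bf(panel["wmc"], panel[f"q{i+1}"]).bf10
        out[f"accuracy_q{i+1}"] = jzs_slope_bf(panel["accuracy"], panel[f"q{i+1}"]).bf10
    out["wmc_accuracy"] = jzs_slope_bf(panel["wmc"], panel["accuracy"]).bf10
    return out


def run_confirmatory(
    config: AnalysisConfig,
    trials: pd.DataFrame | None = None,
    wmc: pd.DataFrame | None = None,
    blinding_record: BlindingRecord | None = None,
) -> ReportBundle:
    """Execute the frozen confirmatory pipeline in a fixed stage order.

    Stages: preprocess -> quantiles/curves -> H1a, H1b, H2 -> hierarchical
    diffusion H3a, H3b -> joint diffusion H4.  In blinded mode all outputs
    are flagged meaningless by construction.
    """
    trials, wmc = _load_inputs(config, trials, wmc)
    _enforce_blinding_gate(config, wmc, blinding_record)
    meaningless = config.blinding == "blinded"

    stage = "preprocess"
    results: dict = {}
    fits: dict = {}
    try:
        filtered, report = preprocess_trials(trials, config.filters)
        qms, curves, panels, panel_bfs = {}, {}, {}, {}
        for cond in ("easy", "hard"):
            qm = compute_quantile_matrix(
                filtered, cond, config.levels, mode=config.quantile_mode
            )
            qms[cond] = qm
            panels[cond] = _panel_data(filtered, qm, wmc)
            acc = panels[cond]["accuracy"]
            curves[cond] = correlation_curve(qm, wmc, accuracy=acc)
            panel_bfs[cond] = _panel_bfs(panels[cond], qm.levels)

        if config.run_h1:
            stage = "h1a"
            cfg = dataclasses.replace(config.wpr_mcmc, seed=stage_seed(config.seed, "h1a"))
            fits["h1a"] = fit_wpr_h1(curves["easy"], constrained=True, mcmc_config=cfg)
            results["h1a"] = _flag(fits["h1a"].summary(), meaningless)
            stage = "h1b"
            cfg = dataclasses.replace(config.wpr_mcmc, seed=stage_seed(config.seed, "h1b"))
            fits["h1b"] = fit_wpr_h1(curves["hard"], constrained=True, mcmc_config=cfg)
            results["h1b"] = _flag(fits["h1b"].summary(), meaningless)
        if config.run_h2:
            stage = "h2"
            cfg = dataclasses.replace(config.wpr_mcmc, seed=stage_seed(config.seed, "h2"))
            fits["h2"] = fit_wpr_h2(curves["easy"], curves["hard"], mcmc_config=cfg)
            results["h2"] = _flag(fits["h2"].summary(), meaningless)
        if config.run_h3:
            for label, cond in (("h3a", "easy"), ("h3b", "hard")):
                stage = label
                cfg = dataclasses.replace(
                    config.diffusion_mcmc, seed=stage_seed(config.seed, label)
                )
                fits[label] = fit_hierarchical_diffusion(filtered, wmc, cond, cfg)
                results[label] = _flag(fits[label].summary(), meaningless)
        boundary = None
        if config.run_h4:
            stage = "h4"
            cfg = dataclasses.replace(
                config.diffusion_mcmc, seed=stage_seed(config.seed, "h4")
            )
            fits["h4"] = fit_joint_diffusion(filtered, wmc, cfg)
            results["h4"] = _flag(fits["h4"].summary(), meaningless)
            boundary = fits["h4"].boundary_export()
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "software": {"wprdm": __version__, "numpy": np.__version__},
        "blinding": config.blinding,
    }
    bundle = ReportBundle(
        results=results,
        fits=fits,
        exclusion_report=report,
        panel_data=panels,
        panel_bfs=panel_bfs,
        meaningless=meaningless,
        provenance=provenance,
        boundary_estimates=boundary,
    )
    bundle._curves = curves  # kept for exploratory reruns
    bundle._qms = qms
    bundle._filtered = filtered
    bundle._wmc = wmc
    return bundle


def run_exploratory(
    config: AnalysisConfig, confirmatory: ReportBundle
) -> ReportBundle:
    """Exploratory variants: released constraints, caution deciles, students.

    Requires the confirmatory bundle (for its preprocessed tables and the
    boundary-separation estimates exported by the joint diffusion fit).
    """
    if not hasattr(confirmatory, "_curves"):
        raise ValueError("pass the bundle returned by run_confirmatory")
    curves = confirmatory._curves
    qms = confirmatory._qms
    filtered = confirmatory._filtered
    wmc = confirmatory._wmc
    meaningless = confirmatory.meaningless

    results: dict = {}
    fits: dict = {}
    # released-constraint reruns of the WPR test
    for label, cond in (("h1a_star", "easy"), ("h1b_star", "hard")):
        cfg = dataclasses.replace(
            config.wpr_mcmc, seed=stage_seed(config.seed, "exploratory_h1")
        )
        fits[label] = fit_wpr_h1(curves[cond], constrained=False, mcmc_config=cfg)
        results[label] = _flag(fits[label].summary(), meaningless)

    # homogeneous-caution subgroups, using the boundary estimates of the
    # joint diffusion fit
    if confirmatory.boundary_estimates is None:
        raise ValueError(
            "no boundary estimates available: run_confirmatory with run_h4 "
            "enabled must precede the caution-subgroup analysis"
        )
    est = confirmatory.boundary_estimates.set_index("participant_id")["alpha_mean"]
    cfg = dataclasses.replace(
        config.wpr_mcmc, seed=stage_seed(config.seed, "caution")
    )
    _, caution_summary, caution_warns = caution_subgroup_wpr(
        qms["easy"], qms["hard"], wmc, est,
        mcmc_config=cfg, min_group_size=config.min_subgroup_size,
    )
    results["caution_subgroups"] = {
        "table": caution_summary.to_dict(orient="records"),
        "warnings": caution_warns,
    }

    # student vs non-student split
    split_info: dict = {}
    if "student" in wmc.columns:
        student = wmc["student"]
        n_missing = int(student.isna().sum())
        split_info["n_missing_student_flag"] = n_missing
        for label, mask in (("students", student == True),  # noqa: E712
                            ("non_students", student == False)):  # noqa: E712
            sub_wmc = wmc[mask.fillna(False)]
            split_info[f"n_{label}"] = int(len(sub_wmc))
            for cond in ("easy", "hard"):
                key = f"h1_{label}_{cond}"
                try:
                    curve = correlation_curve(
                        _subset_qm(qms[cond], sub_wmc), sub_wmc
                    )
                    cfg = dataclasses.replace(
                        config.wpr_mcmc, seed=stage_seed(config.seed, "students")
                    )
                    fits[key] = fit_wpr_h1(curve, constrained=True, mcmc_config=cfg)
                    results[key] = _flag(fits[key].summary(), meaningless)
                except Exception as err:  # small subgroup etc.
                    results[key] = {"skipped": str(err)}
    results["student_split"] = split_info

    provenance = dict(confirmatory.provenance)
    provenance["stage"] = "exploratory"
    return ReportBundle(
        results=results,
        fits=fits,
        exclusion_report=confirmatory.exclusion_report,
        panel_data=confirmatory.panel_data,
        panel_bfs=confirmatory.panel_bfs,
        meaningless=meaningless,
        provenance=provenance,
        boundary_estimates=confirmatory.boundary_estimates,
    )


def _subset_qm(qm, wmc_subset):
    from .data_io import QuantileMatrix

    keep = [p for p in qm.values.index if p in set(wmc_subset["participant_id"])]
    return QuantileMatrix(
        levels=qm.levels,
        values=qm.values.loc[keep],
        condition=qm.condition,
        n_trials_used=qm.n_trials_used.reindex(keep),
    )


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def render_report(bundle: ReportBundle, out_dir) -> list[str]:
    """Write summary JSON, panel data CSVs, and figures.

    Per condition: a 2 x 6 scatter grid (five WMC-quantile panels plus one
    spacer on top; WMC-accuracy plus five accuracy-quantile panels below),
    each annotated with its default-prior slope Bayes factor; plus posterior
    density figures with 95% central whiskers for the fitted hypotheses.
    Data files are written deterministically so reruns are byte-identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not bundle.results and not bundle.panel_data:
        raise ValueError("empty bundle: nothing to render")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    path = out / "summary.json"
    bundle.to_json(path)
    written.append(str(path))

    for cond, panel in bundle.panel_data.items():
        csv_path = out / f"panel_data_{cond}.csv"
        panel.sort_index().to_csv(csv_path, float_format="%.10g")
        written.append(str(csv_path))

        qcols = [c for c in panel.columns if c.startswith("q")]
        bfs = bundle.panel_bfs.get(cond, {})
        fig, axes = plt.subplots(2, 6, figsize=(18, 6), constrained_layout=True)
        for i, qc in enumerate(qcols):
            ax = axes[0, i]
            _scatter(ax, panel["wmc"], panel[qc], "WMC", f"RT {qc}",
                     bfs.get(f"wmc_q{i+1}"))
        axes[0, 5].axis("off")  # layout spacer
        _scatter(axes[1, 0], panel["wmc"], panel["accuracy"], "WMC", "accuracy",
                 bfs.get("wmc_accuracy"))
        for i, qc in enumerate(qcols):
            ax = axes[1, i + 1]
            _scatter(ax, panel["accuracy"], panel[qc], "accuracy", f"RT {qc}",
                     bfs.get(f"accuracy_q{i+1}"))
        fig.suptitle(f"{cond} items" + (" (BLINDED)" if bundle.meaningless else ""))
        fig_path = out / f"panels_{cond}.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        written.append(str(fig_path))

    dens_specs = []
    for label, fit in bundle.fits.items():
        if hasattr(fit, "beta1"):
            dens_specs.append((label, "beta1", fit.beta1))
        elif hasattr(fit, "delta"):
            dens_specs.append((label, "delta", fit.delta))
        elif hasattr(fit, "rho_samples"):
            dens_specs.append((label, "rho", np.asarray(fit.rho_samples)))
        elif hasattr(fit, "group_samples") and "delta" in getattr(fit, "group_samples", {}):
            dens_specs.append((label, "delta", fit.group_samples["delta"].ravel()))
    if dens_specs:
        fig, axes = plt.subplots(
            1, len(dens_specs), figsize=(3 * len(dens_specs), 3),
            constrained_layout=True, squeeze=False,
        )
        for ax, (label, pname, samples) in zip(axes[0], dens_specs):
            ax.hist(samples, bins=60, density=True, color="0.7")
            lo, hi = np.quantile(samples, [0.025, 0.975])
            ax.hlines(0, lo, hi, color="k", lw=3)
            ax.set_title(f"{label}: {pname}")
        fig_path = out / "posterior_densities.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        written.append(str(fig_path))

    rows = []
    for label, summ in sorted(bundle.results.items()):
        if isinstance(summ, dict) and "bf10" in summ:
            rows.append({"hypothesis": label, "bf10": summ["bf10"], "bf01": summ["bf01"]})
    table_path = out / "bayes_factors.csv"
    pd.DataFrame(rows).to_csv(table_path, index=False, float_format="%.10g")
    written.append(str(table_path))
    return written


def _scatter(ax, x, y, xlab, ylab, bf10):
    ax.plot(x, y, ".", ms=2, alpha=0.5)
    if np.std(x) > 0:
        b, a = np.polyfit(x, y, 1)
        xs = np.array([x.min(), x.max()])
        ax.plot(xs, a + b * xs, "k-", lw=1)
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    if bf10 is not None:
        ax.set_title(f"BF10 = {bf10:.3g}", fontsize=8)
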