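"""Tabular I/O, the blinding protocol, trial filtering, and quantile
preprocessing shared by every analysis stage.

Tables travel as UTF-8 CSV with a header row; all response times are in
seconds.  The blinding operations implement the key-variable permutation at
the heart of the two-stage workflow: only the WMC column is shuffled, the
permutation is sealed in an auditable record, and unblinding restores the
original table bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "AuditError",
    "FilterConfig",
    "BlindingRecord",
    "QuantileMatrix",
    "CorrelationCurve",
    "DEFAULT_LEVELS",
    "load_tables",
    "write_tables",
    "validate_trials",
    "validate_wmc",
    "blind_key_variable",
    "unblind",
    "preprocess_trials",
    "compute_quantile_matrix",
    "correlation_curve",
]

#: the five analysis quantile levels
DEFAULT_LEVELS = (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6)

TRIAL_COLUMNS = ("participant_id", "condition", "stimulus_side", "response_side", "rt")
WMC_COLUMNS = ("participant_id", "wmc")

#: dot-proportion labels mapped onto difficulty conditions
_PROPORTION_MAP = {
    "60/40": "easy",
    "40/60": "easy",
    "55/45": "hard",
    "45/55": "hard",
    "50/50": "undoable",
}


class ValidationError(ValueError):
    """Malformed input table."""


class AuditError(RuntimeError):
    """Blinding record does not match the table it is applied to."""


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table lacks required columns: {missing}")
    out = trials.copy()
    out["condition"] = out["condition"].replace(_PROPORTION_MAP)
    bad_cond = ~out["condition"].isin(["easy", "hard", "undoable"])
    if bad_cond.any():
        raise ValidationError(
            f"unrecognized condition labels at rows {list(out.index[bad_cond][:10])}"
        )
    bad_rt = ~(out["rt"] > 0)
    if bad_rt.any():
        raise ValidationError(
            f"non-positive rt at rows {list(out.index[bad_rt][:10])}"
        )
    if "correct" not in out.columns:
        out["correct"] = pd.array(
            out["response_side"] == out["stimulus_side"], dtype="boolean"
        )
        out.loc[out["condition"] == "undoable", "correct"] = pd.NA
    else:
        out["correct"] = out["correct"].astype("boolean")
    if "censored" not in out.columns:
        out["censored"] = False
    out["censored"] = out["censored"].astype(bool)
    return out


def validate_wmc(wmc: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WMC_COLUMNS if c not in wmc.columns]
    if missing:
        raise ValidationError(f"WMC table lacks required columns: {missing}")
    dup = wmc["participant_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate participants in WMC table: "
            f"{sorted(wmc.loc[dup, 'participant_id'].unique()[:10])}"
        )
    if not np.all(np.isfinite(wmc["wmc"].to_numpy(dtype=float))):
        raise ValidationError("non-finite WMC scores")
    out = wmc.copy()
    if "student" in out.columns:
        out["student"] = out["student"].astype("boolean")
    return out


def load_tables(trial_path, wmc_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the trial and WMC tables from CSV."""
    trials = pd.read_csv(trial_path)
    wmc = pd.read_csv(wmc_path)
    return validate_trials(trials), validate_wmc(wmc)


def write_tables(trials: pd.DataFrame, wmc: pd.DataFrame, trial_path, wmc_path) -> None:
    trials.to_csv(trial_path, index=False)
    wmc.to_csv(wmc_path, index=False)


# ---------------------------------------------------------------------------
# blinding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlindingRecord:
    """Sealed permutation that blinds the key variable until reversed."""

    seed: int
    permutation: tuple[int, ...]
    key_column: str = "wmc"
    created_at: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "permutation": list(self.permutation),
                    "key_column": self.key_column,
                    "created_at": self.created_at,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "BlindingRecord":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            permutation=tuple(d["permutation"]),
            key_column=d["key_column"],
            created_at=d["created_at"],
        )


def _check_bijection(perm: tuple[int, ...], n: int) -> np.ndarray:
    p = np.asarray(perm, dtype=int)
    if len(p) != n:
        raise AuditError(f"record permutes {len(p)} rows but table has {n}")
    if not np.array_equal(np.sort(p), np.arange(n)):
        raise AuditError("permutation is not a bijection on the row order")
    return p


def blind_key_variable(
    wmc: pd.DataFrame, seed: int, key_column: str = "wmc"
) -> tuple[pd.DataFrame, BlindingRecord]:
    """Shuffle only the key column across rows; everything else untouched."""
    wmc = validate_wmc(wmc)
    if key_column not in wmc.columns:
        raise ValidationError(f"no column {key_column!r} to blind")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(wmc))
    out = wmc.copy()
    out[key_column] = wmc[key_column].to_numpy()[perm]
    record = BlindingRecord(seed=int(seed), permutation=tuple(int(i) for i in perm),
                            key_column=key_column)
    return out, record


def unblind(blinded: pd.DataFrame, record: BlindingRecord) -> pd.DataFrame:
    """Invert the sealed permutation, restoring the original table exactly."""
    if record.key_column not in blinded.columns:
        raise AuditError(f"table lacks key column {record.key_column!r}")
    perm = _check_bijection(record.permutation, len(blinded))
    out = blinded.copy()
    # blinded[j] = original[perm[j]]  =>  original[perm[j]] = blinded[j]
    out[record.key_column] = blinded[record.key_column].to_numpy()[_inverse(perm)]
    return out


def _inverse(perm: np.ndarray) -> np.ndarray:
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return inv


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Trial-exclusion rules; explicit stand-ins for the analyst's choices."""

    min_rt: float = 0.2  # fast-guess bound (s)
    rt_cutoff: float = 3.5  # too-slow bound, closed at the cutoff (s)
    drop_censored: bool = True
    min_correct_per_difficulty: int = 20  # warning threshold


def preprocess_trials(
    trials: pd.DataFrame, filter_config: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the default exclusion rules and account for every dropped row.

    Returns the filtered table and a JSON-able exclusion report with counts
    per filter, per participant, and warnings for participants left with few
    correct trials per difficulty.
    """
    cfg = filter_config or FilterConfig()
    trials = validate_trials(trials)
    n0 = len(trials)
    drop_censored = trials["censored"].to_numpy() if cfg.drop_censored else np.zeros(n0, bool)
    drop_slow = trials["rt"].to_numpy() >= cfg.rt_cutoff
    drop_fast = trials["rt"].to_numpy() < cfg.min_rt
    dropped = drop_censored | drop_slow | drop_fast
    out = trials.loc[~dropped].reset_index(drop=True)

    per_participant = (
        pd.Series(dropped, index=trials["participant_id"]).groupby(level=0).sum()
    )
    report: dict = {
        "n_input": int(n0),
        "n_kept": int(len(out)),
        "dropped_censored": int(drop_censored.sum()),
        "dropped_slow": int((drop_slow & ~drop_censored).sum()),
        "dropped_fast": int(drop_fast.sum()),
        "dropped_per_participant": {
            k: int(v) for k, v in per_participant.items() if v > 0
        },
        "warnings": [],
    }
    if len(out) == 0 or out["participant_id"].nunique() == 0:
        raise ValidationError("no participants remain after filtering")
    doable = out[out["condition"].isin(["easy", "hard"])]
    counts = (
        doable[doable["correct"] == True]  # noqa: E712 (nullable boolean)
        .groupby(["participant_id", "condition"], observed=True)
        .size()
    )
    for (pid, cond), cnt in counts.items():
        if cnt < cfg.min_correct_per_difficulty:
            report["warnings"].append(
                f"participant {pid} has only {int(cnt)} correct {cond} trials"
            )
    return out, report


# ---------------------------------------------------------------------------
# quantiles and correlation curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantileMatrix:
    """Per-participant RT quantiles at fixed levels, one condition."""

    levels: tuple[float, ...]
    values: pd.DataFrame  # participants x levels
    condition: str
    n_trials_used: pd.Series
    excluded: tuple[str, ...] = ()


@dataclass(frozen=True)
class CorrelationCurve:
    """Sample Pearson correlations of WMC with each RT quantile."""

    levels: tuple[float, ...]
    r: np.ndarray
    n: int
    condition: str = ""
    r_wmc_accuracy: float | None = None
    r_accuracy_quantile: np.ndarray | None = None


def compute_quantile_matrix(
    trials: pd.DataFrame,
    condition: str,
    levels=DEFAULT_LEVELS,
    mode: str = "quantile",
) -> QuantileMatrix:
    """Empirical correct-RT quantiles per participant.

    ``mode='quantile'`` evaluates the quantile values themselves with the
    linear order-statistic interpolation convention; ``mode='band_mean'``
    instead averages RTs within the six bands cut at the five quantiles and
    reports band means at the band-midpoint levels.
    """
    levels = tuple(float(l) for l in levels)
    if any(not (0 < l < 1) for l in levels) or list(levels) != sorted(set(levels)):
        raise ValueError("levels must be strictly increasing within (0, 1)")
    if condition == "undoable":
        raise ValueError("undoable trials have no correct response to condition on")
    sub = trials[(trials["condition"] == condition) & (trials["correct"] == True)]  # noqa: E712
    rows, ns, excluded = {}, {}, []
    for pid, grp in sub.groupby("participant_id", observed=True, sort=True):
        rts = np.sort(grp["rt"].to_numpy(dtype=float))
        if len(rts) == 0:
            excluded.append(str(pid))
            continue
        if mode == "quantile":
            rows[pid] = np.quantile(rts, levels, method="linear")
        elif mode == "band_mean":
            cuts = np.quantile(rts, levels, method="linear")
            bands = np.searchsorted(cuts, rts, side="right")
            rows[pid] = np.array(
                [rts[bands == b].mean() if (bands == b).any() else np.nan
                 for b in range(len(levels) + 1)]
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        ns[pid] = len(rts)
    all_pids = trials.loc[trials["condition"] == condition, "participant_id"].unique()
    excluded.extend(str(p) for p in all_pids if p not in rows and str(p) not in excluded)
    if mode == "band_mean":
        edges = (0.0,) + levels + (1.0,)
        out_levels = tuple((edges[i] + edges[i + 1]) / 2 for i in range(len(levels) + 1))
    else:
        out_levels = levels
    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(out_levels))
    values.index.name = "participant_id"
    return QuantileMatrix(
        levels=out_levels,
        values=values,
        condition=condition,
        n_trials_used=pd.Series(ns, name="n_trials_used"),
        excluded=tuple(sorted(excluded)),
    )


def correlation_curve(
    qm: QuantileMatrix,
    wmc: pd.DataFrame,
    accuracy: pd.Series | None = None,
) -> CorrelationCurve:
    """Pearson correlation of WMC with each quantile column.

    Optionally also correlates WMC and each quantile with per-participant
    accuracy for the descriptive scatter panels.
    """
    wmc = validate_wmc(wmc)
    merged = qm.values.join(
        wmc.set_index("participant_id")["wmc"], how="inner"
    ).dropna()
    if len(merged) < 4:
        raise ValidationError(
            f"need >= 4 participants with both quantiles and WMC, have {len(merged)}"
        )
    w = merged["wmc"].to_numpy(dtype=float)
    if np.std(w) == 0:
        raise ValidationError("zero variance in column 'wmc'")
    rs = []
    for lvl in qm.levels:
        q = merged[lvl].to_numpy(dtype=float)
        if np.std(q) == 0:
            raise ValidationError(f"zero variance in quantile column {lvl}")
        rs.append(float(np.corrcoef(w, q)[0, 1]))
    r_wa, r_aq = None, None
    if accuracy is not None:
        acc = accuracy.reindex(merged.index).to_numpy(dtype=float)
        ok = np.isfinite(acc)
        if ok.sum() >= 4 and np.std(acc[ok]) > 0:
            r_wa = float(np.corrcoef(w[ok], acc[ok])[0, 1])
            r_aq = np.array(
                [
                    float(np.corrcoef(acc[ok], merged[lvl].to_numpy(dtype=float)[ok])[0, 1])
                    for lvl in qm.levels
                ]
            )
    return CorrelationCurve(
        levels=qm.levels,
        r=np.array(rs),
        n=int(len(merged)),
        condition=qm.condition,
        r_wmc_accuracy=r_wa,
        r_accuracy_quantile=r_aq,
    )
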