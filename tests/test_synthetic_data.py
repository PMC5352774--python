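"""Synthetic population generator: configured structure must be recovered."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from wprdm import data_io as dio
from wprdm import synthetic_data as sd


def _fast_cfg(**kw):
    base = dict(
        n_participants=50, trials_easy=2, trials_hard=2, trials_undoable=0, seed=1
    )
    base.update(kw)
    return sd.scenario_config("wpr_true", **base)


class TestScenarioConfig:
    def test_presets_load_from_config_files(self):
        cfg = sd.scenario_config("caution_confound")
        assert cfg.rho_boundary_wmc == 0.5
        assert cfg.rho_drift_wmc_hard == 0.0
        assert sd.scenario_config("wpr_true").rt_cutoff == 3.5

    def test_default_task_design(self):
        cfg = sd.scenario_config("wpr_true")
        assert (cfg.n_participants, cfg.trials_easy, cfg.trials_hard) == (916, 90, 90)

    def test_inadmissible_correlations_rejected_before_simulation(self):
        with pytest.raises(sd.ConfigError):
            _fast_cfg(rho_drift_wmc_easy=0.9, rho_drift_wmc_hard=0.9,
                      rho_drift_drift=-0.9)
        with pytest.raises(sd.ConfigError):
            _fast_cfg(contamination_rate=1.5)
        with pytest.raises(sd.ConfigError):
            _fast_cfg(rt_cutoff=-1.0)


class TestGeneratePopulation:
    def test_trial_counts_match_design(self):
        cfg = sd.scenario_config("wpr_true", n_participants=3, seed=2)
        trials, wmc, _ = sd.generate_population(cfg)
        counts = trials.groupby(["participant_id", "condition"], observed=True).size()
        for pid in wmc["participant_id"]:
            assert counts[(pid, "easy")] == 90
            assert counts[(pid, "hard")] == 90
            assert counts[(pid, "undoable")] == 45

    def test_null_scenario_has_no_wmc_drift_association(self):
        cfg = sd.scenario_config("null", n_participants=2000, trials_easy=1,
                                 trials_hard=1, trials_undoable=0, seed=3)
        _, wmc, truth = sd.generate_population(cfg)
        m = truth.participants
        r = np.corrcoef(m["wmc"], m["nu_hard"])[0, 1]
        assert abs(r) < 3 / np.sqrt(2000)

    def test_configured_drift_wmc_correlation_recovered(self):
        cfg = _fast_cfg(n_participants=2000, rho_drift_wmc_hard=0.5, seed=4)
        _, _, truth = sd.generate_population(cfg)
        m = truth.participants
        r = np.corrcoef(m["wmc"], m["nu_hard"])[0, 1]
        se = (1 - 0.5**2) / np.sqrt(2000)  # large-sample SE of r at rho=.5
        assert abs(r - 0.5) < 3 * se

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = _fast_cfg(seed=9)
        t1, w1, _ = sd.generate_population(cfg)
        t2, w2, _ = sd.generate_population(cfg)
        assert_frame_equal(t1, t2)
        assert_frame_equal(w1, w2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        t1.to_csv(p1, index=False)
        t2.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_undoable_trials_have_no_correct_flag(self):
        cfg = sd.scenario_config("wpr_true", n_participants=4, trials_easy=4,
                                 trials_hard=4, trials_undoable=4, seed=5)
        trials, _, _ = sd.generate_population(cfg)
        und = trials[trials["condition"] == "undoable"]
        assert und["correct"].isna().all()
        doable = trials[trials["condition"] != "undoable"]
        assert doable["correct"].notna().all()

    def test_stimulus_sides_balanced(self):
        cfg = sd.scenario_config("wpr_true", n_participants=4, trials_easy=30,
                                 trials_hard=0, trials_undoable=0, seed=6)
        trials, _, _ = sd.generate_population(cfg)
        per = trials.groupby("participant_id", observed=True)["stimulus_side"].apply(
            lambda s: (s == "left").sum()
        )
        assert (per == 15).all()


class TestContaminationAndCensoring:
    def test_identity_when_disabled(self):
        cfg = _fast_cfg(n_participants=20, trials_easy=10, seed=7,
                        contamination_rate=0.0, rt_cutoff=float("inf"))
        trials, _, _ = sd.generate_population(cfg)
        out = sd.apply_contamination_and_censoring(trials, cfg)
        assert_frame_equal(out.drop(columns="is_contaminant"), trials)
        assert not out["is_contaminant"].any()

    def test_cutoff_is_closed_and_exact(self):
        cfg = _fast_cfg(n_participants=20, trials_easy=10, seed=8)
        trials, _, _ = sd.generate_population(cfg)
        trials.loc[0, "rt"] = 3.6
        trials.loc[1, "rt"] = 3.5
        trials.loc[2, "rt"] = 3.4999
        out = sd.apply_contamination_and_censoring(trials, cfg)
        assert bool(out.loc[0, "censored"]) and bool(out.loc[1, "censored"])
        assert not bool(out.loc[2, "censored"])

    def test_contaminant_count_binomial(self):
        cfg = sd.scenario_config("wpr_true", n_participants=56, trials_easy=90,
                                 trials_hard=90, trials_undoable=0, seed=9,
                                 contamination_rate=0.05)
        trials, _, _ = sd.generate_population(cfg)
        out = sd.apply_contamination_and_censoring(trials, cfg)
        n = len(out)
        expected = 0.05 * n
        se = np.sqrt(n * 0.05 * 0.95)
        assert abs(out["is_contaminant"].sum() - expected) < 3 * se
        assert len(out) == len(trials)  # row count preserved


class TestMechanismSignatures:
    """The two causal structures leave opposite fingerprints on the
    quantile-correlation curve."""

    @staticmethod
    def _mean_curve(scenario, seeds, n=300):
        curves = []
        for seed in seeds:
            cfg = sd.scenario_config(scenario, n_participants=n, trials_undoable=0,
                                     seed=seed)
            trials, wmc, _ = sd.generate_population(cfg)
            qm = dio.compute_quantile_matrix(trials, "hard")
            curves.append(dio.correlation_curve(qm, wmc).r)
        return np.mean(curves, axis=0)

    def test_drift_coupling_gives_negative_decreasing_curve(self):
        r = self._mean_curve("wpr_true", [21, 22, 23])
        assert np.all(r < 0)
        assert r[-1] < r[0]

    def test_caution_coupling_gives_positive_increasing_curve(self):
        r = self._mean_curve("caution_confound", [24, 25, 26])
        assert np.all(r > 0)
        assert r[-1] > r[0]
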