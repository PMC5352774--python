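"""Tables, blinding protocol, filtering and quantile preprocessing."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal, assert_series_equal

from oracles import pearson_longhand, quantile_sort_interpolate
from wprdm import data_io as dio


def _toy_trials():
    rng = np.random.default_rng(0)
    rows = []
    for pid in ("a", "b", "c", "d", "e", "f"):
        for i in range(30):
            rows.append(
                {
                    "participant_id": pid,
                    "condition": "easy" if i % 2 == 0 else "hard",
                    "stimulus_side": "left" if i % 2 else "right",
                    "response_side": "left" if i % 2 else "right",
                    "correct": True,
                    "rt": float(0.4 + 0.1 * rng.random() + 0.02 * i),
                    "censored": False,
                }
            )
    return pd.DataFrame(rows)


def _toy_wmc():
    return pd.DataFrame(
        {
            "participant_id": ["a", "b", "c", "d", "e", "f"],
            "wmc": [-1.2, -0.4, 0.0, 0.3, 0.9, 1.6],
            "student": [True, True, False, True, None, False],
        }
    )


class TestLoadValidate:
    def test_missing_rt_column_rejected(self, tmp_path):
        bad = _toy_trials().drop(columns="rt")
        p = tmp_path / "t.csv"
        bad.to_csv(p, index=False)
        _toy_wmc().to_csv(tmp_path / "w.csv", index=False)
        with pytest.raises(dio.ValidationError, match="rt"):
            dio.load_tables(p, tmp_path / "w.csv")

    def test_roundtrip_preserves_tables(self, tmp_path):
        trials, wmc = _toy_trials(), _toy_wmc()
        dio.write_tables(trials, wmc, tmp_path / "t.csv", tmp_path / "w.csv")
        t2, w2 = dio.load_tables(tmp_path / "t.csv", tmp_path / "w.csv")
        assert_frame_equal(dio.validate_trials(trials), t2)
        assert np.allclose(wmc["wmc"], w2["wmc"])

    def test_dot_proportions_normalised_to_conditions(self):
        t = _toy_trials()
        t.loc[0, "condition"] = "60/40"
        t.loc[1, "condition"] = "55/45"
        t.loc[2, "condition"] = "50/50"
        out = dio.validate_trials(t)
        assert out.loc[0, "condition"] == "easy"
        assert out.loc[1, "condition"] == "hard"
        assert out.loc[2, "condition"] == "undoable"

    def test_duplicate_participant_rejected(self):
        w = _toy_wmc()
        w.loc[5, "participant_id"] = "a"
        with pytest.raises(dio.ValidationError, match="duplicate"):
            dio.validate_wmc(w)

    def test_nonpositive_rt_rejected(self):
        t = _toy_trials()
        t.loc[3, "rt"] = 0.0
        with pytest.raises(dio.ValidationError, match="rt"):
            dio.validate_trials(t)


class TestBlinding:
    def test_roundtrip_is_bit_exact(self):
        wmc = _toy_wmc()
        blinded, record = dio.blind_key_variable(wmc, seed=42)
        restored = dio.unblind(blinded, record)
        assert_series_equal(restored["wmc"], dio.validate_wmc(wmc)["wmc"])

    def test_same_seed_same_permutation(self):
        wmc = _toy_wmc()
        _, r1 = dio.blind_key_variable(wmc, seed=7)
        _, r2 = dio.blind_key_variable(wmc, seed=7)
        assert r1.permutation == r2.permutation

    def test_only_key_column_is_touched(self):
        wmc = dio.validate_wmc(_toy_wmc())
        blinded, _ = dio.blind_key_variable(wmc, seed=3)
        assert list(blinded["participant_id"]) == list(wmc["participant_id"])
        assert_series_equal(blinded["student"], wmc["student"])
        assert sorted(blinded["wmc"]) == sorted(wmc["wmc"])  # multiset kept

    def test_tampered_permutation_is_an_audit_error(self):
        wmc = _toy_wmc()
        blinded, record = dio.blind_key_variable(wmc, seed=1)
        bad = dio.BlindingRecord(
            seed=1, permutation=(0, 0, 1, 2, 3, 4), key_column="wmc"
        )
        with pytest.raises(dio.AuditError, match="bijection"):
            dio.unblind(blinded, bad)

    def test_record_from_other_table_is_an_audit_error(self):
        wmc = _toy_wmc()
        blinded, record = dio.blind_key_variable(wmc, seed=1)
        with pytest.raises(dio.AuditError, match="rows"):
            dio.unblind(blinded.iloc[:4], record)

    def test_record_json_roundtrip(self, tmp_path):
        _, record = dio.blind_key_variable(_toy_wmc(), seed=11)
        p = tmp_path / "rec.json"
        record.to_json(p)
        back = dio.BlindingRecord.from_json(p)
        assert back.permutation == record.permutation
        assert back.seed == record.seed


class TestPreprocess:
    def test_clean_table_passes_untouched(self):
        trials = dio.validate_trials(_toy_trials())
        out, report = dio.preprocess_trials(trials)
        assert len(out) == len(trials)
        assert report["dropped_censored"] == report["dropped_fast"] == 0

    def test_toy_exclusion_counts(self):
        trials = _toy_trials().iloc[:10].copy()
        trials.loc[trials.index[0], "rt"] = 0.05  # fast guess
        trials.loc[trials.index[1], "rt"] = 0.19  # fast guess
        trials.loc[trials.index[2], "censored"] = True
        out, report = dio.preprocess_trials(trials)
        assert len(out) == 7
        assert report["dropped_fast"] == 2
        assert report["dropped_censored"] == 1

    def test_cutoff_closed_at_boundary(self):
        trials = _toy_trials()
        trials.loc[trials.index[0], "rt"] = 3.5
        out, report = dio.preprocess_trials(trials)
        assert len(out) == len(trials) - 1
        assert report["dropped_slow"] == 1

    def test_sparse_participant_triggers_warning(self):
        trials = _toy_trials()
        out, report = dio.preprocess_trials(trials)
        # 15 correct trials per difficulty < 20 for every participant here
        assert any("correct" in w for w in report["warnings"])

    def test_all_rows_filtered_is_an_error(self):
        trials = _toy_trials()
        trials["rt"] = 0.01
        with pytest.raises(dio.ValidationError, match="no participants"):
            dio.preprocess_trials(trials)


class TestQuantileMatrix:
    def test_degenerate_distribution(self):
        trials = _toy_trials()
        trials["rt"] = 0.7
        qm = dio.compute_quantile_matrix(trials, "easy")
        assert np.allclose(qm.values.to_numpy(), 0.7)

    def test_default_levels_are_sixths(self):
        qm = dio.compute_quantile_matrix(_toy_trials(), "easy")
        assert qm.levels == tuple(i / 6 for i in range(1, 6))

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(5)
        rts = np.round(0.3 + rng.random(7), 4)
        trials = pd.DataFrame(
            {
                "participant_id": "z",
                "condition": "hard",
                "stimulus_side": "left",
                "response_side": "left",
                "correct": True,
                "rt": rts,
                "censored": False,
            }
        )
        qm = dio.compute_quantile_matrix(trials, "hard", levels=(0.5,))
        assert qm.values.iloc[0, 0] == pytest.approx(
            quantile_sort_interpolate(rts, 0.5), abs=1e-12
        )

    def test_rows_nondecreasing_across_levels(self, small_scenario):
        _, trials, _, _ = small_scenario
        qm = dio.compute_quantile_matrix(trials, "hard")
        assert (qm.values.diff(axis=1).iloc[:, 1:] >= -1e-12).all().all()

    def test_participant_without_correct_trials_excluded(self):
        trials = _toy_trials()
        trials.loc[trials["participant_id"] == "a", "correct"] = False
        qm = dio.compute_quantile_matrix(trials, "easy")
        assert "a" in qm.excluded
        assert "a" not in qm.values.index

    def test_undoable_condition_rejected(self):
        with pytest.raises(ValueError, match="undoable"):
            dio.compute_quantile_matrix(_toy_trials(), "undoable")

    def test_band_mean_mode_monotone(self, small_scenario):
        _, trials, _, _ = small_scenario
        qm = dio.compute_quantile_matrix(trials, "hard", mode="band_mean")
        assert len(qm.levels) == 6
        assert (qm.values.diff(axis=1).iloc[:, 1:] >= -1e-12).all().all()


class TestCorrelationCurve:
    def test_self_correlation_is_one(self):
        wmc = _toy_wmc().drop(columns="student")
        qm = dio.QuantileMatrix(
            levels=(0.5,),
            values=pd.DataFrame(
                {0.5: wmc["wmc"].to_numpy()},
                index=pd.Index(wmc["participant_id"], name="participant_id"),
            ),
            condition="easy",
            n_trials_used=pd.Series(10, index=wmc["participant_id"]),
        )
        curve = dio.correlation_curve(qm, wmc)
        assert curve.r[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_wmc_is_zero_variance_error(self):
        wmc = _toy_wmc()
        wmc["wmc"] = 1.0
        qm = dio.compute_quantile_matrix(_toy_trials(), "easy")
        with pytest.raises(dio.ValidationError, match="wmc"):
            dio.correlation_curve(qm, wmc)

    def test_matches_longhand_pearson(self):
        trials, wmc = _toy_trials(), _toy_wmc()
        qm = dio.compute_quantile_matrix(trials, "easy")
        curve = dio.correlation_curve(qm, wmc)
        for i, lvl in enumerate(qm.levels):
            expected = pearson_longhand(
                wmc.set_index("participant_id")["wmc"].reindex(qm.values.index),
                qm.values[lvl],
            )
            assert curve.r[i] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_affine_rescaling(self):
        trials, wmc = _toy_trials(), _toy_wmc()
        qm = dio.compute_quantile_matrix(trials, "easy")
        base = dio.correlation_curve(qm, wmc)
        wmc2 = wmc.copy()
        wmc2["wmc"] = 3.7 * wmc2["wmc"] - 11.0
        qm_ms = dio.QuantileMatrix(
            levels=qm.levels,
            values=qm.values * 1000.0,  # seconds -> milliseconds
            condition=qm.condition,
            n_trials_used=qm.n_trials_used,
        )
        rescaled = dio.correlation_curve(qm_ms, wmc2)
        assert np.allclose(base.r, rescaled.r, atol=1e-12)

    def test_accuracy_correlations_returned(self, small_scenario):
        _, trials, wmc, _ = small_scenario
        qm = dio.compute_quantile_matrix(trials, "hard")
        acc = (
            trials[trials["condition"] == "hard"]
            .groupby("participant_id", observed=True)["correct"]
            .mean()
            .astype(float)
        )
        curve = dio.correlation_curve(qm, wmc, accuracy=acc)
        assert curve.r_wmc_accuracy is not None
        assert len(curve.r_accuracy_quantile) == len(curve.levels)
        assert len(curve.r) == len(curve.levels)
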