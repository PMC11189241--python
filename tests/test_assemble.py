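"""Assembly rules: aggregation, window selection, drop rule, imputation,
median-split labels, per-participant z-normalization."""

import numpy as np
import pandas as pd
import pytest

from lonesense.assemble import (aggregate_last, aggregate_point, filter_missing,
                                impute_neighbors, impute_participant_mean,
                                make_labels, select_imputation, select_windows,
                                training_row_mask, znormalize_split)
from lonesense.errors import DataError

H = 3600.0


class TestAggregation:
    def test_single_value_in_window(self):
        t = np.array([9 * H])
        v = np.array([5.0])
        out = aggregate_point(t, v, np.array([10 * H]), 4 * H, "mean")
        assert out[0] == 5.0

    def test_counts_sum(self):
        t = np.array([1 * H, 2 * H])
        v = np.array([2.0, 3.0])
        out = aggregate_point(t, v, np.array([3 * H]), 4 * H, "sum")
        assert out[0] == 5.0

    def test_empty_window_missing_for_mean(self):
        out = aggregate_point(np.array([100.0]), np.array([1.0]),
                              np.array([50.0]), 10.0, "mean")
        assert np.isnan(out[0])

    def test_window_excludes_ema_instant(self):
        # [t - w, t): a value exactly at the EMA time is outside
        t = np.array([10 * H])
        out = aggregate_point(t, np.array([1.0]), np.array([10 * H]), 4 * H, "sum")
        assert out[0] == 0.0

    def test_last_value_with_lookback_cap(self):
        t = np.array([0.0, 10 * H])
        v = np.array([1.0, 2.0])
        out = aggregate_last(t, v, np.array([12 * H, 60 * H]))
        assert out[0] == 2.0
        assert np.isnan(out[1])  # older than the 36-h cap


class TestWindowSelection:
    def _planted(self, rng, n=200):
        scores = rng.normal(0, 1, n)
        cand = {"f": {4: rng.normal(0, 1, n),
                      8: rng.normal(0, 1, n),
                      24: scores + rng.normal(0, 0.5, n)}}
        return cand, scores

    def test_planted_window_selected(self, rng):
        cand, scores = self._planted(rng)
        train = np.ones(len(scores), dtype=bool)
        spec = select_windows(cand, scores, train, (4, 8, 24))
        assert spec["f"].window_hours == 24

    def test_anticorrelated_feature_selected_by_abs(self, rng):
        n = 200
        scores = rng.normal(0, 1, n)
        cand = {"f": {4: rng.normal(0, 1, n), 24: -scores + rng.normal(0, 0.5, n)}}
        spec = select_windows(cand, scores, np.ones(n, bool), (4, 24))
        assert spec["f"].window_hours == 24

    def test_constant_feature_default_window_flagged(self, rng):
        n = 50
        cand = {"f": {4: np.ones(n), 24: np.ones(n)}}
        spec = select_windows(cand, rng.normal(0, 1, n), np.ones(n, bool), (4, 24))
        assert spec["f"].window_hours == 24 and spec["f"].flagged

    def test_tie_goes_to_shorter_window(self, rng):
        n = 100
        scores = rng.normal(0, 1, n)
        x = scores.copy()
        cand = {"f": {4: x, 24: x.copy()}}
        spec = select_windows(cand, scores, np.ones(n, bool), (4, 24))
        assert spec["f"].window_hours == 4

    def test_selection_ignores_test_rows(self, rng):
        cand, scores = self._planted(rng)
        train = np.zeros(len(scores), dtype=bool)
        train[:100] = True
        spec1 = select_windows(cand, scores, train)
        # scramble every non-training value; the choice must not move
        cand2 = {f: {w: v.copy() for w, v in per.items()} for f, per in cand.items()}
        for per in cand2.values():
            for v in per.values():
                v[~train] = rng.normal(0, 10, (~train).sum())
        scores2 = scores.copy()
        scores2[~train] = rng.normal(0, 10, (~train).sum())
        spec2 = select_windows(cand2, scores2, train)
        assert spec1["f"].window_hours == spec2["f"].window_hours


class TestMissingFilter:
    def test_strict_boundary(self):
        n = 100
        at = np.ones(n)
        at[:30] = np.nan  # exactly 30% -> retained
        above = np.ones(n)
        above[:31] = np.nan  # 31% -> dropped
        kept, dropped = filter_missing({"at": at, "above": above})
        assert "at" in kept
        assert dropped == [("above", pytest.approx(0.31))]

    def test_no_missing_nothing_dropped(self):
        kept, dropped = filter_missing({"a": np.ones(5)})
        assert not dropped

    def test_all_dropped_is_error(self):
        with pytest.raises(DataError):
            filter_missing({"a": np.full(10, np.nan)})


def _one_participant(values):
    arr = np.asarray(values, dtype=float)
    groups = {"p": np.arange(len(arr))}
    t = np.arange(len(arr), dtype=float)
    return arr, groups, t


class TestImputation:
    def test_method_a_worked_example(self):
        arr, groups, t = _one_participant([1, 2, np.nan, 4, 5])
        out = impute_neighbors(arr, groups, t)
        assert out[2] == pytest.approx(3.0)

    def test_method_a_edge_uses_available_side(self):
        arr, groups, t = _one_participant([np.nan, 7])
        out = impute_neighbors(arr, groups, t)
        assert out[0] == pytest.approx(7.0)

    def test_method_b_participant_mean(self):
        arr, groups, t = _one_participant([2, 4, np.nan, 6])
        out = impute_participant_mean(arr, groups)
        assert out[2] == pytest.approx(4.0)

    def test_imputation_never_alters_observed(self, rng):
        arr = rng.normal(0, 1, 50)
        arr[rng.choice(50, 10, replace=False)] = np.nan
        groups = {"p": np.arange(50)}
        obs = np.isfinite(arr)
        a = impute_neighbors(arr, groups, np.arange(50.0))
        b = impute_participant_mean(arr, groups)
        assert np.array_equal(a[obs], arr[obs])
        assert np.array_equal(b[obs], arr[obs])


class TestImputationSelection:
    def _values(self, rng, b_wins: int, total: int = 10, n: int = 120):
        """Plant features where method B's fill tracks the scores better (or
        worse) by making the participant mean informative vs. disruptive."""
        scores = np.tile(rng.normal(0, 1, 2), n // 2)  # two-level score per pid
        pids = np.repeat(["p1", "p2"], n // 2)
        groups = {p: np.flatnonzero(pids == p) for p in ("p1", "p2")}
        values = {}
        for k in range(total):
            base = np.where(pids == "p1", scores[0], scores[1]) + rng.normal(0, 0.1, n)
            miss = rng.choice(n, n // 4, replace=False)
            if k < b_wins:
                # neighbours are corrupted, participant mean is clean
                v = base.copy()
                v[miss] = np.nan
                noise_at = np.clip(np.concatenate([miss - 1, miss + 1]), 0, n - 1)
                v[np.setdiff1d(noise_at, miss)] += rng.normal(0, 5, 1)
            else:
                # within-participant trend: local neighbours beat the mean
                v = base + np.linspace(-2, 2, n) * np.where(pids == "p1", 1, -1) * \
                    np.sign(scores[0] - scores[1] + 1e-9)
                v[miss] = np.nan
            values[k] = v
        return values, groups, np.arange(n, dtype=float), scores

    def test_majority_b_applied_everywhere(self, rng):
        values, groups, t, scores = self._values(rng, b_wins=8)
        method, _ = select_imputation(values, groups, t, scores, np.ones(len(t), bool))
        assert method == "B"

    def test_tie_defaults_to_b(self):
        method, _ = select_imputation({}, {}, np.empty(0), np.empty(0),
                                      np.empty(0, dtype=bool))
        assert method == "B"

    def test_no_missing_reports_b(self, rng):
        n = 40
        scores = rng.normal(0, 1, n)
        values = {"f": scores + rng.normal(0, 0.1, n)}
        groups = {"p": np.arange(n)}
        method, stats = select_imputation(values, groups, np.arange(n, dtype=float),
                                          scores, np.ones(n, bool))
        assert method == "B"
        ra, rb = stats["f"]
        assert ra == pytest.approx(rb)


class TestLabels:
    def _ema(self, scores, pid="p1"):
        return pd.DataFrame({"participant_id": pid, "t": np.arange(len(scores), dtype=float),
                             "score": scores})

    def test_median_split_worked_example(self):
        labels, excluded = make_labels(self._ema([10, 20, 30, 40]))
        assert labels.tolist() == [0, 0, 1, 1]
        assert not excluded

    def test_scores_at_median_are_not_lonely(self):
        labels, _ = make_labels(self._ema([50, 50, 50, 80]))
        assert labels.tolist() == [0, 0, 0, 1]

    def test_constant_scores_participant_excluded(self):
        with pytest.warns(UserWarning):
            labels, excluded = make_labels(self._ema([50, 50, 50, 50]))
        assert excluded == ["p1"]

    def test_continuous_scores_balanced_prevalence(self, rng):
        n = 401
        labels, _ = make_labels(self._ema(rng.normal(50, 10, n)))
        assert abs(labels.mean() - 0.5) <= 1.0 / np.sqrt(n)


class TestZNormalization:
    def _df(self):
        return pd.DataFrame({
            "participant_id": ["a", "a", "a", "b", "b", "b"],
            "t": [0, 1, 2, 0, 1, 2],
            "f": [1.0, 3.0, 2.0, 10.0, 30.0, 20.0],
        })

    def test_two_point_training_maps_to_unit(self):
        df = self._df()
        out, _ = znormalize_split(df, ["f"], np.array([0, 1, 3, 4]))
        assert out.loc[0, "f"] == pytest.approx(-1.0)
        assert out.loc[1, "f"] == pytest.approx(1.0)

    def test_test_value_at_training_mean_maps_to_zero(self):
        df = self._df()
        out, _ = znormalize_split(df, ["f"], np.array([0, 1, 3, 4]))
        assert out.loc[2, "f"] == pytest.approx(0.0)  # 2.0 == mean(1, 3)

    def test_constant_training_feature_flagged_zero(self):
        df = self._df()
        df.loc[[0, 1], "f"] = 5.0
        out, flags = znormalize_split(df, ["f"], np.array([0, 1, 3, 4]))
        assert out.loc[0, "f"] == 0.0
        assert "a" in flags["constant_training_feature"]

    def test_absent_participant_errors(self):
        df = self._df()
        with pytest.raises(DataError):
            znormalize_split(df, ["f"], np.array([0, 1, 2]))  # 'b' not in training

    def test_training_columns_standardised(self, rng):
        n = 60
        df = pd.DataFrame({
            "participant_id": np.repeat(["a", "b", "c"], n // 3),
            "t": np.tile(np.arange(n // 3), 3),
            "f1": rng.normal(5, 3, n), "f2": rng.normal(-2, 0.5, n),
        })
        train = np.flatnonzero(np.tile(np.arange(n // 3) < 10, 3))
        out, _ = znormalize_split(df, ["f1", "f2"], train)
        for pid, sub in out.loc[train].groupby("participant_id"):
            for c in ("f1", "f2"):
                assert sub[c].mean() == pytest.approx(0.0, abs=1e-9)
                assert sub[c].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


class TestTrainingRowMask:
    def test_earliest_half_ceiling(self):
        ema = pd.DataFrame({"participant_id": ["p"] * 5, "t": [4.0, 0, 1, 2, 3],
                            "score": [1, 2, 3, 4, 5]})
        mask = training_row_mask(ema)
        assert mask.sum() == 3  # ceil(5/2)
        assert mask[np.argsort(ema["t"].to_numpy())[:3]].all()


class TestEndToEndAssembly:
    def test_small_cohort_assembles(self, small_assembly):
        table = small_assembly.materialize()
        df = table.df
        assert set(df["label"]) <= {0, 1}
        assert not df[table.feature_cols].isna().any().any()
        devices = set(table.device_of.values())
        assert devices == {"ring", "watch", "phone"}

    def test_device_subset_restricts_columns(self, small_assembly):
        phone = small_assembly.materialize(["phone"])
        assert all(small_assembly.device_of[c] == "phone" for c in phone.feature_cols)
        assert not any(c.startswith(("hrv_", "sleep_")) for c in phone.feature_cols)

    def test_row_count_matches_labelled_emas(self, small_cohort, small_assembly):
        kept = ~small_cohort.ema["participant_id"].isin(
            small_assembly.excluded_participants)
        assert len(small_assembly.ema) == int(kept.sum())
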