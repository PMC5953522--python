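"""Encounter summarisation: outlier rule, per-category stats, billable minutes."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hewcost as h
from hewcost.tms_stats import exclude_outliers, read_observation_log


def oracle_exclude(durations, two_sided=False):
    """Independent brute-force evaluation of the 3-SD rule (stdlib statistics)."""
    mu = statistics.fmean(durations)
    sigma = statistics.stdev(durations) if len(durations) > 1 else 0.0
    kept = []
    n_excl = 0
    for v in durations:
        too_high = v > mu + 3 * sigma
        too_low = two_sided and v < mu - 3 * sigma
        if too_high or too_low:
            n_excl += 1
        else:
            kept.append(v)
    return kept, n_excl


class TestExcludeOutliers:
    @pytest.mark.parametrize(
        "durations",
        [
            [10.0],
            [2.0, 4.0, 6.0, 8.0],
            [5.0] * 9 + [500.0],
            [1.0] * 30 + [1000.0],
            [0.0, 0.0, 5.0],
        ],
    )
    def test_matches_brute_force_oracle(self, durations):
        kept, n_excl = exclude_outliers(durations)
        exp_kept, exp_excl = oracle_exclude(durations)
        assert kept == pytest.approx(exp_kept)
        assert n_excl == exp_excl

    def test_single_value_never_excluded(self):
        assert exclude_outliers([10.0]) == ([10.0], 0)

    def test_values_below_mean_kept_one_sided(self):
        # a near-zero duration among large ones survives the one-sided rule
        durations = [0.1] + [50.0] * 20
        kept, _ = exclude_outliers(durations)
        assert 0.1 in kept

    def test_two_sided_switch(self):
        durations = [0.0] * 2 + [100.0] * 48
        one, _ = exclude_outliers(durations, two_sided=False)
        two, _ = exclude_outliers(durations, two_sided=True)
        assert len(two) <= len(one)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            exclude_outliers([])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=1, max_size=100)
    )
    def test_oracle_equivalence_property(self, durations):
        kept, n_excl = exclude_outliers(durations)
        exp_kept, exp_excl = oracle_exclude(durations)
        assert n_excl == exp_excl
        assert kept == pytest.approx(exp_kept)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=1, max_size=60)
    )
    def test_idempotent_under_original_threshold(self, durations):
        """Re-applying the rule with the original mean/SD removes nothing."""
        mu = statistics.fmean(durations)
        sigma = statistics.stdev(durations) if len(durations) > 1 else 0.0
        kept, _ = exclude_outliers(durations)
        assert all(v <= mu + 3 * sigma for v in kept)


class TestSummarizeEncounters:
    def test_single_category_mean_and_pct(self, taxonomy):
        df = pd.DataFrame(
            {
                "worker_id": ["w1", "w1"],
                "setting": ["rural", "rural"],
                "date": ["2014-04-14"] * 2,
                "activity_label": ["Provide TB related services"] * 2,
                "duration_min": [10.0, 20.0],
            }
        )
        stats = {s.category.id: s for s in h.summarize_encounters(df, "rural")}
        tb = stats["tb_services"]
        assert tb.mean_min == pytest.approx(15.0)
        assert tb.sd_min == pytest.approx(statistics.stdev([10.0, 20.0]))
        assert tb.pct_of_encounters == pytest.approx(100.0)

    def test_percent_breakdown_from_counts(self, taxonomy):
        rows = [("Provide TB related services", 5.0)] * 3 + [("First aid", 7.0)]
        df = pd.DataFrame(
            {
                "worker_id": "w1",
                "setting": "rural",
                "date": "2014-04-14",
                "activity_label": [r[0] for r in rows],
                "duration_min": [r[1] for r in rows],
            }
        )
        stats = {s.category.id: s for s in h.summarize_encounters(df, "rural")}
        assert stats["tb_services"].pct_of_encounters == pytest.approx(75.0)
        assert stats["first_aid"].pct_of_encounters == pytest.approx(25.0)

    def test_zero_encounter_categories_reported_not_dropped(self, small_log):
        stats = h.summarize_encounters(small_log, "rural")
        assert len(stats) == 14
        by_id = {s.category.id: s for s in stats}
        assert by_id["group_training"].n_encounters == 0
        assert not by_id["group_training"].mean_defined
        assert np.isnan(by_id["group_training"].mean_min)

    def test_out_of_scope_category_not_billable(self, small_log):
        """Urban TB encounters fall out of the urban billable summary."""
        stats = {s.category.id for s in h.summarize_encounters(small_log, "urban")}
        assert "tb_services" not in stats

    def test_counts_conserved_and_pct_sums_to_100(self, small_log):
        stats = h.summarize_encounters(small_log, "rural")
        assert sum(s.n_encounters for s in stats) == 4  # kept billable rural rows
        assert sum(s.pct_of_encounters for s in stats) == pytest.approx(100.0, abs=0.2)

    def test_agrees_with_brute_force_on_random_log(self, taxonomy):
        """Full per-category recomputation with stdlib tools on <=100 records."""
        rng = np.random.default_rng(42)
        cats = taxonomy.billable("rural")
        labels = rng.choice([c.display_name for c in cats], size=100)
        durs = np.round(rng.gamma(2.0, 8.0, size=100), 1)
        df = pd.DataFrame(
            {
                "worker_id": "w1",
                "setting": "rural",
                "date": "2014-04-14",
                "activity_label": labels,
                "duration_min": durs,
            }
        )
        stats = {s.category.id: s for s in h.summarize_encounters(df, "rural")}
        # brute force: group durations by classified category, apply oracle
        groups = {}
        for lbl, d in zip(labels, durs):
            groups.setdefault(taxonomy.classify(lbl).id, []).append(float(d))
        kept_all = {cid: oracle_exclude(v)[0] for cid, v in groups.items()}
        total = sum(len(v) for v in kept_all.values())
        for cid, kept in kept_all.items():
            s = stats[cid]
            assert s.n_encounters == len(kept)
            assert s.mean_min == pytest.approx(statistics.fmean(kept))
            assert s.pct_of_encounters == pytest.approx(100 * len(kept) / total)

    def test_no_billable_encounters_is_error(self, taxonomy):
        df = pd.DataFrame(
            {
                "worker_id": ["w1"],
                "setting": ["rural"],
                "date": ["2014-04-14"],
                "activity_label": ["travel"],
                "duration_min": [30.0],
            }
        )
        with pytest.raises(ValueError, match="no billable"):
            h.summarize_encounters(df, "rural")


class TestBillableMinutes:
    def _log(self, minutes_rows, setting="rural"):
        return pd.DataFrame(
            {
                "worker_id": [r[0] for r in minutes_rows],
                "setting": setting,
                "date": [r[1] for r in minutes_rows],
                "activity_label": "Provide TB related services",
                "duration_min": [r[2] for r in minutes_rows],
            }
        )

    def test_scales_observation_window_to_30_day_month(self):
        # 1120 billable minutes over 21 days -> 1600 per month
        df = self._log([("w1", "2014-04-14", 1120.0)])
        out = h.billable_minutes_per_month(df, "rural", days_observed=21)
        assert out.billable_min_per_month == pytest.approx(1600.0)

    def test_identity_window(self):
        df = self._log([("w1", "2014-04-14", 900.0)])
        out = h.billable_minutes_per_month(df, "rural", days_observed=30)
        assert out.billable_min_per_month == pytest.approx(900.0)

    def test_average_over_workers(self):
        df = self._log([("w1", "2014-04-14", 100.0), ("w2", "2014-04-14", 200.0)])
        out = h.billable_minutes_per_month(df, "rural", days_observed=30)
        assert out.billable_min_per_month == pytest.approx(150.0)
        assert out.n_workers == 2

    def test_zero_days_rejected(self):
        df = self._log([("w1", "2014-04-14", 10.0)])
        with pytest.raises(ValueError):
            h.billable_minutes_per_month(df, "rural", days_observed=0)


class TestLogReader:
    def test_round_trip(self, tmp_path, small_log):
        p = tmp_path / "log.csv"
        small_log.to_csv(p, index=False)
        df = read_observation_log(p)
        assert len(df) == len(small_log)
        assert list(df.columns) == list(small_log.columns)

    def test_negative_duration_reported_with_line(self, tmp_path, small_log):
        bad = small_log.copy()
        bad.loc[2, "duration_min"] = -5
        p = tmp_path / "log.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(h.ObservationLogError, match="line 4"):
            read_observation_log(p)

    def test_unknown_setting_rejected(self, tmp_path, small_log):
        bad = small_log.copy()
        bad.loc[0, "setting"] = "periurban"
        p = tmp_path / "log.csv"
        bad.to_csv(p, index=False)
        with pytest.raises(h.ObservationLogError, match="periurban"):
            read_observation_log(p)

    def test_missing_column_rejected(self, tmp_path, small_log):
        p = tmp_path / "log.csv"
        small_log.drop(columns=["duration_min"]).to_csv(p, index=False)
        with pytest.raises(h.ObservationLogError, match="duration_min"):
            read_observation_log(p)
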