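"""Long-format analysis tables: row expansion, z-scoring, windows."""
import numpy as np
import pandas as pd
import pytest

import coalrank as cr
from coalrank.coalition import CoalitionEvent
from coalrank.datasets import add_autocorrelation_term

from conftest import manual_trajectories, presence_frame

START = pd.Timestamp("2020-01-01")


def flat_updates(ratings, days=400):
    """Constant-but-distinct daily ratings so standardization is defined."""
    return {
        m: [(START + pd.Timedelta(days=i), r) for i in range(days)]
        for m, r in ratings.items()
    }


def toy_world(males_ratings, events):
    pres = presence_frame(list(males_ratings), entry="2020-01-01",
                          exit="2021-12-31")
    traj = manual_trajectories(pres, flat_updates(males_ratings, days=500))
    metrics = cr.event_metrics(events, traj, pres)
    return pres, traj, metrics


class TestBuildRankDataset:
    def test_one_event_three_males_gives_36_rows(self):
        """Each of the 3 involved males is represented 12 times."""
        ratings = {"A": 1200.0, "B": 1100.0, "C": 900.0, "D": 800.0}
        ev = CoalitionEvent("E1", "2020-03-01", "G1", ("A", "B"), ("C",))
        pres, traj, metrics = toy_world(ratings, [ev])
        rank = cr.build_rank_dataset([ev], metrics, traj, pres)
        assert len(rank) == 36
        assert set(rank["days_since"]) == set(range(10, 121, 10))
        assert rank.groupby("male").size().to_dict() == {
            "A": 12, "B": 12, "C": 12}

    def test_two_events_expand_to_84_rows(self):
        ratings = {"A": 1200.0, "B": 1100.0, "C": 1000.0, "D": 900.0,
                   "E": 800.0}
        ev1 = CoalitionEvent("E1", "2020-03-01", "G1", ("A", "B"), ("C",))
        ev2 = CoalitionEvent("E2", "2020-04-01", "G1", ("A", "B", "C"), ("D",))
        pres, traj, metrics = toy_world(ratings, [ev1, ev2])
        rank = cr.build_rank_dataset([ev1, ev2], metrics, traj, pres)
        assert len(rank) == (3 + 4) * 12

    def test_empty_event_list_gives_empty_table_with_schema(self):
        ratings = {"A": 1200.0, "B": 800.0}
        pres, traj, metrics = toy_world(ratings, [])
        rank = cr.build_rank_dataset([], metrics, traj, pres)
        assert rank.empty
        for col in ("event_id", "male", "role", "configuration", "feasibility",
                    "days_since", "future_rating", "day0_rating", "autocorr"):
            assert col in rank.columns

    def test_emigrated_offsets_dropped_not_imputed(self):
        ratings = {"A": 1200.0, "B": 1100.0, "C": 900.0}
        ev = CoalitionEvent("E1", "2020-03-01", "G1", ("A", "B"), ("C",))
        pres = presence_frame([("A", "2020-01-01", "2020-04-15"), "B", "C"])
        traj = manual_trajectories(pres, {
            "A": flat_updates({"A": 1200.0}, days=106)["A"],
            **flat_updates({"B": 1100.0, "C": 900.0}, days=500),
        })
        metrics = cr.event_metrics([ev], traj, pres)
        rank = cr.build_rank_dataset([ev], metrics, traj, pres)
        # A present through offset 40 only (leaves 45 days after the event)
        assert rank.loc[rank["male"] == "A", "days_since"].max() == 40
        assert len(rank) == 4 + 12 + 12

    def test_standardized_response_variant(self):
        ratings = {"A": 1200.0, "B": 1100.0, "C": 900.0, "D": 800.0}
        ev = CoalitionEvent("E1", "2020-03-01", "G1", ("A", "B"), ("C",))
        pres, traj, metrics = toy_world(ratings, [ev])
        rank = cr.build_rank_dataset([ev], metrics, traj, pres,
                                     standardize_response=True)
        # constant distinct ratings: standardized values are fixed
        assert set(rank["future_rating"].round(6)) == {1.0, 0.75, 0.25}

    def test_row_count_matches_brute_force_recount(self, small_world):
        rank = small_world["rank"]
        traj = small_world["trajectories"]
        expected = 0
        for ev in small_world["events"]:
            if ev.event_id not in set(rank["event_id"]):
                continue
            for male in ev.males:
                fut = traj.future_ratings(male, ev.date)
                expected += int(fut.loc[fut["offset"] > 0, "present"].sum())
        assert len(rank) == expected

    def test_zscored_columns_standardized(self, small_world):
        rank = small_world["rank"]
        for col in ("feas_z", "days_z", "day0_z", "age_z", "stab_z"):
            vals = rank[col].dropna()
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std(ddof=0) - 1.0) < 1e-10

    def test_day0_rating_is_control_not_response(self, small_world):
        rank = small_world["rank"]
        day0 = rank.groupby(["event_id", "male"])["day0_rating"].nunique()
        assert (day0 == 1).all()  # constant within a series
        # and the response varies with the offset in general
        assert (rank.groupby(["event_id", "male"])["future_rating"]
                .nunique() > 1).any()


class TestBuildPaternityDataset:
    def _setup(self):
        ratings = {"A": 1200.0, "B": 1000.0, "C": 800.0}
        pres = presence_frame(list(ratings))
        traj = manual_trajectories(pres, flat_updates(ratings, days=500))
        conceptions = pd.DataFrame({
            "infant": ["I1"], "group": ["G1"],
            "conception_date": [pd.Timestamp("2020-06-01")],
            "sire": ["A"],
        })
        return pres, traj, conceptions

    def test_window_spans_11_calendar_days(self):
        pres, traj, conc = self._setup()
        pat = cr.build_paternity_dataset(conc, traj, pres, window=11)
        assert len(pat) == 3
        assert pat.loc[pat["male"] == "A", "sired"].iloc[0] == 1
        assert pat.loc[pat["male"] != "A", "sired"].eq(0).all()
        # constant trajectory across the window -> mean equals the constant
        assert pat.set_index("male")["rating"].to_dict() == pytest.approx(
            {"A": 1.0, "B": 0.5, "C": 0.0})

    def test_even_window_rejected(self):
        pres, traj, conc = self._setup()
        with pytest.raises(cr.ConfigError, match="odd"):
            cr.build_paternity_dataset(conc, traj, pres, window=10)

    def test_candidate_present_one_day_uses_that_day(self):
        ratings = {"A": 1200.0, "B": 1000.0, "C": 800.0}
        pres = presence_frame([("A", "2020-01-01", "2020-05-27"), "B", "C"])
        traj = manual_trajectories(pres, {
            "A": flat_updates({"A": 1200.0}, days=148)["A"],
            **flat_updates({"B": 1000.0, "C": 800.0}, days=500),
        })
        conc = pd.DataFrame({
            "infant": ["I1"], "group": ["G1"],
            "conception_date": [pd.Timestamp("2020-06-01")], "sire": [""],
        })
        pat = cr.build_paternity_dataset(conc, traj, pres, window=11)
        # A present only on 2020-05-27, the first window day
        row = pat.loc[pat["male"] == "A"].iloc[0]
        assert row["rating"] == pytest.approx(1.0)
        assert pat["sired"].eq(0).all()

    def test_generator_long_form_accepted(self, small_world):
        pop = small_world["population"]
        traj = small_world["trajectories"]
        conc = cr.simulate_conceptions(pop, traj,
                                       cr.PaternitySimConfig(n_conceptions=4),
                                       seed=77)
        pat = cr.build_paternity_dataset(conc, traj, pop.presence)
        assert pat["infant"].nunique() == 4
        per_infant = pat.groupby("infant").size()
        assert (per_infant >= 2).all()


class TestAutocorrelationTerm:
    def test_single_row_series_gets_zero(self):
        df = pd.DataFrame({"event_id": ["E1"], "male": ["A"],
                           "days_since": [10]})
        out = add_autocorrelation_term(df, np.array([3.0]))
        assert out["autocorr"].iloc[0] == 0.0

    def test_zero_residuals_give_zero_terms(self):
        df = pd.DataFrame({"event_id": "E1", "male": "A",
                           "days_since": [10, 20, 30]})
        out = add_autocorrelation_term(df, np.zeros(3))
        assert (out["autocorr"] == 0.0).all()

    def test_three_row_hand_computed_weights(self):
        df = pd.DataFrame({"event_id": "E1", "male": "A",
                           "days_since": [10, 20, 40]})
        r = np.array([1.0, 2.0, 4.0])
        out = add_autocorrelation_term(df, r)
        w12, w13, w23 = 1 / 2, 1 / 4, 1 / 3  # 1/(1+|dt|/10)
        expected = [
            (w12 * 2.0 + w13 * 4.0) / (w12 + w13),
            (w12 * 1.0 + w23 * 4.0) / (w12 + w23),
            (w13 * 1.0 + w23 * 2.0) / (w13 + w23),
        ]
        np.testing.assert_allclose(out["autocorr"], expected)

    def test_length_mismatch_rejected(self):
        df = pd.DataFrame({"event_id": ["E1"], "male": ["A"],
                           "days_since": [10]})
        with pytest.raises(cr.DataError):
            add_autocorrelation_term(df, np.zeros(3))
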