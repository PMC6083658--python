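import numpy as np
import pandas as pd
import pytest

import groomchoice as gc
from groomchoice.choices import (GroomingInitiation, StandardizationError,
                                 Session, build_choice_rows, finalize_table,
                                 group_sessions)


def _init(minute, focal="F", target="A", present=("F", "A", "B"),
          day="2024-03-02"):
    return GroomingInitiation(
        pd.Timestamp(f"{day}T10:00:00") + pd.Timedelta(minutes=minute),
        focal, target, frozenset(present))


class TestSessions:
    def test_close_initiations_share_a_session(self):
        sessions = group_sessions([_init(0), _init(3), _init(10)])
        assert [len(s.initiations) for s in sessions] == [2, 1]
        assert sessions[0].first.timestamp.minute == 0

    def test_gap_of_exactly_five_minutes_splits(self):
        sessions = group_sessions([_init(0), _init(5)])
        assert len(sessions) == 2

    def test_focal_change_splits(self):
        sessions = group_sessions([_init(0, focal="F"),
                                   _init(1, focal="G", target="A",
                                         present=("G", "A"))])
        assert len(sessions) == 2

    def test_single_initiation_is_its_own_first_choice(self):
        sessions = group_sessions([_init(0)])
        assert len(sessions) == 1
        assert sessions[0].first is sessions[0].initiations[0]


class TestBuildRows:
    @pytest.fixture()
    def components(self, toy_log, toy_roster):
        ratings = gc.EloRatings.from_events(toy_log, roster=toy_roster)
        dyads = gc.DyadIndex.from_events(toy_log)
        return ratings, dyads

    def test_manual_enumeration(self, components, toy_roster):
        ratings, dyads = components
        session = Session("sX", "A", [_init(0, focal="A", target="B",
                                            present=("A", "B", "C", "D"))])
        rows = build_choice_rows(session, ratings, dyads, toy_roster)
        assert list(rows["candidate"]) == ["B", "C", "D"]
        assert list(rows["chosen"]) == [1, 0, 0]
        # bystanders of A's candidate B are {C, D}; of C are {B, D}
        assert rows.loc[rows.candidate == "B",
                        "max_bystander_ddsi"].iloc[0] == pytest.approx(
            max(dyads.value("B", "C", "2024-03-02"),
                dyads.value("B", "D", "2024-03-02")))

    def test_single_candidate_session_is_degenerate(self, components,
                                                    toy_roster):
        ratings, dyads = components
        session = Session("sX", "A", [_init(0, focal="A", target="B",
                                            present=("A", "B"))])
        rows = build_choice_rows(session, ratings, dyads, toy_roster)
        assert len(rows) == 1
        assert rows["chosen"].iloc[0] == 1
        assert bool(rows["bystander_degenerate"].iloc[0])

    def test_excluded_target_drops_session(self, components, toy_roster):
        ratings, dyads = components
        session = Session("sX", "A", [_init(0, focal="A", target="S",
                                            present=("A", "B", "S"))])
        # S is subadult: the extractor strips it from the present set, so
        # the target is missing and the whole session is dropped
        rows = build_choice_rows(
            Session("sX", "A", [GroomingInitiation(
                session.first.timestamp, "A", "S", frozenset({"A", "B"}))]),
            ratings, dyads, toy_roster)
        assert rows is None

    def test_aggression_window_is_half_open_thirty_minutes(self, components,
                                                           toy_roster):
        ratings, dyads = components
        t = pd.Timestamp("2024-03-02T12:00:00")
        session = Session("sX", "A", [GroomingInitiation(
            t, "A", "B", frozenset({"A", "B", "C"}))])

        def rows_with_aggression_at(minutes_before):
            agg = pd.DataFrame({
                "timestamp": [t - pd.Timedelta(minutes=minutes_before)],
                "actor": ["A"], "receiver": ["C"],
            })
            return build_choice_rows(session, ratings, dyads, toy_roster,
                                     aggression=agg)

        def flag(rows, cand):
            return rows.loc[rows.candidate == cand,
                            "prior_aggression"].iloc[0]

        assert flag(rows_with_aggression_at(10), "C") == 1
        assert flag(rows_with_aggression_at(30), "C") == 1  # boundary inside
        assert flag(rows_with_aggression_at(31), "C") == 0
        assert flag(rows_with_aggression_at(10), "B") == 0  # other dyad


class TestFinalize:
    def test_zscore_of_arithmetic_sequence(self, toy_table):
        frame = pd.DataFrame({
            "session": ["s1"] * 3, "group": ["g"] * 3,
            "focal": ["F"] * 3, "candidate": list("ABC"),
            "chosen": [1, 0, 0], "n_candidates": [3] * 3,
            "ddsi": [1.0, 2.0, 3.0], "repro_state": ["other"] * 3,
        })
        table = finalize_table(frame)
        assert np.allclose(table.frame["z_ddsi"], [-1.0, 0.0, 1.0])

    def test_offset_is_log_inverse_candidate_count(self):
        frame = pd.DataFrame({
            "session": ["s1"] * 5, "group": ["g"] * 5, "focal": ["F"] * 5,
            "candidate": list("ABCDE"), "chosen": [0, 0, 1, 0, 0],
            "n_candidates": [5] * 5, "ddsi": [0.1, 0.2, 0.3, 0.4, 0.5],
            "repro_state": ["other"] * 5,
        })
        table = finalize_table(frame)
        assert np.allclose(table.frame["offset"], np.log(0.2))

    def test_zero_variance_column_is_named_in_error(self):
        frame = pd.DataFrame({
            "session": ["s1"] * 3, "group": ["g"] * 3, "focal": ["F"] * 3,
            "candidate": list("ABC"), "chosen": [1, 0, 0],
            "n_candidates": [3] * 3, "ddsi": [0.5, 0.5, 0.5],
            "repro_state": ["other"] * 3,
        })
        with pytest.raises(StandardizationError, match="ddsi"):
            finalize_table(frame)

    def test_square_then_standardize_switch(self, sim_products):
        raw = sim_products["table"].frame[[
            "session", "group", "focal", "candidate", "chosen",
            "n_candidates", "cand_rank_global", "repro_state"]].copy()
        alt = finalize_table(raw, square_mode="square_then_standardize")
        sq = alt.frame["z_cand_rank_global_sq"]
        assert abs(sq.mean()) < 1e-12 and sq.std(ddof=1) == pytest.approx(1.0)

    def test_standardized_columns_have_unit_moments(self, sim_products):
        table = sim_products["table"]
        for col, (mean, sd) in table.standardization.items():
            z = table.frame["z_" + col] if "z_" + col in table.frame else None
            if z is None:
                continue
            assert abs(z.mean()) < 1e-12
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestRoundTripWithSimulator:
    def test_session_count_matches_emitted_decisions(self, sim_products):
        table = sim_products["table"]
        truth = sim_products["truth"]
        assert table.counts["n_sessions"] == len(truth.decisions)
        assert table.counts["n_chosen"] == len(truth.decisions)

    def test_exactly_one_chosen_row_per_session(self, sim_products):
        per_session = sim_products["table"].frame.groupby("session")[
            "chosen"].sum()
        assert (per_session == 1).all()

    def test_recovered_parties_match_ground_truth(self, sim_products):
        frame = sim_products["table"].frame
        truth = sim_products["truth"]
        sizes = frame.groupby("session")["candidate"].count() + 1
        true_sizes = truth.decisions["present_ids"].str.split(";").apply(len)
        assert sorted(sizes) == sorted(true_sizes)

    def test_choice_table_tsv_round_trip(self, sim_products, tmp_path):
        table = sim_products["table"]
        path = tmp_path / "choices.tsv"
        table.to_tsv(path)
        back = gc.ChoiceTable.from_tsv(path)
        assert back.counts == table.counts
        assert len(back.frame) == len(table.frame)
        assert np.allclose(back.frame["z_ddsi"], table.frame["z_ddsi"])
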