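"""Window classification, pattern tabulation and the robustness subsets."""

import datetime as dt

import pytest
from hypothesis import given, strategies as st

from triscreen.records import (
    EventType,
    MAIN_WINDOWS,
    MalformedRowError,
    ParticipationPattern,
    Programme,
    ScreeningEvent,
    WindowSpec,
    WomanRecord,
    classify_last_round,
    ever_participant_flags,
    load_cohort,
    pre_age54_patterns,
    read_events,
    read_patterns,
    restrict_to_invited,
    round_half_up,
    tabulate_patterns,
    tabulate_two_programme,
    write_cohort,
    write_patterns,
    years_before,
    add_years,
)

from conftest import REF, make_woman


class TestClassifyLastRound:
    def test_single_breast_screen_inside_window(self):
        w = make_woman([("breast", "screen", int(3.5 * 365))])
        p = classify_last_round(w)
        assert p.flags == (True, False, False)

    def test_boundary_day_excluded_at_far_end(self):
        # cervical screen exactly 6 years + 1 day before reference: outside
        day_past = (REF - years_before(REF, 6)).days + 1
        w = make_woman([("cervical", "screen", day_past)])
        assert classify_last_round(w).cervical is False

    def test_boundary_day_included_at_near_end_of_lookback(self):
        # exactly 6 years before reference: the window is closed there
        on_boundary = (REF - years_before(REF, 6)).days
        w = make_woman([("cervical", "screen", on_boundary)])
        assert classify_last_round(w).cervical is True

    def test_invitations_never_count_as_participation(self):
        w = make_woman([("bowel", "invitation", 100)])
        assert classify_last_round(w).bowel is False

    def test_programmes_without_window_are_false(self):
        w = make_woman([("bowel", "screen", 100)])
        p = classify_last_round(w, windows=[WindowSpec(Programme.BREAST, 4)])
        assert p.flags == (False, False, False)

    def test_anchor_before_birth_raises(self):
        w = make_woman([])
        with pytest.raises(ValueError, match="anchor"):
            classify_last_round(w, anchor=w.birth_date - dt.timedelta(days=1))

    def test_duplicate_programme_windows_raise(self):
        w = make_woman([])
        dup = [WindowSpec(Programme.BREAST, 4), WindowSpec(Programme.BREAST, 2)]
        with pytest.raises(ValueError, match="at most once"):
            classify_last_round(w, windows=dup)

    def test_leap_day_anchor_maps_to_feb28(self):
        assert years_before(dt.date(2012, 2, 29), 3) == dt.date(2009, 2, 28)
        assert add_years(dt.date(1948, 2, 29), 54) == dt.date(2002, 2, 28)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([p.value for p in Programme]),
                st.sampled_from(["screen", "invitation"]),
                st.integers(min_value=0, max_value=5000),
            ),
            max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_invariant_to_event_order(self, spec, rnd):
        w1 = make_woman(spec)
        shuffled = list(w1.events)
        rnd.shuffle(shuffled)
        w2 = WomanRecord(w1.woman_id, w1.birth_date, w1.reference_date, events=shuffled)
        assert classify_last_round(w1) == classify_last_round(w2)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([p.value for p in Programme]),
                st.just("screen"),
                st.integers(min_value=0, max_value=5000),
            ),
            max_size=8,
        ),
        st.sampled_from([p.value for p in Programme]),
    )
    def test_event_outside_all_windows_never_changes_pattern(self, spec, prog):
        w1 = make_woman(spec)
        base = classify_last_round(w1)
        far = ScreeningEvent(
            w1.woman_id, Programme(prog), EventType.SCREEN,
            years_before(REF, 7),  # beyond the longest (6-year) window
        )
        w2 = WomanRecord(w1.woman_id, w1.birth_date, w1.reference_date,
                         events=[*w1.events, far])
        assert classify_last_round(w2) == base


class TestTabulatePatterns:
    def test_single_woman_single_row(self):
        t = tabulate_patterns([ParticipationPattern("a", True, False, False)])
        row = t[(t.breast) & (~t.cervical) & (~t.bowel)].iloc[0]
        assert row["count"] == 1 and row["percent"] == 100
        assert t["count"].sum() == 1

    def test_empty_input_gives_zero_table(self):
        t = tabulate_patterns([])
        assert len(t) == 8
        assert t["count"].sum() == 0 and t["percent"].sum() == 0

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()), max_size=200
        )
    )
    def test_count_conservation_and_percent_sum(self, triples):
        pats = [ParticipationPattern(str(i), *t) for i, t in enumerate(triples)]
        t = tabulate_patterns(pats)
        assert t["count"].sum() == len(pats)
        if pats:
            assert abs(t["percent"].sum() - 100) <= 4  # 8 cells x 0.5 rounding

    def test_percent_rounds_half_away_from_zero(self):
        assert round_half_up(2.5) == 3.0
        assert round_half_up(0.125, 2) == 0.13


class TestPreAge54:
    def test_screens_before_age54_count(self):
        birth = dt.date(1948, 3, 1)
        ref = dt.date(2010, 6, 1)
        a49 = add_years(birth, 49) - birth
        a51 = add_years(birth, 51) - birth
        w = make_woman(
            [("cervical", "screen", (ref - birth - a49).days),
             ("breast", "screen", (ref - birth - a51).days)],
            birth=birth, ref=ref,
        )
        (p,) = pre_age54_patterns([w])
        assert (p.breast, p.cervical) == (True, True)
        assert p.bowel is False

    def test_breast_screen_older_than_four_years_excluded(self):
        birth = dt.date(1948, 3, 1)
        ref = dt.date(2010, 6, 1)
        a49 = add_years(birth, 49) - birth
        w = make_woman([("breast", "screen", (ref - birth - a49).days)],
                       birth=birth, ref=ref)
        (p,) = pre_age54_patterns([w])
        assert p.breast is False

    def test_two_programme_tabulation(self):
        pats = [
            ParticipationPattern("a", True, True, False),
            ParticipationPattern("b", True, False, False),
            ParticipationPattern("c", False, False, False),
        ]
        assert tabulate_two_programme(pats) == {"both": 1, "one": 1, "neither": 1}


class TestRestrictToInvited:
    def test_invitation_18_months_before_reference_retained(self):
        w = make_woman([("bowel", "invitation", 548)])
        assert restrict_to_invited([w], 1.0) == [w]

    def test_recent_invitation_excluded(self):
        w = make_woman([("bowel", "invitation", 90)])
        assert restrict_to_invited([w], 1.0) == []

    def test_bowel_screen_is_not_an_invitation(self):
        w = make_woman([("bowel", "screen", 548)])
        assert restrict_to_invited([w], 1.0) == []

    @given(st.lists(st.integers(min_value=0, max_value=2000), max_size=6),
           st.integers(min_value=0, max_value=3),
           st.integers(min_value=0, max_value=3))
    def test_monotone_in_lag_and_idempotent(self, days, lag_a, lag_b):
        w = make_woman([("bowel", "invitation", d) for d in days])
        lo, hi = sorted((lag_a, lag_b))
        kept_hi = restrict_to_invited([w], hi)
        assert set(x.woman_id for x in kept_hi) <= set(
            x.woman_id for x in restrict_to_invited([w], lo)
        )
        assert restrict_to_invited(kept_hi, hi) == kept_hi


class TestIO:
    def test_cohort_round_trip(self, tmp_path):
        w1 = make_woman([("breast", "screen", 100), ("bowel", "invitation", 500)], woman_id="A")
        w2 = make_woman([("cervical", "screen", 900)], woman_id="B")
        write_cohort([w1, w2], tmp_path / "events.csv", tmp_path / "roster.csv")
        back = load_cohort(tmp_path / "events.csv", tmp_path / "roster.csv")
        assert len(back) == 2
        assert [w.woman_id for w in back] == ["A", "B"]
        assert back[0].events == w1.events
        assert ever_participant_flags(back) == {"A": True, "B": True}

    def test_pattern_table_round_trip(self, tmp_path, published_patterns):
        pats, _ = published_patterns
        t = tabulate_patterns(pats)
        write_patterns(tmp_path / "t.csv", t)
        back = read_patterns(tmp_path / "t.csv")
        assert (back["count"] == t["count"]).all()

    def test_malformed_date_rejected_with_line_number(self, tmp_path):
        f = tmp_path / "events.csv"
        f.write_text(
            "woman_id,programme,event_type,event_date\n"
            "A,breast,screen,2009-05-01\n"
            "B,breast,screen,2010-13-40\n"
        )
        with pytest.raises(MalformedRowError, match="line 3"):
            read_events(f)

    def test_missing_column_named_in_error(self, tmp_path):
        f = tmp_path / "events.csv"
        f.write_text("woman_id,programme,event_date\nA,breast,2009-05-01\n")
        with pytest.raises(ValueError, match="event_type"):
            read_events(f)

    def test_unknown_programme_skipped_with_warning(self, tmp_path):
        f = tmp_path / "events.csv"
        f.write_text(
            "woman_id,programme,event_type,event_date\n"
            "A,prostate,screen,2009-05-01\n"
            "A,breast,screen,2009-05-01\n"
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            events = read_events(f)
        assert len(events) == 1
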