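"""Design generators: printed constants, timing constraints, counterbalancing."""

import numpy as np
import pytest

from tagattn import design
from tagattn.design import (
    EXP1_LAYOUT,
    EXP2_FREQS,
    EXP3_FREQS,
    LOCATIONS,
    RSVP_ALPHABET,
    DimmingProfile,
    EventSchedule,
    adjust_switch_rate,
    assign_event_kinds,
    build_session,
    frame_locked_frequency,
    make_probability_table,
    make_rsvp_stream,
    merged_region_span,
    schedule_dimming_events,
)


class TestProbabilityTable:
    def test_narrow_printed_values(self):
        t = make_probability_table("narrow")
        assert t.probs["cued"] == 0.75
        assert t.probs["neighbor_1"] == t.probs["neighbor_2"] == 0.125

    def test_split_printed_values(self):
        t = make_probability_table("split")
        assert t.probs["cued_1"] == t.probs["cued_2"] == 0.375
        assert t.probs["intermediate"] == pytest.approx(0.0833, abs=5e-5)

    def test_broad_printed_values(self):
        t = make_probability_table("broad")
        assert all(t.probs[f"cued_{i}"] == 0.15 for i in range(1, 6))
        assert t.probs["neighbor_1"] == 0.125

    @pytest.mark.parametrize("focus", ["narrow", "split", "broad"])
    def test_normalization_and_cued_mass(self, focus):
        t = make_probability_table(focus)
        assert sum(t.probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(t.probs[c] for c in t.cued) == pytest.approx(0.75, abs=1e-9)

    def test_unknown_focus_rejected(self):
        with pytest.raises(ValueError, match="unknown focus"):
            make_probability_table("diffuse")

    @pytest.mark.parametrize("focus", ["narrow", "split", "broad"])
    def test_empirical_frequencies_match(self, focus, rng):
        """Sampled probe locations match the table within 3 binomial SDs."""
        t = make_probability_table(focus)
        n = 100_000
        draws = t.sample(rng, size=n)
        for loc, p in t.probs.items():
            k = int((draws == loc).sum())
            sd = np.sqrt(n * p * (1 - p))
            assert abs(k - n * p) < 3 * sd, (loc, k / n, p)


class TestGeometry:
    def test_three_segment_merge(self):
        assert merged_region_span(EXP1_LAYOUT, 3) == pytest.approx(50.1)

    def test_single_segment(self):
        assert merged_region_span(EXP1_LAYOUT, 1) == pytest.approx(14.7)

    def test_single_segment_ignores_gap(self):
        from dataclasses import replace

        assert merged_region_span(replace(EXP1_LAYOUT, gap=7.7), 1) == pytest.approx(14.7)

    def test_too_many_segments_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            merged_region_span(EXP1_LAYOUT, 6)


class TestFrequencies:
    @pytest.mark.parametrize("frames,expected", [(11, 10.91), (13, 9.23), (10, 12.0),
                                                 (9, 13.33), (15, 8.0), (17, 7.06), (1, 120.0)])
    def test_frame_locked_display_values(self, frames, expected):
        assert frame_locked_frequency(120, frames).freq_display == expected

    def test_full_precision_exposed(self):
        f = frame_locked_frequency(120, 17)
        assert f.freq == pytest.approx(120 / 17)

    def test_non_integer_frames_rejected(self):
        with pytest.raises(ValueError):
            frame_locked_frequency(120, 10.5)

    def test_exp_frequency_sets(self):
        assert [EXP2_FREQS[l].freq_display for l in LOCATIONS] == [10.91, 12.0, 13.33]
        assert [f.freq_display for f in EXP3_FREQS] == [7.06, 8.0, 9.23, 10.91, 12.0, 13.33]


class TestSwitchRate:
    def test_no_collision_unchanged(self):
        tags = [7.06, 8, 9.23, 10.91, 12, 13.33]
        assert adjust_switch_rate(2.5, tags) == pytest.approx(2.5)

    def test_subharmonic_not_a_collision(self):
        assert adjust_switch_rate(4.0, [12.0]) == pytest.approx(4.0)

    def test_tag_coincidence_shifted_one_frame(self):
        out = adjust_switch_rate(8.0, [8.0])
        assert out == pytest.approx(120 / 16)

    @pytest.mark.parametrize("rate", np.linspace(1.5, 6.5, 40))
    def test_output_collision_free_and_frame_realizable(self, rate):
        """Brute-force recheck: output hits no tag harmonic below 70 Hz and
        sits on the 120 Hz frame grid."""
        tags = [120 / n for n in (17, 15, 13, 11, 10, 9)]
        out = adjust_switch_rate(rate, tags)
        assert 120 / round(120 / out) == pytest.approx(out)
        harmonics = [k * f for f in tags for k in range(1, 11) if k * f <= 70]
        assert all(abs(out - h) > 1e-6 for h in harmonics)


def _check_schedule(sched: EventSchedule):
    """Independent brute-force constraint checker."""
    on = sched.onsets
    for i in range(len(on)):
        assert on[i] >= 0.5 - 1e-12
        assert on[i] <= sched.trial_duration - 0.7 + 1e-12
        for j in range(i + 1, len(on)):
            assert abs(on[j] - on[i]) >= 1.1 - 1e-12


class TestDimmingSchedule:
    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("n_events", [1, 2, 3])
    def test_constraints_hold(self, seed, n_events):
        sched = schedule_dimming_events(4.5, n_events, seed)
        assert len(sched.events) == n_events
        _check_schedule(sched)

    def test_zero_events_empty(self):
        assert schedule_dimming_events(4.5, 0, 0).events == ()

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            schedule_dimming_events(1.0, 3, 0)

    def test_deterministic(self):
        a = schedule_dimming_events(4.8, 3, 42)
        b = schedule_dimming_events(4.8, 3, 42)
        assert a.onsets == b.onsets


class TestEventKinds:
    def test_split_target_is_both_cued(self):
        sched = schedule_dimming_events(4.9, 3, 1)
        for seed in range(30):
            out = assign_event_kinds("split", sched, seed)
            for ev in out.events:
                if ev.kind == "target":
                    assert ev.locations == frozenset({"innermost", "outermost"})
                    assert ev.configuration == "disjoint"

    def test_broad_target_two_of_three(self):
        sched = schedule_dimming_events(4.9, 3, 2)
        for seed in range(30):
            out = assign_event_kinds("broad", sched, seed)
            for ev in out.events:
                if ev.kind == "target":
                    assert len(ev.locations) == 2
                else:
                    assert len(ev.locations) == 1

    def test_narrow_needs_cued_location(self):
        sched = schedule_dimming_events(4.9, 1, 3)
        with pytest.raises(ValueError, match="narrow"):
            assign_event_kinds("narrow", sched, 0)
        out = assign_event_kinds("narrow_innermost", sched, 0)
        for ev in out.events:
            if ev.kind == "target":
                assert ev.locations == frozenset({"innermost"})
            else:
                assert ev.locations < {"intermediate", "outermost"}

    def test_split_nontarget_configuration_frequencies(self):
        """singular vs adjacent nontargets each ~50% over many draws."""
        rng = np.random.default_rng(99)
        sched = schedule_dimming_events(4.9, 3, 7)
        counts = {"singular": 0, "adjacent": 0}
        total = 0
        for _ in range(4000):
            out = assign_event_kinds("split", sched, rng)
            for ev in out.events:
                if ev.kind == "nontarget":
                    counts[ev.configuration] += 1
                    total += 1
        p = counts["singular"] / total
        sd = np.sqrt(0.25 / total)
        assert abs(p - 0.5) < 3 * sd

    def test_target_rate_half(self):
        rng = np.random.default_rng(5)
        sched = schedule_dimming_events(4.9, 3, 11)
        hits = sum(ev.kind == "target"
                   for _ in range(3000)
                   for ev in assign_event_kinds("broad", sched, rng).events)
        n = 3000 * 3
        assert abs(hits / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_stratified_exact_half(self):
        sched = schedule_dimming_events(4.9, 2, 13)
        out = assign_event_kinds("split", sched, 0, stratified=True)
        assert sum(e.kind == "target" for e in out.events) == 1


class TestDimmingProfile:
    def test_trajectory_peaks_at_mu_and_returns_to_zero(self):
        prof = DimmingProfile(depth=0.8)
        traj = prof.trajectory(120)
        t = np.arange(len(traj)) / 120
        assert traj[0] == pytest.approx(0.0, abs=1e-12)
        assert t[np.argmax(traj)] == pytest.approx(prof.mu, abs=1 / 120)
        assert traj.max() == pytest.approx(0.8)


class TestRsvpStream:
    def test_broad_target_frames_uniform_letter(self):
        s = make_rsvp_stream("broad", 2.5, 4.5, 2, 0)
        frame_dur = 1 / 2.5
        for onset in s.target_onsets:
            frame = s.letters[int(round(onset / frame_dur))]
            assert frame["innermost"] == frame["intermediate"] == frame["outermost"]

    def test_split_nontarget_frames(self):
        s = make_rsvp_stream("split", 2.5, 4.5, 0, 3, n_nontargets=2)
        frame_dur = 1 / 2.5
        for onset in s.nontarget_onsets:
            f = s.letters[int(round(onset / frame_dur))]
            assert f["intermediate"] in (f["innermost"], f["outermost"])
            assert f["innermost"] != f["outermost"]

    @pytest.mark.parametrize("focus", ["split", "broad"])
    def test_no_accidental_events(self, focus):
        """With zero scheduled events no frame forms a target or nontarget."""
        from tagattn.design import _EXP3_CUED, _frame_config

        for seed in range(10):
            s = make_rsvp_stream(focus, 2.5, 4.5, 0, seed)
            for frame in s.letters:
                assert _frame_config(frame, _EXP3_CUED[focus]) == "none"

    def test_letters_from_alphabet_only(self):
        s = make_rsvp_stream("broad", 2.5, 5.0, 2, 3, n_nontargets=1)
        for frame in s.letters:
            assert set(frame.values()) <= set(RSVP_ALPHABET)

    def test_no_event_in_pretest(self):
        for seed in range(10):
            s = make_rsvp_stream("split", 2.5, 4.5, 2, seed, n_nontargets=1)
            assert all(t >= 0.5 for t in s.target_onsets + s.nontarget_onsets)

    def test_too_slow_switch_rate_rejected(self):
        with pytest.raises((ValueError, RuntimeError)):
            make_rsvp_stream("broad", 0.2, 1.2, 2, 0)


class TestSessions:
    def test_exp1_block_structure(self):
        d = build_session("exp1", 720, 0)
        assert d.n_trials == 720
        assert d.trials["block"].nunique() == 72
        assert d.trials.groupby("block").size().eq(10).all()

    def test_exp1_counterbalancing(self):
        d = build_session("exp1", 720, 1)
        per = d.trials.drop_duplicates("block").groupby(["focus", "side"]).size()
        assert set(per) == {12}

    def test_exp2_balance_and_events(self):
        d = build_session("exp2", 240, 2)
        per = d.trials.drop_duplicates("block").groupby(["focus", "side"]).size()
        assert set(per) == {6}
        assert set(d.events["kind"]) <= {"target", "nontarget"}
        assert d.trials["trial_duration"].between(4.5, 5.0).all()

    def test_exp2_event_constraints(self):
        d = build_session("exp2", 80, 3)
        for trial, g in d.events.groupby("trial"):
            dur = d.trials.loc[d.trials.trial == trial, "trial_duration"].iloc[0]
            on = np.sort(g["onset"].to_numpy())
            assert on[0] >= 0.5 and on[-1] <= dur - 0.7
            assert (np.diff(on) >= 1.1 - 1e-9).all()

    def test_exp3_focus_split_count(self):
        d = build_session("exp3", 480, 4)
        counts = d.trials["focus"].value_counts()
        assert counts["split"] == 240 and counts["broad"] == 240

    def test_exp3_frequency_side_balance(self):
        d = build_session("exp3", 480, 5)
        blocks = d.trials.drop_duplicates("block")
        for loc in LOCATIONS:
            by_side = d.trials.groupby(["side", f"freq_{loc}"]).size()
            vals = by_side.unstack(fill_value=0)
            # each frequency equally often on each side
            assert (vals.to_numpy() == 120).all()
        assert blocks.groupby(["side", "layout_flipped"]).size().eq(40).all()

    def test_left_right_cue_balance(self):
        for exp, n in (("exp1", 120), ("exp2", 80), ("exp3", 48)):
            d = build_session(exp, n, 6)
            sides = d.trials["side"].value_counts()
            assert sides["left"] == sides["right"]

    @pytest.mark.parametrize("exp,n", [("exp1", 120), ("exp2", 80), ("exp3", 48)])
    def test_deterministic_sessions(self, exp, n):
        a = build_session(exp, n, 7)
        b = build_session(exp, n, 7)
        assert a.trials.to_csv() == b.trials.to_csv()
        assert a.events.to_csv() == b.events.to_csv()

    def test_indivisible_counts_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_session("exp1", 715, 0)
        with pytest.raises(ValueError, match="divisible"):
            build_session("exp3", 481, 0)

    def test_tsv_roundtrip(self, tmp_path):
        import pandas as pd

        d = build_session("exp2", 40, 8)
        d.to_tsv(tmp_path / "t.tsv", tmp_path / "e.tsv")
        back = pd.read_csv(tmp_path / "t.tsv", sep="\t")
        assert len(back) == 40
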