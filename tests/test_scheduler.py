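"""Control and AOS timeline construction, mechanisms and lesion effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from godiva_aos import (
    LesionConfig,
    PhoneSpec,
    SimulationError,
    SyllableSpec,
    TimingCalibration,
    UtteranceSpec,
    activity_at_initiation,
    assign_mechanisms,
    build_control_timeline,
    default_calibration,
    load_fixture,
    simulate_aos,
)

LES = LesionConfig()


def make_syllable(label, duration, short=False, combo=False, initial=30.0):
    final = duration - initial - 10.0
    return SyllableSpec(
        label=label,
        control_duration=duration,
        phones=(
            PhoneSpec(f"{label}_i", initial, "initial"),
            PhoneSpec(f"{label}_f", final, "final"),
        ),
        is_short=short,
        is_frequent_combo=combo,
    )


@st.composite
def utterances(draw, min_size=1, max_size=6, allow_short=True):
    n = draw(st.integers(min_size, max_size))
    syls = []
    for i in range(n):
        duration = draw(
            st.floats(min_value=120.0, max_value=400.0, allow_nan=False)
        )
        short = allow_short and draw(st.booleans())
        syls.append(make_syllable(f"s{i}", duration, short=short))
    return UtteranceSpec(label="random", syllables=tuple(syls))


class TestControlTimeline:
    def test_fixture_shifts_and_triggers(self, control_tl):
        shifts = [o.shift_out for o in control_tl.outcomes]
        triggers = [o.trigger_out for o in control_tl.outcomes]
        assert shifts[:4] == pytest.approx([423.0, 570.0, 666.0, 788.0])
        assert triggers[:4] == pytest.approx([381.0, 549.0, 636.0, 763.0])
        assert all(o.alpha_ff == 0.85 for o in control_tl.outcomes)
        assert all(
            o.initial_phone_prolongation_pct == 0.0 for o in control_tl.outcomes
        )
        assert all(o.mechanism_used == "threshold" for o in control_tl.outcomes)
        durations = [o.duration for o in control_tl.outcomes]
        assert durations == pytest.approx([278, 147, 96, 122, 180, 160])

    def test_single_syllable(self, cal):
        u = load_fixture("single_syllable")
        tl = build_control_timeline(u, cal)
        assert tl.outcomes[0].onset == pytest.approx(cal.onset_latency)
        assert tl.outcomes[0].shift_out == pytest.approx(cal.onset_latency + 200.0)

    @given(utterances())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_prefix_sum_oracle(self, u):
        """Control shifts are the utterance-onset latency plus prefix sums."""
        cal = TimingCalibration(activity_tau=6.72, activity_latency=8.2)
        tl = build_control_timeline(u, cal)
        expected = cal.onset_latency + np.cumsum(
            [s.control_duration for s in u.syllables]
        )
        assert [o.shift_out for o in tl.outcomes] == pytest.approx(list(expected))

    def test_lead_longer_than_duration_rejected(self, cal):
        u = UtteranceSpec("x", (make_syllable("s0", 121.0),))
        bad = TimingCalibration(
            trigger_leads={"s0": 130.0},
            activity_tau=cal.activity_tau,
            activity_latency=cal.activity_latency,
        )
        with pytest.raises(SimulationError, match="s0"):
            build_control_timeline(u, bad)


class TestActivityRise:
    def test_anchor_values(self, cal):
        assert activity_at_initiation(21.0, cal) == pytest.approx(332.0, abs=1e-6)
        assert activity_at_initiation(11.0, cal) == pytest.approx(133.0, abs=1e-6)

    def test_asymptote_never_exceeded(self, cal):
        assert activity_at_initiation(1e6, cal) <= cal.activity_asymptote
        assert activity_at_initiation(1e6, cal) == pytest.approx(390.0, abs=1e-6)

    def test_zero_below_latency(self, cal):
        assert activity_at_initiation(0.0, cal) == 0.0
        assert activity_at_initiation(cal.activity_latency, cal) == 0.0

    @given(
        st.floats(min_value=0.0, max_value=300.0),
        st.floats(min_value=0.5, max_value=50.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_strictly_increasing_past_latency(self, w, dw):
        cal = default_calibration()
        a1 = activity_at_initiation(w, cal)
        a2 = activity_at_initiation(w + dw, cal)
        assert a2 >= a1
        # strict increase past the latency, until float saturation at A_dyn
        if w > cal.activity_latency and a1 < cal.activity_asymptote * (1 - 1e-12):
            assert a2 > a1

    def test_negative_window_rejected(self, cal):
        with pytest.raises(SimulationError):
            activity_at_initiation(-1.0, cal)


class TestMechanismAssignment:
    def test_fixture_rules(self, potato, cal):
        rules = assign_mechanisms(potato, cal)
        by_from = {r.from_label: r for r in rules}
        assert by_from[None].mechanism == "altIII"
        assert by_from[None].memorized_latency == cal.onset_latency
        assert by_from["the"].mechanism == "altII"
        assert by_from["the"].memorized_duration == 96.0
        for label in ("here", "is", "po", "ta", "to"):
            assert by_from[label].mechanism == "altI"
            assert by_from[label].fixed_period == cal.lead_for(label)
        # terminal shift is the transition out of the last syllable
        assert by_from["to"].to_label is None

    def test_no_frequent_combos(self, cal):
        u = load_fixture("all_long_syllables")
        rules = assign_mechanisms(u, cal)
        assert rules[0].mechanism == "altIII"
        assert all(r.mechanism == "altI" for r in rules[1:])

    def test_consecutive_frequent_combos(self, cal):
        u = UtteranceSpec(
            "x",
            (
                make_syllable("a", 150.0),
                make_syllable("b", 130.0, short=True, combo=True),
                make_syllable("c", 140.0, short=True, combo=True),
                make_syllable("d", 200.0),
            ),
        )
        rules = {r.from_label: r.mechanism for r in assign_mechanisms(u, cal)}
        assert rules["b"] == rules["c"] == "altII"
        assert rules["a"] == rules["d"] == "altI"

    def test_first_syllable_frequent_combo_precedence(self, cal):
        u = UtteranceSpec(
            "x",
            (
                make_syllable("a", 130.0, short=True, combo=True),
                make_syllable("b", 200.0),
            ),
        )
        rules = assign_mechanisms(u, cal)
        assert rules[0].mechanism == "altIII"  # utterance start wins
        assert rules[1].from_label == "a" and rules[1].mechanism == "altII"


class TestAOSSimulation:
    def test_fixture_milestones(self, aos_tl, control_tl):
        the, po = aos_tl.outcome("the"), aos_tl.outcome("po")
        assert the.trigger_out == pytest.approx(655.0, abs=0.1)
        assert the.shift_out == pytest.approx(666.0)
        assert po.trigger_out == pytest.approx(900.0, abs=0.2)
        assert po.shift_out == pytest.approx(925.0, abs=0.2)
        assert po.duration == pytest.approx(259.0, abs=0.2)
        assert the.activity_at_init == pytest.approx(332.0, abs=1e-6)
        assert po.activity_at_init == pytest.approx(133.0, abs=0.6)
        assert the.mechanism_used == "altII"
        assert po.mechanism_used == "altI"

    def test_zero_lesion_equivalence(self, potato, cal, control_tl):
        tl = simulate_aos(potato, LesionConfig(left_lesion_fraction=0.0), cal)
        assert [(e.time, e.kind) for e in tl.events] == [
            (e.time, e.kind) for e in control_tl.events
        ]
        assert tl.durations() == control_tl.durations()

    def test_subthreshold_guarantee(self, aos_tl):
        assert max(o.activity_at_init for o in aos_tl.outcomes) < LES.readout_threshold
        assert max(o.activity_at_init for o in aos_tl.outcomes) <= 390.0

    def test_long_syllable_durations_preserved(self, cal):
        u = load_fixture("all_long_syllables")
        control = build_control_timeline(u, cal)
        for lesion in (0.05, 0.2225, 0.6, 1.0):
            aos = simulate_aos(u, LesionConfig(left_lesion_fraction=lesion), cal)
            assert aos.durations() == pytest.approx(control.durations())

    @given(utterances(allow_short=False, min_size=2))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_all_long_random_utterances_keep_control_durations(self, u):
        cal = TimingCalibration(activity_tau=6.72, activity_latency=8.2)
        control = build_control_timeline(u, cal)
        aos = simulate_aos(u, LES, cal)
        for c, a in zip(control.outcomes, aos.outcomes):
            assert a.duration == pytest.approx(c.duration)
            # catch-up truncates the final phone by the initial prolongation
            assert a.final_phone_truncation_ms == pytest.approx(
                a.initial_phone_prolongation_ms
            )

    def test_is_truncation_equals_initial_prolongation(self, aos_tl):
        o = aos_tl.outcome("is")
        assert o.final_phone_truncation_ms == pytest.approx(
            o.initial_phone_prolongation_ms
        )
        assert o.final_phone_truncation_ms > 0.0

    def test_short_syllables_have_no_truncation(self, aos_tl):
        for label in ("the", "po"):
            assert aos_tl.outcome(label).final_phone_truncation_ms == 0.0

    def test_domino_monotonicity(self):
        """Squeezing a short syllable's preparation window lengthens it."""
        u = UtteranceSpec(
            "x",
            (
                make_syllable("long0", 250.0),
                make_syllable("short1", 130.0, short=True),
                make_syllable("long2", 250.0),
            ),
        )
        durations = []
        for lead in (40.0, 30.0, 20.0, 14.0):
            cal = TimingCalibration(
                trigger_leads={"long0": lead, "short1": 25.0, "long2": 25.0},
                activity_tau=6.72,
                activity_latency=8.2,
            )
            tl = simulate_aos(u, LES, cal)
            assert tl.outcome("short1").prep_window == pytest.approx(lead)
            durations.append(tl.outcome("short1").duration)
        assert durations == sorted(durations)  # smaller window, longer syllable

    def test_over_truncation_raises_naming_syllable(self, cal):
        syl = SyllableSpec(
            label="tight",
            control_duration=200.0,
            phones=(
                PhoneSpec("t_i", 150.0, "initial"),
                PhoneSpec("t_f", 10.0, "final"),
            ),
        )
        u = UtteranceSpec("x", (make_syllable("first", 150.0, short=True), syl))
        with pytest.raises(SimulationError, match="tight"):
            simulate_aos(u, LES, cal)

    def test_event_ordering_invariants(self, control_tl, aos_tl):
        for tl in (control_tl, aos_tl):
            times = [e.time for e in tl.events]
            assert times == sorted(times)
            assert sum(e.kind == "utterance_onset" for e in tl.events) == 1
            assert sum(e.kind == "shift" for e in tl.events) == len(tl.outcomes)
            for o in tl.outcomes:
                assert o.onset < o.trigger_out < o.shift_out
                assert o.alpha_ff + o.alpha_fb == pytest.approx(1.0)
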