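"""Event-driven construction of control and AOS syllable timelines.

The control (neurotypical) timeline is pure bookkeeping: each syllable's SSM
population reaches the normal-readout threshold exactly on schedule, so
shifts fall at cumulative control durations after the utterance-onset
latency, and each shift-preparation trigger precedes its shift by the
calibrated lead.

The AOS timeline replaces threshold crossings with three alternative
shift-timing mechanisms (the populations never reach threshold):

* alt-I  — shift a learned fixed period after the shift-preparation trigger;
* alt-II — shift when the ongoing syllable's memorized (control) duration has
  elapsed since its onset, used for short syllables with a frequent
  syllable/duration combination;
* alt-III — start the first syllable a memorized latency after the
  utterance-initiation signal.

Two lesion effects propagate through the event chain.  Short-syllable
effect: prolonging a short syllable's initial phone pushes its outgoing
trigger late by the same amount; long syllables instead move the trigger
back to its control position, truncating their final phone.  Extra-low-
activity effect: a squeezed preparation window leaves the next population
far below threshold, amplifying its own prolongation — the domino that
lengthens 'po' after 'the'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple

from .config import (
    LesionConfig,
    TimingCalibration,
    UtteranceSpec,
    default_calibration,
    resolved,
)
from .weighting import compute_alpha_ff, prolong_ms, prolongation_percent

__all__ = [
    "SimulationError",
    "Mechanism",
    "TransitionRule",
    "SyllableOutcome",
    "Event",
    "EventTimeline",
    "activity_at_initiation",
    "assign_mechanisms",
    "build_control_timeline",
    "simulate_aos",
]

Mechanism = Literal["threshold", "altI", "altII", "altIII"]


class SimulationError(RuntimeError):
    """Raised when a timeline cannot be realized (e.g. over-truncation)."""


@dataclass(frozen=True)
class TransitionRule:
    """Shift-timing rule for one boundary (from_label None = utterance start,
    to_label None = terminal shift)."""

    from_label: str | None
    to_label: str | None
    mechanism: Mechanism
    fixed_period: float | None = None      # altI
    memorized_duration: float | None = None  # altII
    memorized_latency: float | None = None   # altIII

    def __post_init__(self) -> None:
        if self.mechanism == "altIII" and self.from_label is not None:
            raise SimulationError("altIII applies only at the utterance start")


@dataclass(frozen=True)
class SyllableOutcome:
    label: str
    onset: float
    trigger_out: float
    shift_out: float
    prep_window: float
    activity_at_init: float
    alpha_ff: float
    alpha_fb: float
    initial_phone_prolongation_pct: float
    initial_phone_prolongation_ms: float
    final_phone_truncation_ms: float
    mechanism_used: Mechanism

    @property
    def duration(self) -> float:
        return self.shift_out - self.onset


class Event(NamedTuple):
    time: float
    kind: str  # utterance_onset | prep_trigger | shift
    payload: dict


@dataclass
class EventTimeline:
    mode: Literal["control", "aos"]
    utterance: UtteranceSpec
    outcomes: list[SyllableOutcome]
    events: list[Event] = field(default_factory=list)

    def outcome(self, label: str) -> SyllableOutcome:
        for o in self.outcomes:
            if o.label == label:
                return o
        raise KeyError(label)

    def durations(self) -> dict[str, float]:
        return {o.label: o.duration for o in self.outcomes}

    def validate(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a - 1e-9 for a, b in zip(times, times[1:])):
            raise SimulationError("event times must be non-decreasing")
        onsets = [e for e in self.events if e.kind == "utterance_onset"]
        if len(onsets) != 1 or onsets[0].time < 0:
            raise SimulationError("exactly one utterance_onset at t >= 0 required")
        shifts = [e for e in self.events if e.kind == "shift"]
        if len(shifts) != len(self.outcomes):
            raise SimulationError("one shift per syllable boundary plus terminal")
        for o in self.outcomes:
            if not (o.onset < o.trigger_out < o.shift_out):
                raise SimulationError(
                    f"syllable {o.label!r}: require onset < trigger_out < shift_out"
                )


def activity_at_initiation(prep_window: float, cal: TimingCalibration) -> float:
    """SSM activity reached inside a preparation window of ``prep_window`` ms.

    Saturating exponential rise toward the sub-threshold asymptote A_dyn,
    after an onset latency t_lat below which no activity accrues; strictly
    increasing in the window length and bounded above by A_dyn.
    """
    if prep_window < 0:
        raise SimulationError(f"preparation window must be >= 0, got {prep_window}")
    cal = resolved(cal)
    if prep_window <= cal.activity_latency:
        return 0.0
    return cal.activity_asymptote * (
        1.0 - math.exp(-(prep_window - cal.activity_latency) / cal.activity_tau)
    )


def assign_mechanisms(
    u: UtteranceSpec, cal: TimingCalibration | None = None
) -> list[TransitionRule]:
    """Assign a shift-timing mechanism to every boundary of an AOS run.

    The first syllable is timed from the utterance-onset signal (alt-III);
    a transition out of a short, frequent-combination syllable uses the
    memory trace of its control duration (alt-II); every other transition —
    including the terminal shift — uses the fixed post-trigger period
    (alt-I).  At the utterance start alt-III takes precedence even if the
    first syllable is a frequent combination.
    """
    cal = cal or default_calibration()
    rules = [
        TransitionRule(
            from_label=None,
            to_label=u.syllables[0].label,
            mechanism="altIII",
            memorized_latency=cal.onset_latency,
        )
    ]
    for i, syl in enumerate(u.syllables):
        to_label = u.syllables[i + 1].label if i + 1 < len(u.syllables) else None
        if syl.is_frequent_combo and syl.is_short:
            rules.append(
                TransitionRule(
                    from_label=syl.label,
                    to_label=to_label,
                    mechanism="altII",
                    memorized_duration=syl.control_duration,
                )
            )
        else:
            rules.append(
                TransitionRule(
                    from_label=syl.label,
                    to_label=to_label,
                    mechanism="altI",
                    fixed_period=cal.fixed_period_for(syl.label),
                )
            )
    return rules


def _transition_events(
    u: UtteranceSpec, outcomes: list[SyllableOutcome]
) -> list[Event]:
    events: list[Event] = [Event(0.0, "utterance_onset", {"to": u.syllables[0].label})]
    labels = list(u.labels) + [None]
    for o, nxt in zip(outcomes, labels[1:]):
        events.append(Event(o.trigger_out, "prep_trigger", {"from": o.label, "to": nxt}))
        events.append(Event(o.shift_out, "shift", {"from": o.label, "to": nxt}))
    events.sort(key=lambda e: e.time)
    return events


def build_control_timeline(
    u: UtteranceSpec, cal: TimingCalibration | None = None
) -> EventTimeline:
    """Neurotypical timeline: threshold shifts at cumulative control durations."""
    cal = resolved(cal or default_calibration())
    outcomes: list[SyllableOutcome] = []
    onset = cal.onset_latency
    prev_lead = (
        cal.first_prep_window
        if cal.first_prep_window is not None
        else cal.lead_for(u.syllables[0].label)
    )
    threshold = LesionConfig().readout_threshold
    for syl in u.syllables:
        lead = cal.lead_for(syl.label)
        if lead >= syl.control_duration:
            raise SimulationError(
                f"syllable {syl.label!r}: trigger lead {lead} must be shorter "
                f"than control duration {syl.control_duration}"
            )
        shift_out = onset + syl.control_duration
        outcomes.append(
            SyllableOutcome(
                label=syl.label,
                onset=onset,
                trigger_out=shift_out - lead,
                shift_out=shift_out,
                prep_window=prev_lead,
                activity_at_init=threshold,
                alpha_ff=0.85,
                alpha_fb=0.15,
                initial_phone_prolongation_pct=0.0,
                initial_phone_prolongation_ms=0.0,
                final_phone_truncation_ms=0.0,
                mechanism_used="threshold",
            )
        )
        prev_lead = lead
        onset = shift_out
    tl = EventTimeline(
        mode="control",
        utterance=u,
        outcomes=outcomes,
        events=_transition_events(u, outcomes),
    )
    tl.validate()
    return tl


def simulate_aos(
    u: UtteranceSpec,
    les: LesionConfig | None = None,
    cal: TimingCalibration | None = None,
) -> EventTimeline:
    """Lesioned timeline under the alternative shift-timing mechanisms.

    Per syllable, in order: the preparation window it was granted sets its
    SSM activity at initiation, hence its feedforward weighting and the
    prolongation of its initial phone; the prolongation then either delays
    the outgoing trigger (short syllable) or truncates the final phone while
    the trigger catches up to its control position (long syllable); finally
    the transition's mechanism places the outgoing shift.  With a zero
    lesion the construction collapses to the control timeline event-for-
    event.
    """
    les = les or LesionConfig()
    cal = resolved(cal or default_calibration())
    if les.total_dead_fraction == 0.0:
        return replace(build_control_timeline(u, cal), mode="aos")

    rules = assign_mechanisms(u, cal)
    outcomes: list[SyllableOutcome] = []
    onset = rules[0].memorized_latency  # altIII: memorized utterance latency
    prep = (
        cal.first_prep_window
        if cal.first_prep_window is not None
        else cal.lead_for(u.syllables[0].label)
    )
    for syl, rule_out in zip(u.syllables, rules[1:]):
        activity = activity_at_initiation(prep, cal)
        if activity >= les.readout_threshold:
            raise SimulationError(
                f"syllable {syl.label!r}: sub-threshold regime violated "
                f"(activity {activity} >= T {les.readout_threshold})"
            )
        w = compute_alpha_ff(activity, les)
        pct = prolongation_percent(w, les)
        pro_ms = prolong_ms(syl.initial_phone, pct)
        # control-relative trigger position within the syllable
        ctrl_trigger_rel = syl.control_duration - cal.lead_for(syl.label)
        if syl.is_short:
            trigger_out = onset + ctrl_trigger_rel + pro_ms  # Short-syllable effect
            truncation = 0.0
        else:
            trigger_out = onset + ctrl_trigger_rel  # catch-up
            truncation = pro_ms
            if truncation >= syl.final_phone.duration:
                raise SimulationError(
                    f"syllable {syl.label!r}: final-phone truncation "
                    f"{truncation:.1f} ms exceeds final phone duration "
                    f"{syl.final_phone.duration} ms"
                )
        if rule_out.mechanism == "altII":
            shift_out = onset + rule_out.memorized_duration
        else:  # altI
            shift_out = trigger_out + rule_out.fixed_period
        if not (onset < trigger_out < shift_out):
            raise SimulationError(
                f"syllable {syl.label!r}: event ordering violated "
                f"(onset {onset:.1f}, trigger {trigger_out:.1f}, shift {shift_out:.1f})"
            )
        outcomes.append(
            SyllableOutcome(
                label=syl.label,
                onset=onset,
                trigger_out=trigger_out,
                shift_out=shift_out,
                prep_window=prep,
                activity_at_init=activity,
                alpha_ff=w.alpha_ff,
                alpha_fb=w.alpha_fb,
                initial_phone_prolongation_pct=pct,
                initial_phone_prolongation_ms=pro_ms,
                final_phone_truncation_ms=truncation,
                mechanism_used=rule_out.mechanism,
            )
        )
        prep = shift_out - trigger_out
        if prep < 0:
            raise SimulationError(
                f"negative preparation window after syllable {syl.label!r}"
            )
        onset = shift_out
    tl = EventTimeline(
        mode="aos",
        utterance=u,
        outcomes=outcomes,
        events=_transition_events(u, outcomes),
    )
    tl.validate()
    return tl
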