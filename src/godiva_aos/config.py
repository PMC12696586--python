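"""Domain types, configuration parsing and default calibration tables.

The simulator works in milliseconds from the utterance-initiation signal at
t = 0; syllable intervals are half-open [onset, shift_out).  Everything the
other modules consume — the utterance description, the lesion parameters and
the timing calibration — is defined and validated here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from scipy.optimize import fsolve

__all__ = [
    "ConfigError",
    "PhoneSpec",
    "SyllableSpec",
    "UtteranceSpec",
    "LesionConfig",
    "TimingCalibration",
    "load_utterance",
    "serialize_utterance",
    "default_calibration",
    "fit_activity_rise",
    "load_fixture",
    "fixture_path",
    "ACTIVITY_ANCHORS",
]

PHONE_POSITIONS = ("initial", "final", "other")


class ConfigError(ValueError):
    """Raised when an utterance or calibration config violates an invariant."""


@dataclass(frozen=True)
class PhoneSpec:
    """A single phone with its neurotypical (control) duration.

    position marks the phone's role for shift-trigger timing: the *initial*
    phone is the one prolonged under feedback reliance, the *final* phone
    hosts the articulatory configuration that cues the shift-preparation
    trigger.  A CV syllable may carry a single phone with position
    ``initial``; it then doubles as the final phone.
    """

    label: str
    duration: float  # ms, control condition
    position: str = "other"

    def __post_init__(self) -> None:
        if self.position not in PHONE_POSITIONS:
            raise ConfigError(
                f"phone {self.label!r}: position must be one of "
                f"{PHONE_POSITIONS}, got {self.position!r}"
            )
        if not self.duration > 0:
            raise ConfigError(
                f"phone {self.label!r}: duration must be > 0, got {self.duration}"
            )


@dataclass(frozen=True)
class SyllableSpec:
    label: str
    control_duration: float  # ms
    phones: tuple[PhoneSpec, ...]
    is_short: bool = False
    is_frequent_combo: bool = False

    def __post_init__(self) -> None:
        if not self.control_duration > 0:
            raise ConfigError(
                f"syllable {self.label!r}: control_duration must be > 0"
            )
        initials = [p for p in self.phones if p.position == "initial"]
        finals = [p for p in self.phones if p.position == "final"]
        if len(initials) != 1:
            raise ConfigError(
                f"syllable {self.label!r}: exactly one initial phone required, "
                f"found {len(initials)}"
            )
        if len(finals) > 1:
            raise ConfigError(
                f"syllable {self.label!r}: at most one final phone allowed, "
                f"found {len(finals)}"
            )
        if self.initial_phone.duration + self.final_phone.duration > self.control_duration and finals:
            raise ConfigError(
                f"syllable {self.label!r}: initial + final phone durations "
                f"exceed control_duration"
            )
        if self.is_frequent_combo and not self.is_short:
            # memory-trace shift timing applies strictly to short syllables
            raise ConfigError(
                f"syllable {self.label!r}: is_frequent_combo requires is_short"
            )

    @property
    def initial_phone(self) -> PhoneSpec:
        return next(p for p in self.phones if p.position == "initial")

    @property
    def final_phone(self) -> PhoneSpec:
        """Explicit final phone, or the initial phone for CV syllables."""
        for p in self.phones:
            if p.position == "final":
                return p
        return self.initial_phone


@dataclass(frozen=True)
class UtteranceSpec:
    label: str
    syllables: tuple[SyllableSpec, ...]

    def __post_init__(self) -> None:
        if not self.syllables:
            raise ConfigError("utterance must contain at least one syllable")
        labels = [s.label for s in self.syllables]
        if len(set(labels)) != len(labels):
            raise ConfigError(
                f"utterance {self.label!r}: syllable labels must be unique"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.syllables)

    def __getitem__(self, label: str) -> SyllableSpec:
        for s in self.syllables:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class LesionConfig:
    """Lesion extent and the control-weighting constants it acts through.

    Defaults describe the average AOS lesion of the study cohort: 22.25 % of
    left-hemisphere SSM neurons dead, with 80 % of SSM neurons sitting in the
    left hemisphere, i.e. 17.8 % of the population overall.
    """

    left_lesion_fraction: float = 0.2225
    left_hemisphere_share: float = 0.8
    readout_threshold: float = 400.0   # T: 80 % of max activity
    max_activity: float = 500.0        # A_max, BA6/44/insula ceiling
    baseline_alpha_ff: float = 0.85    # neurotypical feedforward weighting
    prolongation_factor: float = -2.142  # P_estimate, printed value

    def __post_init__(self) -> None:
        if not 0.0 <= self.left_lesion_fraction <= 1.0:
            raise ConfigError("left_lesion_fraction must be in [0, 1]")
        if not 0.0 < self.left_hemisphere_share <= 1.0:
            raise ConfigError("left_hemisphere_share must be in (0, 1]")
        if not self.readout_threshold > 0:
            raise ConfigError("readout_threshold must be > 0")
        if self.prolongation_factor >= 0:
            raise ConfigError("prolongation_factor must be negative")

    @property
    def total_dead_fraction(self) -> float:
        """Whole-SSM dead fraction: right hemisphere is assumed intact."""
        return self.left_lesion_fraction * self.left_hemisphere_share


# Calibration anchors for the sub-threshold activity rise: printed SSM
# activities reached inside known preparation windows of the AOS timeline
# (332 inside the 21 ms is->the gap; 133 inside the 11 ms the->po gap).
ACTIVITY_ANCHORS: tuple[tuple[float, float], tuple[float, float]] = (
    (21.0, 332.0),
    (11.0, 133.0),
)

# Control-condition trigger leads (shift minus trigger, per transition out of
# a syllable).  here/is/the/po are differences of printed event times
# (423-381, 570-549, 666-636, 788-763); ta/to are unconstrained defaults.
_DEFAULT_TRIGGER_LEADS: Mapping[str, float] = {
    "here": 42.0,
    "is": 21.0,
    "the": 30.0,
    "po": 25.0,
    "ta": 25.0,
    "to": 25.0,
}


@dataclass(frozen=True)
class TimingCalibration:
    """Event-timing constants for both the control and AOS schedulers.

    onset_latency is the gap between the utterance-initiation signal (t = 0)
    and the first syllable's onset (145 ms = 423 − 278 from the control
    timeline).  trigger_leads map a syllable label to the control-condition
    interval between its outgoing shift-preparation trigger and the shift;
    fixed_periods are the learned post-trigger delays of alternative
    shift-timing I and default to the corresponding control lead.  The
    activity-rise constants (asymptote, tau, latency) describe how far a
    sub-threshold SSM population climbs inside a preparation window.
    """

    onset_latency: float = 145.0
    trigger_leads: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TRIGGER_LEADS)
    )
    default_trigger_lead: float = 25.0
    fixed_periods: Mapping[str, float] = field(default_factory=dict)
    activity_asymptote: float = 390.0  # A_dyn: sub-threshold ceiling
    activity_tau: float | None = None  # ms, derived from anchors if None
    activity_latency: float | None = None  # ms, derived from anchors if None
    first_prep_window: float | None = None  # None -> first syllable's lead
    trace_dt: float = 0.33  # ms, integration/rendering step

    def __post_init__(self) -> None:
        if self.onset_latency < 0:
            raise ConfigError("onset_latency must be >= 0")
        if not self.trace_dt > 0:
            raise ConfigError("trace_dt must be > 0")
        if any(v < 0 for v in self.trigger_leads.values()):
            raise ConfigError("trigger leads must be >= 0")

    def lead_for(self, label: str) -> float:
        return float(self.trigger_leads.get(label, self.default_trigger_lead))

    def fixed_period_for(self, label: str) -> float:
        """Alt-I fixed period for the transition out of ``label``.

        Defaults to the control trigger-to-shift gap, which is what an
        intact system would implicitly have learned premorbidly.
        """
        if label in self.fixed_periods:
            return float(self.fixed_periods[label])
        return self.lead_for(label)


def fit_activity_rise(
    anchors: Iterable[tuple[float, float]] = ACTIVITY_ANCHORS,
    asymptote: float = 390.0,
) -> tuple[float, float]:
    """Solve the activity-rise constants (tau, latency) from two anchors.

    The sub-threshold rise is ``a(w) = A_dyn * (1 - exp(-(w - t_lat)/tau))``
    for a preparation window ``w > t_lat``.  Given two (window, activity)
    anchor points the two constants are determined; they are obtained here by
    numerically solving the pair of equations.
    """
    (w1, a1), (w2, a2) = tuple(anchors)
    if not (0 < a1 < asymptote and 0 < a2 < asymptote):
        raise ConfigError("anchor activities must lie in (0, asymptote)")

    def equations(p):
        tau, lat = p
        return (
            asymptote * (1.0 - math.exp(-(w1 - lat) / tau)) - a1,
            asymptote * (1.0 - math.exp(-(w2 - lat) / tau)) - a2,
        )

    (tau, lat), info, ier, msg = fsolve(
        equations, x0=(5.0, 5.0), full_output=True
    )
    if ier != 1 or max(abs(r) for r in info["fvec"]) > 1e-8:
        raise ConfigError(f"activity-rise calibration did not converge: {msg}")
    return float(tau), float(lat)


def default_calibration() -> TimingCalibration:
    """The default timing calibration, with rise constants re-derived.

    tau and t_lat are solved from the two activity anchors at call time
    rather than stored, so the table is always self-consistent with the
    anchors (tau ~ 6.72 ms, t_lat ~ 8.20 ms).
    """
    tau, lat = fit_activity_rise()
    return TimingCalibration(activity_tau=tau, activity_latency=lat)


def resolved(cal: TimingCalibration) -> TimingCalibration:
    """Return a calibration with activity constants filled in if absent."""
    if cal.activity_tau is not None and cal.activity_latency is not None:
        return cal
    tau, lat = fit_activity_rise(asymptote=cal.activity_asymptote)
    return replace(cal, activity_tau=tau, activity_latency=lat)


# ---------------------------------------------------------------------------
# Utterance config I/O

def _parse_phone(raw: dict, where: str) -> PhoneSpec:
    if "duration" not in raw:
        raise ConfigError(f"{where}: missing duration")
    try:
        return PhoneSpec(
            label=str(raw.get("label", "?")),
            duration=float(raw["duration"]),
            position=str(raw.get("position", "other")),
        )
    except ConfigError as exc:
        raise ConfigError(f"{where}: {exc}") from None


def _parse_syllable(raw: dict, idx: int) -> SyllableSpec:
    where = f"syllables[{idx}]"
    if "label" not in raw:
        raise ConfigError(f"{where}: missing label")
    if "control_duration" not in raw:
        raise ConfigError(f"{where}.control_duration: missing duration")
    phones = tuple(
        _parse_phone(p, f"{where}.phones[{j}]")
        for j, p in enumerate(raw.get("phones", []))
    )
    try:
        return SyllableSpec(
            label=str(raw["label"]),
            control_duration=float(raw["control_duration"]),
            phones=phones,
            is_short=bool(raw.get("is_short", False)),
            is_frequent_combo=bool(raw.get("is_frequent_combo", False)),
        )
    except ConfigError as exc:
        raise ConfigError(f"{where}: {exc}") from None


def load_utterance(source: str | Path) -> UtteranceSpec:
    """Parse an utterance config from YAML/JSON text or a file path.

    Unspecified flags default to False; missing or non-positive durations and
    a frequent-combo flag on a long syllable raise :class:`ConfigError`
    naming the offending field.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "syllables" not in raw:
        raise ConfigError("utterance config must be a mapping with 'syllables'")
    syllables = tuple(
        _parse_syllable(s, i) for i, s in enumerate(raw["syllables"])
    )
    return UtteranceSpec(label=str(raw.get("label", "utterance")), syllables=syllables)


def serialize_utterance(u: UtteranceSpec) -> dict:
    """Normalized plain-dict form of an utterance (round-trips with load)."""
    return {
        "label": u.label,
        "syllables": [
            {
                "label": s.label,
                "control_duration": s.control_duration,
                "is_short": s.is_short,
                "is_frequent_combo": s.is_frequent_combo,
                "phones": [
                    {"label": p.label, "duration": p.duration, "position": p.position}
                    for p in s.phones
                ],
            }
            for s in u.syllables
        ],
    }


def fixture_path(name: str) -> Path:
    """Path to a packaged utterance fixture (e.g. 'here_is_the_potato')."""
    ref = resources.files("godiva_aos").joinpath(f"data/{name}.yaml")
    with resources.as_file(ref) as p:
        return Path(p)


def load_fixture(name: str) -> UtteranceSpec:
    ref = resources.files("godiva_aos").joinpath(f"data/{name}.yaml")
    return load_utterance(ref.read_text())
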