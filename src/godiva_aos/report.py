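"""Paired control/AOS comparison: lengthening, stress contrast, report I/O.

Syllable lengthening is the percent change of a syllable's duration between
the AOS and control runs.  Lexical stress contrast is summarized with the
pairwise variability index (PVI): 100 times the mean, over adjacent
syllable pairs, of the absolute duration difference normalized by the pair
mean.  The PVI here uses total syllable durations (the simulator's native
quantity); acoustic studies often restrict it to the voiced portion, a known
representational difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .scheduler import EventTimeline

__all__ = [
    "ComparisonReport",
    "lengthening_percent",
    "compute_pvi",
    "stress_pairs",
    "build_report",
]


def lengthening_percent(d_aos: float, d_control: float) -> float:
    """Percent lengthening of a syllable between AOS and control runs."""
    if d_control <= 0:
        raise ValueError(f"control duration must be > 0, got {d_control}")
    return 100.0 * (d_aos - d_control) / d_control


def compute_pvi(durations: Sequence[float]) -> float:
    """Pairwise variability index of an ordered duration sequence.

    100 x mean over adjacent pairs of |d_k - d_{k+1}| / pair mean; zero for
    a perfectly even sequence, larger for stronger durational contrast.
    """
    if len(durations) < 2:
        raise ValueError("PVI needs at least 2 durations")
    terms = [
        abs(a - b) / ((a + b) / 2.0)
        for a, b in zip(durations, durations[1:])
    ]
    return 100.0 * sum(terms) / len(terms)


def stress_pairs(tl: EventTimeline) -> list[tuple[str, str]]:
    """Designated unstressed-stressed pairs: a short syllable followed by a
    long one (e.g. 'po'-'ta' in 'potato')."""
    syls = tl.utterance.syllables
    return [
        (a.label, b.label)
        for a, b in zip(syls, syls[1:])
        if a.is_short and not b.is_short
    ]


@dataclass
class ComparisonReport:
    utterance_label: str
    per_syllable: pd.DataFrame          # label, control/aos durations, lengthening
    pvi_pairs: dict[tuple[str, str], dict[str, float]]
    phone_prolongation: pd.DataFrame    # label, pct, ms, truncation
    calibration_echo: dict = field(default_factory=dict)

    def lengthening(self, label: str) -> float:
        row = self.per_syllable.set_index("label").loc[label]
        return float(row["lengthening_pct"])

    def to_json_dict(self) -> dict:
        return {
            "utterance": self.utterance_label,
            "per_syllable": self.per_syllable.to_dict(orient="records"),
            "pvi_pairs": [
                {"pair": list(pair), **vals} for pair, vals in self.pvi_pairs.items()
            ],
            "phone_prolongation": self.phone_prolongation.to_dict(orient="records"),
            "calibration": self.calibration_echo,
        }


def build_report(
    control: EventTimeline, aos: EventTimeline
) -> ComparisonReport:
    """Full paired comparison of a control and an AOS timeline."""
    if [o.label for o in control.outcomes] != [o.label for o in aos.outcomes]:
        raise ValueError("control and AOS timelines describe different utterances")

    rows = []
    for c, a in zip(control.outcomes, aos.outcomes):
        rows.append(
            {
                "label": c.label,
                "control_duration_ms": c.duration,
                "aos_duration_ms": a.duration,
                "lengthening_pct": lengthening_percent(a.duration, c.duration),
            }
        )
    per_syllable = pd.DataFrame(rows)

    pvi_pairs: dict[tuple[str, str], dict[str, float]] = {}
    ctrl_dur = control.durations()
    aos_dur = aos.durations()
    for pair in stress_pairs(control):
        pvi_pairs[pair] = {
            "pvi_control": compute_pvi([ctrl_dur[x] for x in pair]),
            "pvi_aos": compute_pvi([aos_dur[x] for x in pair]),
        }

    phone = pd.DataFrame(
        [
            {
                "label": a.label,
                "alpha_ff": a.alpha_ff,
                "activity_at_init": a.activity_at_init,
                "prolongation_pct": a.initial_phone_prolongation_pct,
                "prolongation_ms": a.initial_phone_prolongation_ms,
                "final_phone_truncation_ms": a.final_phone_truncation_ms,
            }
            for a in aos.outcomes
        ]
    )
    return ComparisonReport(
        utterance_label=control.utterance.label,
        per_syllable=per_syllable,
        pvi_pairs=pvi_pairs,
        phone_prolongation=phone,
    )
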