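"""Lesion-induced control re-weighting algebra.

Under a speech-sound-map (SSM) lesion, a syllable's motor program is read out
while its neuron population is still sub-threshold.  The readout strength —
the weighting toward feedforward control, alpha_ff — scales linearly with the
population activity s at the time of the shift:

    alpha_ff = 0.85 * min(s, T) / T

with T the normal-readout threshold.  Feedback control compensates
(alpha_fb = 1 - alpha_ff), and the reliance on slow feedback prolongs the
syllable-initial phone in proportion to the percent change of alpha_ff from
its 0.85 baseline, via the prolongation factor P_estimate = -2.142
(calibrated on a 150 % phone prolongation at a 70 % alpha_ff reduction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import LesionConfig, PhoneSpec

__all__ = [
    "ControlWeights",
    "compute_alpha_ff",
    "prolongation_percent",
    "prolong_ms",
    "lesion_total_fraction",
    "unified_lesion_mean",
]


@dataclass(frozen=True)
class ControlWeights:
    """Feedforward/feedback weighting pair; the two always sum to 1.

    alpha_ff_rounded is alpha_ff truncated to two decimals — the precision at
    which the weighting enters the prolongation formula (0.7055 enters as
    0.70).  The unrounded value is retained for reporting.
    """

    alpha_ff: float
    alpha_fb: float
    alpha_ff_rounded: float


def _truncate2(x: float) -> float:
    # floor to 2 decimals with a guard against float dust just below a tick
    return math.floor(x * 100.0 + 1e-9) / 100.0


def compute_alpha_ff(s: float, cfg: LesionConfig | None = None) -> ControlWeights:
    """Feedforward weighting for SSM activity ``s`` at syllable initiation.

    Activity at or above the normal-readout threshold clamps the weighting at
    the baseline (readout is normal); below threshold the weighting degrades
    linearly.  Negative activity is a domain error.
    """
    cfg = cfg or LesionConfig()
    if s < 0:
        raise ValueError(f"SSM activity must be >= 0, got {s}")
    alpha = cfg.baseline_alpha_ff * min(s, cfg.readout_threshold) / cfg.readout_threshold
    return ControlWeights(
        alpha_ff=alpha,
        alpha_fb=1.0 - alpha,
        alpha_ff_rounded=_truncate2(alpha),
    )


def prolongation_percent(w: ControlWeights, cfg: LesionConfig | None = None) -> float:
    """Percent prolongation of the syllable-initial phone.

    Applies the prolongation factor to the percent change of the (truncated)
    feedforward weighting from baseline; zero iff the weighting is at
    baseline, and at most ``-P_estimate * 100`` for a fully silent population.
    """
    cfg = cfg or LesionConfig()
    pct_change_alpha = (
        100.0 * (w.alpha_ff_rounded - cfg.baseline_alpha_ff) / cfg.baseline_alpha_ff
    )
    # both factors are negative (weight drops, factor is inverse): product >= 0
    result = cfg.prolongation_factor * pct_change_alpha
    return result if result != 0.0 else 0.0  # normalize -0.0 at baseline


def prolong_ms(phone: PhoneSpec, pct: float) -> float:
    """Absolute prolongation of a phone, in ms, from a percent prolongation."""
    if pct < 0:
        raise ValueError(f"prolongation percent must be >= 0, got {pct}")
    return phone.duration * pct / 100.0


def lesion_total_fraction(left_fraction: float, left_share: float) -> float:
    """Whole-SSM dead fraction from a left-hemisphere lesion fraction.

    The right-hemisphere SSM is assumed intact, so e.g. a 22.25 % left lesion
    with an 80 % left share gives 17.8 % dead neurons in total.
    """
    if not 0.0 <= left_fraction <= 1.0:
        raise ValueError(f"left_fraction must be in [0, 1], got {left_fraction}")
    if not 0.0 <= left_share <= 1.0:
        raise ValueError(f"left_share must be in [0, 1], got {left_share}")
    return left_fraction * left_share


def unified_lesion_mean(lateral_pct: float, medial_pct: float) -> float:
    """Mean lesion extent over the lateral and medial left-SSM components."""
    if lateral_pct < 0 or medial_pct < 0:
        raise ValueError("lesion percentages must be >= 0")
    return (lateral_pct + medial_pct) / 2.0
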