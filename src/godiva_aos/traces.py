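"""Continuous activity time courses derived from an event timeline.

The scheduler is event-level; these traces are a post-hoc rendering for
visualization and milestone cross-checks, in the style of the model's
published time-course figures.  Each syllable's SSM series rises along a
saturating exponential during its preparation window so that it attains
exactly the recorded activity-at-initiation at its shift-in time, holds that
level during execution, and is quenched (fast exponential decay) once its
own putamen D2R population fires the outgoing shift-preparation trigger.
The D2R series are rectangular transient pulses at the trigger times.

Shapes (pulse width, decay constant, pulse amplitude) are presentation
parameters only; the event times and activity levels are the quantities
anchored to the scheduler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, TimingCalibration, default_calibration, resolved
from .scheduler import EventTimeline

__all__ = ["TraceSet", "render_traces", "export_traces", "plot_traces"]

QUENCH_TAU = 5.0     # ms, post-trigger decay constant
PULSE_WIDTH = 20.0   # ms, D2R transient width
PULSE_AMPLITUDE = 450.0  # arbitrary units, unconstrained presentation choice
TAIL = 60.0          # ms of padding after the last event


@dataclass
class TraceSet:
    dt: float
    time: np.ndarray                      # ms grid
    ssm: dict[str, np.ndarray] = field(default_factory=dict)
    d2r: dict[str, np.ndarray] = field(default_factory=dict)

    def max_ssm(self) -> float:
        if not self.ssm:
            return 0.0
        return max(float(np.max(v)) for v in self.ssm.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: time_ms, population, value."""
        rows = []
        for label, series in self.ssm.items():
            rows.append(
                pd.DataFrame(
                    {"time_ms": self.time, "population": f"ssm:{label}", "value": series}
                )
            )
        for label, series in self.d2r.items():
            rows.append(
                pd.DataFrame(
                    {"time_ms": self.time, "population": f"d2r:{label}", "value": series}
                )
            )
        if not rows:
            return pd.DataFrame(columns=["time_ms", "population", "value"])
        return pd.concat(rows, ignore_index=True)


def _rise(t: np.ndarray, start: float, end: float, level: float,
          tau: float, lat: float) -> np.ndarray:
    """Scaled saturating rise that reaches ``level`` exactly at ``end``."""
    window = end - start
    out = np.zeros_like(t)
    if window <= 0 or level <= 0:
        return out
    denom = 1.0 - np.exp(-max(window - lat, 1e-12) / tau)
    x = t - start
    active = x > lat
    out[active] = level * (1.0 - np.exp(-(x[active] - lat) / tau)) / denom
    return np.clip(out, 0.0, level)


def render_traces(
    tl: EventTimeline, cal: TimingCalibration | None = None
) -> TraceSet:
    """Render per-syllable SSM and putamen-D2R series for a timeline."""
    cal = resolved(cal or default_calibration())
    if cal.trace_dt <= 0:
        raise ConfigError("trace_dt must be > 0")
    if not tl.outcomes:
        return TraceSet(dt=cal.trace_dt, time=np.array([]))
    t_end = max(o.shift_out for o in tl.outcomes) + TAIL
    time = np.arange(0.0, t_end, cal.trace_dt)
    ts = TraceSet(dt=cal.trace_dt, time=time)
    for o in tl.outcomes:
        rise_start = o.onset - o.prep_window  # trigger-in of this syllable
        series = _rise(
            time, rise_start, o.onset, o.activity_at_init,
            cal.activity_tau, cal.activity_latency,
        )
        # hold at the initiation level while the syllable executes
        hold = (time >= o.onset) & (time < o.trigger_out)
        series[hold] = o.activity_at_init
        # quench after the outgoing D2R pulse
        decay = time >= o.trigger_out
        series[decay] = o.activity_at_init * np.exp(
            -(time[decay] - o.trigger_out) / QUENCH_TAU
        )
        ts.ssm[o.label] = series
        pulse = np.zeros_like(time)
        pulse[(time >= o.trigger_out) & (time < o.trigger_out + PULSE_WIDTH)] = (
            PULSE_AMPLITUDE
        )
        ts.d2r[o.label] = pulse
    return ts


def export_traces(ts: TraceSet, path) -> pd.DataFrame:
    """Write the long-format CSV (time_ms, population, value); returns it."""
    frame = ts.to_frame()
    frame.to_csv(path, index=False)
    return frame


def plot_traces(ts: TraceSet, path=None):
    """Two-panel figure (SSM populations, D2R pulses); optional save."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_ssm, ax_d2r) = plt.subplots(
        2, 1, sharex=True, figsize=(9, 5), height_ratios=[2, 1]
    )
    for label, series in ts.ssm.items():
        ax_ssm.plot(ts.time, series, label=label)
    ax_ssm.axhline(400.0, ls="--", c="k", lw=0.8)  # normal-readout threshold
    ax_ssm.set_ylabel("SSM activity (a.u.)")
    ax_ssm.legend(fontsize=7, ncol=3)
    for label, series in ts.d2r.items():
        ax_d2r.plot(ts.time, series, label=label)
    ax_d2r.set_ylabel("putamen D2R (a.u.)")
    ax_d2r.set_xlabel("time (ms)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
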