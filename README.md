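# godiva-aos

An event-level simulator of **acquired apraxia of speech (AOS)** in the
bilateral GODIVA framework of speech motor sequencing, for researchers in
speech motor control and motor speech disorders.

In the intact model, each syllable's speech sound map (SSM) population must
reach the normal-readout threshold *T* = 400 before its motor program is
read out with full feedforward weighting α_ff = 0.85 (feedback control
takes α_fb = 1 − α_ff). A lesion killing 22.25 % of left-SSM neurons
(17.8 % of the bilateral total) keeps every population sub-threshold, so:

* readout happens anyway, with degraded weighting α_ff = 0.85 · s/T at
  initiation activity *s*;
* the initial phone of the syllable is prolonged by
  %Δduration = P_estimate · %Δα_ff with P_estimate = −2.142;
* syllable shifts are re-timed by compensatory mechanisms — a fixed period
  after the shift-preparation trigger (I), a memory trace of a frequent
  short syllable's duration (II), or the utterance-onset latency (III);
* in short syllables the prolongation delays the outgoing trigger; long
  syllables catch up by truncating their final phone.

These rules interact to produce a domino effect: a delayed trigger into a
memory-trace shift squeezes the next syllable's preparation window, so it
initiates at very low activity and is massively lengthened. For
"here is the potato", 'po' roughly doubles (122 → ≈259 ms, +112 %) while
the stressed 'ta' is unchanged — a durational stress-contrast reduction
characteristic of AOS. A companion module re-creates the associated
resting-state ROI functional-connectivity group comparison on synthetic
series (Pearson r → Fisher Z → Welch t → Benjamini–Hochberg FDR).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from godiva_aos import (LesionConfig, build_control_timeline, build_report,
                        default_calibration, load_fixture, simulate_aos)

cal = default_calibration()           # solves the activity-rise constants
u = load_fixture("here_is_the_potato")
control = build_control_timeline(u, cal)
aos = simulate_aos(u, LesionConfig(), cal)   # 22.25 % left-SSM lesion
print(build_report(control, aos).per_syllable.to_string(index=False))
```

prints

```
label  control_duration_ms  aos_duration_ms  lengthening_pct
 here                278.0            278.0              0.0
   is                147.0            147.0              0.0
  the                 96.0             96.0              0.0
   po                122.0            259.2            112.4
   ta                180.0            180.0             -0.0
   to                160.0            160.0              0.0
```

Only the word-initial unstressed 'po' is lengthened (+112 %), because it
was initiated with activity ≈132.5 — 33 % of threshold — after an 11 ms
preparation window; its initial phone /p/ was prolonged by 143.6 %, and the
pairwise variability index of the 'po'–'ta' pair drops from 38.41 to 36.06
(reduced stress contrast). The scripts in `examples/` walk through each
capability: the paired timelines, the weighting algebra, the stress-contrast
report, the rendered activity traces, and the synthetic connectivity
comparison (e.g. `python examples/simulate_timelines.py`).

A thin CLI mirrors the library:

```sh
godiva-aos simulate --mode aos --out run/       # events.csv, syllables.csv
godiva-aos compare --out cmp/                   # report.json, report.csv
godiva-aos traces --mode aos --plot --out tr/   # traces.csv, traces.png
godiva-aos fc analyze --seed 11 --out fc/       # fc_stats.csv
godiva-aos calibrate                            # derived constants
godiva-aos acceptance --json                    # reference checker
```

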