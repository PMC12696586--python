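# Utterance of long syllables only: with any lesion every shift-preparation
# trigger catches up, so all AOS durations equal the control durations.
label: all_long_syllables
syllables:
  - label: di
    control_duration: 240.0
    phones:
      - {label: d, duration: 55.0, position: initial}
      - {label: i, duration: 110.0, position: final}
  - label: no
    control_duration: 210.0
    phones:
      - {label: n, duration: 50.0, position: initial}
      - {label: o, duration: 100.0, position: final}
  - label: saur
    control_duration: 280.0
    phones:
      - {label: s, duration: 70.0, position: initial}
      - {label: aur, duration: 120.0, position: final}
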