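# "here is the potato" — the simulated utterance.
# Control syllable durations: 278 / 147 / 96 / 122 ms for here/is/the/po
# (po = 122 for internal consistency of the printed timeline); ta/to are
# unconstrained defaults (long syllables catch up, so they do not shape the
# comparison quantities).
# Initial-phone durations: /ɪ/ in "is" = 65 ms (half the typical 130 ms for
# this frequent unstressed function word); ð = 50.3 ms and p = 95.5 ms are
# back-derived from the 19 ms and 137 ms trigger delays; h and the two t's
# are free defaults.
label: here_is_the_potato
syllables:
  - label: here
    control_duration: 278.0
    phones:
      - {label: h, duration: 60.0, position: initial}
      - {label: r, duration: 100.0, position: final}
  - label: is
    control_duration: 147.0
    phones:
      - {label: i, duration: 65.0, position: initial}
      - {label: z, duration: 82.0, position: final}
  - label: the
    control_duration: 96.0
    is_short: true
    is_frequent_combo: true
    phones:
      - {label: th, duration: 50.3, position: initial}
      - {label: e, duration: 45.7, position: final}
  - label: po
    control_duration: 122.0
    is_short: true
    phones:
      - {label: p, duration: 95.5, position: initial}
      - {label: o, duration: 26.5, position: final}
  - label: ta
    control_duration: 180.0
    phones:
      - {label: t, duration: 85.0, position: initial}
      - {label: a, duration: 95.0, position: final}
  - label: to
    control_duration: 160.0
    phones:
      - {label: t2, duration: 85.0, position: initial}
      - {label: o2, duration: 75.0, position: final}
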