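# Minimal one-syllable utterance; a CV syllable whose single phone serves as
# both initial and final segment.
label: single_syllable
syllables:
  - label: ba
    control_duration: 200.0
    phones:
      - {label: b, duration: 80.0, position: initial}
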