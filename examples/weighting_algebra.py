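"""The control re-weighting algebra, stand-alone.

Sweeps SSM activity at syllable initiation and prints the feedforward
weighting and the induced initial-phone prolongation.  The two printed
worked points are the simulated 'the' (activity 332 -> alpha_ff 0.70 ->
37.8 %) and 'po' (activity 133 -> alpha_ff 0.28 -> ~143.6 %).
"""

from godiva_aos import (
    LesionConfig,
    compute_alpha_ff,
    lesion_total_fraction,
    prolongation_percent,
)

les = LesionConfig()
print(
    f"lesion: {les.left_lesion_fraction:.2%} of left SSM neurons "
    f"= {lesion_total_fraction(les.left_lesion_fraction, les.left_hemisphere_share):.1%} of all SSM neurons"
)
print(f"{'activity':>8} {'alpha_ff':>9} {'(2 dec)':>8} {'prolongation':>13}")
for s in (400, 390, 358, 332, 200, 133, 50):
    w = compute_alpha_ff(float(s), les)
    pct = prolongation_percent(w, les)
    print(f"{s:8d} {w.alpha_ff:9.4f} {w.alpha_ff_rounded:8.2f} {pct:12.1f} %")
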