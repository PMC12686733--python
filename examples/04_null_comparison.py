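"""Real genome versus shuffled and Markov nulls.

Fits both heavy-tailed models to a repetitive genome, to a uniform base
shuffle of it (composition preserved, structure destroyed) and to an
order-1 Markov imitation, then measures how far the fitted curves
diverge. At k=7 the spectrum is sparse, which is where shuffling hurts most.
"""

import kmerlex as kx

genome = kx.synth_hierarchical_repeat_genome(seed=3)
report = kx.compare_real_vs_null(genome, k=7, seed=3)

for variant, models in report.fits.items():
    zm = models["zipf_mandelbrot"].params
    print(f"{variant:9s} ZM: s={zm.s:6.3f} q={zm.q:10.1f}  "
          f"R^2={models['zipf_mandelbrot'].r_squared:.3f}")
print()
for variant, models in report.divergences.items():
    d = models["zipf_mandelbrot"]
    print(f"real vs {variant:9s}: KS={d.ks:.4f}  JS={d.js:.4f} bits "
          f"(over {d.support_size} shared ranks)")
print()
print("Shuffling removes the repeat hierarchy, so the shuffled fit needs a")
print("larger shift q (artificial smoothing of the head). The order-1 Markov")
print("control destroys the same long-range structure and behaves likewise.")
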