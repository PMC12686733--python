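"""Fitting heavy-tailed rank-frequency models and choosing between them.

Compares plain Zipf, Zipf-Mandelbrot and the truncated power law on the
6-mer spectrum of a repetitive genome, in linear frequency space, and
applies the k-dependent selection rule.
"""

import kmerlex as kx

genome = kx.synth_hierarchical_repeat_genome(seed=2)
k = 6
table = kx.to_rank_frequency(kx.count_canonical_kmers(genome, k))

fits = {
    "zipf": kx.fit_zipf(table),
    "zipf_mandelbrot": kx.fit_zipf_mandelbrot(table),
    "truncated_power_law": kx.fit_truncated_power_law(table),
}
for name, fit in fits.items():
    print(f"{name:20s} R^2={fit.r_squared:7.3f}  AIC={fit.aic:10.1f}  {fit.params}")

choice = kx.select_model(k, fits)
print()
print(f"chosen model: {choice.chosen}")
print(f"reason      : {choice.reason}")
print()
print("Zipf's single 1/r decay cannot bend: its R^2 collapses. The shift q")
print("(Zipf-Mandelbrot) flattens the head; the cutoff lambda (truncated")
print("power law) curtails the tail. For k in 3..6 the lower-AIC model wins;")
print("above k=6 sparse spectra break the truncated power law.")
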