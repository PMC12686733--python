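"""Vocabulary growth and the Heaps/Menzerath pair of exponents.

Scans a genome once, recording distinct versus total canonical k-mers at
each 1% checkpoint, then fits V(n) = K n^beta and the vocabulary-density
relation M(n) = A n^b. For a Heapsian curve b = beta - 1, so delta near 0
means the two accounts of growth agree.
"""

import kmerlex as kx

genome = kx.synth_hierarchical_repeat_genome(seed=1)

for k in (4, 8, 12):
    curve = kx.vocabulary_growth(genome, k)
    heaps = kx.fit_heaps(curve)
    menz = kx.fit_menzerath(curve, heaps)
    print(
        f"k={k:2d}: beta={heaps.beta:6.3f} K={heaps.K:10.2f} "
        f"R^2={heaps.r_squared:.4f}  b={menz.b:7.3f} delta={menz.delta:+.4f}"
    )

print()
print("Small k: the possible vocabulary is tiny, so it is exhausted almost")
print("immediately (beta near 0). Large k: nearly every window is new and")
print("beta approaches 1, the edge of sublinear (Heapsian) growth.")
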