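"""Canonical k-mer spectrum and usage inequality of a repetitive genome.

Builds a small synthetic genome with a hierarchy of repeat families, counts
canonical 5-mers, and summarizes how unequally they are used.
"""

import kmerlex as kx

genome = kx.synth_hierarchical_repeat_genome(seed=0)
spectrum = kx.count_canonical_kmers(genome, k=5)
table = kx.to_rank_frequency(spectrum)
g = kx.gini(kx.lorenz_curve(table))

print(f"genome length        : {genome.total_length} bp (GC {genome.gc_content:.3f})")
print(f"5-mer tokens counted : {spectrum.total_tokens}")
print(f"distinct canonical   : {spectrum.distinct} of {kx.expected_canonical_count(5)} possible")
print(f"top three 5-mers     : {table.kmers[:3]} at frequencies {table.frequencies[:3].round(4)}")
print(f"Gini coefficient     : {g:.3f}")
print()
print("A Gini of 0 would mean every observed 5-mer is used equally; values")
print("toward 1 mean a few words (here, the repeat families) dominate usage.")
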