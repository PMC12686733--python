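# Methods

## Canonical k-mer counting

A k-mer and its reverse complement are one word read off the two strands;
we keep the lexicographically smaller of the pair (bases ordered
A < C < G < T). Sequences are uppercased on input; a width-k window is
counted only if all k bases are unambiguous A/C/G/T — any window touching
an N or another IUPAC ambiguity code contributes nothing. Windows never
span record boundaries, since records are distinct molecules
(chromosomes, contigs, plasmids); all records in a file are included.

Counting packs bases two bits each into int64 word codes, so lexicographic
order on strings equals numeric order on codes and whole genomes are
processed as numpy arrays. This caps k at 31; the package targets k ≤ 15,
and in-memory spectra are intended for desk-scale genomes (the default
modeling window k = 3..7 has at most 8,192 canonical words).

The number of possible canonical k-mers is (4ᵏ + 4^{k/2})/2 for even k —
the 4^{k/2} reverse-complement palindromes are their own partner — and
exactly 4ᵏ/2 for odd k, because an odd-length word would need a
self-complementary middle base to equal its reverse complement, and no DNA
base is self-complementary. Both branches are verified against brute-force
enumeration for k = 1..6 in the test suite. (A published piecewise formula
for the odd branch circulates that evaluates to 36 at k = 3; enumeration
gives 32, which is what this package implements.)

## Rank-frequency tables, Lorenz curves, Gini

Counts are sorted descending — ties broken lexicographically by k-mer so
ranks are deterministic — and normalized to frequencies summing to one.
The Lorenz curve cumulates frequencies sorted ascending, with x-coordinates
i/m; the Gini coefficient is 1 − 2 × (trapezoid area under the curve),
which coincides exactly with the mean-absolute-difference form
Σᵢⱼ|xᵢ−xⱼ|/(2m²μ) on discrete tables (asserted to 1e-12 in tests). Gini is
computed over the *observed* support only: on sparsely sampled spectra
(tokens ≪ possible k-mers) this measures inequality among seen words, and
its monotone increase with k is only expected in the densely sampled
regime.

## Vocabulary growth and the Heaps/Menzerath pair

The growth curve records (n, V) — total and distinct canonical k-mer
tokens — at 100 evenly spaced checkpoints of the token stream (each 1% of
the clean windows). Checkpoints are defined on the window stream rather
than on base positions: the two differ by k − 1, and the token definition
makes V ≤ n exact at every checkpoint. Records are streamed in file order
with no randomization.

Heaps' law V(n) = K·nᵝ and the Menzerath-type density relation
M(n) = V/n = A·nᵇ are both fitted by nonlinear least squares in linear
space (`scipy.optimize.curve_fit`), initialized from the log-log linear
regression and with a few extra exponent starts as a fallback. β is not
clipped at 1, so super-linear breakdown of sublinear growth remains
visible rather than being hidden; the 100 checkpoints enter the fit with
equal weight. Δ = b − (β − 1) is zero to fitting tolerance whenever the
curve is exactly Heapsian (an algebraic identity), so a non-zero Δ flags
multi-regime growth.

## Heavy-tailed rank-frequency models

Three models of normalized frequency versus rank:

* Zipf, f(r) = C/r, with C pinned to the observed rank-1 frequency
  (p = 1 free parameter; a free-C least-squares variant exists behind a
  flag, since pinning versus fitting the scale is a genuine modeling
  choice). As the tables are normalized, C is the top *frequency*, not a
  raw count.
* Zipf–Mandelbrot, f(r) = C/(r + q)ˢ, and the truncated power law,
  f(r) = C·r⁻ᵅ·e^{−λr} (p = 3 each). The textbook normalization constants
  (generalized harmonic number; incomplete-gamma integral) are replaced by
  the free scale C because the data are already normalized.

Fitting is least squares in **linear frequency space**, which is also the
space in which R² is defined; this deliberately weights the high-frequency
head of the spectrum. The optimizer is a bounded trust-region least-squares
run from a fixed multi-start grid (decay exponents {0.3, 1, 3, 10}; shifts
{0.1, 10, 1000}; cutoffs {0, 1e-4, 1e-2}), the scale initialized
consistently with each start from the rank-1 frequency, with analytic
Jacobians. The best sum of squared residuals across starts wins, and the
grid is fixed so identical inputs give identical results.

Numerical bounds: s, α ≤ 60, q ≤ 1e6, λ ≤ 5, C ≤ 1e30. These are not
scientific priors but termination guards: near-flat tables push the
Zipf–Mandelbrot fit along the ridge q → ∞ with C ∝ qˢ (the model tends to
a constant there), which would otherwise never converge; beyond the caps
the models are indistinguishable from their limiting forms on any table
this package produces. A start that exhausts its evaluation budget still
contributes its best iterate, but only a properly converged solution sets
the `converged` flag. Noiseless generate-then-fit recovery is better than
1e-3 relative over a 3×3 grid of true parameters for both 3-parameter
models, and multinomial resamples at 10⁶ draws recover within 5%.

R² = 1 − SSres/SStot may be negative (model worse than the mean line) and
is NaN-flagged when SStot = 0 (degenerate one-row or constant tables).
AIC uses the Gaussian least-squares likelihood — the unique family under
which least squares is maximum likelihood — in the form
n·ln(SSres/n) + 2p, dropping the additive constant shared by all models on
one table so cross-model differences are meaningful; SSres = 0 maps to a
−∞ sentinel. Model choice: for k = 3..6 the lower-AIC of the two
three-parameter models (truncated power law on ties, reflecting its slight
edge in that window); for k > 6 the Zipf–Mandelbrot unless its own R² is
negative, because sparse high-k spectra (flat heads with abrupt absent
tails) systematically break the truncated power law. Negative-R² fits are
flagged and reported, never silently dropped; the pipeline's
`exclude_negative_r2` option reproduces exclusion-style analyses.

Spearman correlations between fit quality and genome covariates (genome
size, GC content) use average-rank ties via `scipy.stats.spearmanr`,
optionally within covariate quartiles — the stratified form exposes
U-shaped relations (e.g. GC versus R²) that a single pooled coefficient
averages away. At least 5 observations per stratum are required; constant
inputs yield NaN.

## Null models and divergences

The uniform shuffle permutes each record's bases independently with a
seeded generator, preserving per-record length and base multiset exactly —
the mononucleotide spectrum is invariant by construction, which the tests
assert. The Markov generator (order 0–2) samples from transitions either
given explicitly or estimated from a source genome's (order+1)-mer counts
over clean windows; unseen contexts fall back to uniform rows. Shuffling
destroys all positional structure while the Markov control preserves
short-range composition, bracketing the real genome from two sides.

Fitted curves are compared on the common support 1..min(m₁, m₂), each
prediction renormalized to a probability vector there (the comparison is
between *predicted* curves; an empirical-vs-empirical variant is available
through the same `ks_distance`/`js_divergence` primitives). KS is the
maximum cumulative gap; JS uses base-2 logarithms so it is bounded by 1
and read in bits. Both are symmetric and zero iff the renormalized curves
coincide.

## Synthetic data

Rank-table fixtures are exact model frequencies or multinomial samples of
them (zero-count ranks dropped and re-ranked, mimicking finite genomes);
the multinomial generator is chi-square-calibrated against its generating
model in the tests before it is used to exercise the fitters. Heaps
fixtures are i.i.d. token streams over a finite vocabulary with
Zipf–Mandelbrot probabilities, so the true growth regime is controlled
independently of the overlap correlations of DNA windows; DNA-level growth
is exercised through the Markov and repeat generators instead.

Two repeat generators emulate repeat-driven heavy tails. The single-unit
mix splices one tandem block into an order-0 background — useful for
top-rank and inequality checks, but its spectrum is a flat spike over a
flat background, not a heavy tail. The hierarchical generator draws
hundreds of short repeat families whose copy numbers follow a power law
(defaults: 800 families, 10 bp units, copy decay 0.8, 15 kb of repeat in a
30 kb background at GC 0.30 — virus-to-small-bacterium scale with roughly
a third repetitive content), producing the smoothly decaying spectra that
multi-scale repeat hierarchies give real genomes. What these fixtures do
not emulate: genic/intergenic compartmentalization, GC-domain mosaicism,
and sequence evolution; conclusions from passing tests transfer to real
genomes only insofar as heavy-tailed spectra arise from repeat hierarchy
and composition bias.

## Known limitations

* On the hierarchical-repeat fixture the shuffled null robustly needs a
  larger Zipf–Mandelbrot shift q than the real genome at k = 7 (artificial
  head smoothing after the repeat hierarchy is destroyed), but the fitted
  truncated-power-law cutoffs of real and shuffled genomes are
  statistically comparable rather than ordered: at desk scale both share
  the same sparse multinomial tail, and under head-weighted linear-space
  fitting that tail, not the repeat structure, sets λ. The corresponding
  acceptance check on the λ ordering is expected to fail and is kept as a
  documented open discrepancy rather than weakened.
* Counting is exact and in-memory: no probabilistic sketches, no
  disk-backed k-mer databases, k ≤ 31 by representation and k ≤ 15 by
  intent.
* Only uniform base shuffling is provided as the permutation null;
  k-let-preserving (composition-of-order-k-preserving) shuffles are a
  possible extension.
* The maximum-likelihood/KS-minimizing approach to discrete power-law
  fitting is intentionally out of scope; the least-squares convention is
  the one implemented, and all R²/AIC statements are relative to it.
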