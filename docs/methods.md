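# Methods

## The measure

For a collection `S` of DNA sequences, `d_k(S)` is the number of distinct
canonical k-mers over all members: every length-k window containing only
A/C/G/T is replaced by the lexicographic minimum of itself and its reverse
complement, and windows never span member boundaries. The
substring-complexity measure is

    δ(S) = max_k d_k(S)/k,      k* = argmax_k d_k(S)/k.

δ is a parameter-free proxy for the amount of distinct sequence in `S`:
for small k the ratio is capped by the 4^k alphabet space; for large k it
is capped by the total window count, which shrinks as k grows; the maximum
sits at the point of diminishing returns between the two. Consequences
used throughout (and tested): δ is invariant to strand, to member order,
and to full-string reversal; it is monotone under appending sequence; and
for collections `A`, `B` it satisfies `max(δ(A), δ(B)) ≤ δ(A∪B) ≤ δ(A) +
δ(B)`, which is exactly what pins the k-independent Jaccard to [0, 1].

Assumption worth stating: δ treats all k-mers alike. Genomes with strong
composition bias (GC skew, repeat families) compress their k-mer space in
ways δ does not model; δ measures distinct substring content, not
population-genetic distance.

## Locating k*

`d_k/k` need not be bitonic in k, so the search looks for a *certified
local maximum*: three consecutive k with
`d_{k-1}/(k-1) < d_k/k ≥ d_{k+1}/(k+1)`. From a starting value (default
`k_init = 14`, configurable) the sweep hill-climbs toward the
larger-ratio neighbor and stops at the first certificate. Tie handling:
an equal ratio on the right does not block certification, while an equal
ratio on the left pulls the climb left — so the left edge of a plateau is
reported (smaller k wins). When both neighbors beat the current ratio
(possible with estimator fluctuations) the climb moves toward the larger
neighbor. If the climb reaches the upper bound (the longest member
length by default) without a certificate, it is an error that names the
boundary rather than a silently wrong answer. `delta_scan` evaluates
every k in a range instead and takes the global maximum, for inputs where
the first local maximum is not trusted.

For unions, the search starts at the maximum of the components' k*s —
cardinalities only grow under union, so the union's maximum essentially
never sits below every component's.

Every per-k structure a stack ever builds is cached on the stack, and a
union stack builds its per-k entry from its components' entries (set
union, or elementwise register maximum). A progressive run therefore
scans each input sequence at most once per queried k, no matter how many
unions touch it.

## Backends

**Exact.** k ≤ 32 packs k-mers 2 bits/base into `uint64` (A=0<C=1<G=2<T=3
preserves lexicographic order, so canonical = numeric min); larger k
falls back to fixed-width byte strings. Sets are sorted unique numpy
arrays; unions are `union1d`. The two representations have identical set
semantics, which the tests check against a naive string-window oracle.

**Sketch.** One HyperLogLog per (input, k): `m = 2^p` registers (default
p = 14, i.e. 16,384 registers and a few kB — keeping relative error near
1.04/√m ≈ 0.8% — configurable in [8, 24]). The packed canonical k-mer is
avalanched with the SplitMix64 finalizer (seeded; long k-mers go through
an 8-byte BLAKE2 digest first); the top p bits pick a register, which
keeps the maximum of leading-zero-count+1 of the remaining 64−p bits.
Unions are elementwise register maxima and are bit-identical to sketching
the concatenated input — the composability that makes progressive unions
and all-pairs analyses cheap.

Cardinality is the maximum-likelihood estimate under the standard Poisson
register model: with per-register rate `x = n/m`, `P(K ≤ j) =
exp(-x/2^j)` up to saturation. The score equation of the register-value
histogram is strictly decreasing in `x`, so it is bracketed by doubling
and solved with Brent's method (relative tolerance 1e-13); empty sketches
return 0 and fully saturated sketches (unreachable at genomic scales)
return infinity. The estimator's relative standard error is ≈ 1.04/√m and
its bias is negligible (measured ≈ 3×10⁻⁴ at p = 14, n = 10⁵ in the
acceptance script); note the *mean absolute* relative error of any
estimator at this design is ≥ √(2/π)·σ ≈ 0.65%, so accuracy claims here
are stated as bias plus spread, not as a sub-σ mean absolute error.

## Growth, Heaps' law, openness

Progressive runs accumulate one genome at a time along each ordering and
record δ (or, in the k-sweep, `d_k`) of the running union, plus the
increment over the previous step. Orderings are uniform random
permutations sampled with replacement (duplicates possible); for 2–7
genomes with enough requested orderings, all permutations are enumerated
instead. A single requested input always yields the identity ordering.

The increment model is Heaps' law, `Δδ_i = K·i^(−α)`, fit to the mean
increments across orderings: step 1 is excluded by default
(`fit_min_step = 2`) because the first "increment" is an entire genome,
not a discovery increment; non-positive increments are dropped from the
log fit and counted in the result. The fit is ordinary least squares on
log Δδ vs log i, refined by nonlinear least squares on the original
scale; at least three usable points are required. Openness: *open* iff
α ≤ 1. Pooled (all-orderings) fitting is available by passing a table's
raw increment rows to `heaps_fit` instead of the means.

The k-sweep records `d_k` growth for every k in a range and fits α(k)
per k. A k whose space saturates within the first genome has no positive
increments and is reported as α = NaN rather than a fabricated fit.

## The synthetic generators

`synthetic_pangenome` emulates exactly one thing: a pangenome with a
known openness exponent. Genome *i* is a lightly mutated copy of a shared
core plus a *fresh* i.i.d. segment of deterministic length
`round(K0·i^(−α0))` — deterministic so the power law is sharp, i.i.d. so
the distinct-k-mer gain tracks segment length almost exactly at
informative k. Defaults: 50 kb core, K0 = 5000 bases, α0 = 0.9
(an open pangenome, in the range observed for real human-assembly
collections), substitution rate 10⁻⁴.

Because the novelty schedule is indexed by *genome*, not by *step*, the
power law is expressed along the canonical ordering (genome 1, 2, …, n):
under a random ordering each genome's fresh segment is novel whenever it
arrives, so expected increments are flat and no α is recoverable by
design. End-to-end α-recovery therefore runs the canonical ordering,
while random orderings are exercised for what they actually guarantee
here — order-invariance of the final δ. The k-sweep's saturation
dynamics, by contrast, are exchangeable, so its α(k) analysis does use
random orderings; reproducing the small-k "closed" regime additionally
requires genuine divergence between genomes (the α(k) example and tests
use a 2% substitution rate, strain-level divergence), since a near-clonal
core saturates tiny-k space within the first genome.

What these generators do *not* emulate: repeat families, indels,
structural variation, sequencing error, GC bias. Passing tests show the
machinery is correct on sequences with known ground truth, not that real
assemblies satisfy a clean power law.

`phylogeny_pangenome` evolves a root genome along a balanced binary tree
with independent per-branch substitution, returning the true Newick
topology so distance-based reconstruction can be scored (neighbor joining
on 1−KIJ recovers the 8-leaf topology exactly in the tests).

## KIJ and distances

`KIJ(A,B) = (δ(A)+δ(B)−δ(A∪B))/δ(A∪B)`; the distance reported is 1−KIJ.
The three δs are computed independently and may settle on different k*s;
all three k*s are kept in the per-pair detail table. With the exact
backend KIJ lies in [0, 1] by the union bounds above; sketch noise can
push it marginally outside, so values are clamped and the raw value
retained. A zero union δ (no k-mer content at all) is an error, not a 0
distance. Matrices are written as square PHYLIP (width-padded labels,
6 decimals) and long-form TSV.

## Caching

Per-input per-k artifacts are cached under a BLAKE2-based content key:
per-file digests, sorted (so listing order is irrelevant), combined with
the canonicalized parameters (k, backend, p, hash seed). Payloads carry
their own checksum; a corrupt or truncated entry triggers a rebuild with
a warning rather than being trusted. Warm and cold caches are required —
and tested — to produce bit-identical results.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen so the full
suite finishes in well under a minute of compute per pillar: oracle
equivalence on 100 collections of 1–5 members and 100–1200 bases per
member; estimator accuracy at p = 14 with 10⁵ true distinct values over
50 trials; α recovery on a 20-genome, ~50 kb/genome pangenome; the α(k)
curve on a 12-genome, ~20 kb/genome divergent pangenome with k ∈ [2, 20]
and 6 orderings. The independent δ oracle scans k upward and stops only
once the window-count bound `W(k)/k` (with `W(k) = Σ max(0, len−k+1)`, a
quantity that upper-bounds `d_k` for any input) falls below the best
ratio seen, which makes the scan provably equivalent to evaluating every
k up to the longest sequence.

Known limitations: multiplicities are ignored (sets, not multisets);
single-threaded; sketch-mode δ inherits estimator noise in k* near ties;
Heaps fits on saturating series are reported as undefined rather than
extrapolated.
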