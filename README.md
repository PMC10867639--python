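# deltasketch

Measuring how much *distinct* sequence a genome collection contains — and
how much each new genome adds — is surprisingly slippery: alignment-based
estimates swing by orders of magnitude with pipeline choices, and k-mer
methods inherit whatever k you picked. `deltasketch` implements a
parameter-free alternative built on the substring-complexity measure

```
δ(S) = max_k  d_k(S) / k
```

where `d_k(S)` is the number of distinct canonical k-mers (each k-mer
identified with its reverse complement) across all sequences of the
collection `S`, and `k*` denotes the maximizing k. δ comes from
compression theory (it lower-bounds measures like the string-attractor
size), needs nothing more than k-mer counting, grows monotonically as
sequence is added, and is invariant to strand and member order.

On top of δ the package provides:

- **Two interchangeable backends.** Exact canonical k-mer counting
  (2-bit-packed sets), or composable HyperLogLog sketches whose unions
  are an elementwise register maximum — so the sketch of a pangenome union
  is obtained without rescanning any sequence. Cardinalities are recovered
  with Ertl's maximum-likelihood estimator (relative error ≈ 1.04/√m for
  m registers).
- **The k\* sweep.** δ is located by an outward hill-climb from a
  configurable starting k (default 14) that certifies a local maximum
  `d_{k-1}/(k-1) < d_k/k ≥ d_{k+1}/(k+1)`; an exhaustive per-k scan is
  available when the certificate is not trusted.
- **Pangenome growth and openness.** Progressive unions along random
  orderings yield δ growth tables; fitting Heaps' law `Δδ_i = K·i^(−α)`
  to the per-step increments classifies the pangenome as *open* (α ≤ 1,
  still accumulating novel sequence) or *closed* (α > 1). A k-sweep mode
  produces the α(k) curve showing how k-specific conclusions drift.
- **k-independent Jaccard (KIJ).** The Jaccard coefficient computed from
  three δs instead of three k-specific cardinalities,
  `KIJ(A,B) = (δ(A)+δ(B)−δ(A∪B))/δ(A∪B)`, with all-pairs `1−KIJ`
  distance matrices in PHYLIP and long TSV form.
- **Content-addressed caching** of per-input sketches/k-mer sets keyed by
  BLAKE2 digests of the input FASTAs plus sketch parameters, so repeated
  and cross-command analyses never resketch an input.
- **Synthetic data generators** (random genomes, mutated pangenomes with
  a controlled Heaps'-law novelty schedule, tree-structured genomes) so
  every feature is testable without downloads.

## Worked example

```python
from deltasketch import delta_exact, delta_sketch, random_genome

genome = random_genome(100_000, seed=1, label="toy")
exact = delta_exact(genome)
approx = delta_sketch(genome, p=14)
print(exact.delta, exact.k_star)    # 9103.9  10
print(approx.delta, approx.k_star)  # 9015.3  10
```

A 100 kb random genome has δ ≈ 9104 achieved at k\* = 10: distinct 10-mers
are the best trade-off between the 4^k space (too small below) and the
~10^5 window count (no gain above). The sketch estimate (16,384 registers,
a few kB) lands within about 1%, the expected HyperLogLog error scale.

Growth and openness (`examples/pangenome_growth.py`): a 20-genome
synthetic pangenome whose genome *i* adds ≈ 5000·i^(−0.9) novel bases
yields

```
Heaps fit: K = 460.0, alpha = 0.881 -> pangenome is open (truth: alpha0 = 0.9)
```

and the α(k) curve (`examples/openness_vs_k.py`) shows the k-dependence
δ avoids: α = 2.15 ("closed") at k = 7 where the k-mer space saturates,
stabilizing near 0.27 ("open") for k ≥ 11, with δ's k\* = 11 inside the
stable region.

Every script in `examples/` is self-contained and prints a short
explanation with its numbers. The same functionality is exposed as a thin
CLI:

```
deltasketch tree a.fa b.fa --out report.json
deltasketch progressive *.fa --norder 20 --out-prefix growth
deltasketch ksweep *.fa --mink 2 --maxk 32 -n 20
deltasketch kij *.fa --out-phylip dist.phy --out-tsv dist.tsv
```

All commands accept `--exact` (exact counting instead of sketching),
`--sketchdir` (the content-addressed cache), `--precision` and `--seed`.

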