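"""Seeded synthetic genomes and pangenomes.

Fixtures for the rest of the package: i.i.d. random genomes, per-base
substitution, and pangenomes with a controlled Heaps'-law novelty
structure.  Genome i of a synthetic pangenome is a lightly mutated copy of
a shared core plus a fresh random segment of length round(K0 * i**(-a0)),
so the ground-truth openness exponent a0 is known exactly and the growth
pipeline's fitted alpha can be checked against it.  Novel segments are
drawn i.i.d. (no repeat structure), so at informative k the distinct-k-mer
gain tracks segment length almost exactly.

Everything is reproducible bit-exactly from (spec, seed).  These are
synthetic stand-ins: no repeat families, indels, or sequencing error.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass

import numpy as np

from .sequences import SequenceCollection

__all__ = ["SyntheticPangenomeSpec", "random_genome", "mutate",
           "synthetic_pangenome", "phylogeny_pangenome"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(length: int, seed: int, gc: float = 0.5,
                  label: str = "genome") -> SequenceCollection:
    """One i.i.d. random genome at the given GC fraction."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    seq = _random_bases(length, rng, gc)
    return SequenceCollection([(label, seq)])


def _random_bases(length: int, rng: np.random.Generator, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return _BASES[idx].tobytes().decode("ascii")


def mutate(seq: str, rate: float, seed: int) -> str:
    """Per-base substitution at the given rate, to a different base."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    acgt = np.isin(arr, _BASES)
    hit &= acgt
    n = int(hit.sum())
    if n:
        code = np.searchsorted(_BASES, arr[hit])  # A,C,G,T are sorted
        shift = rng.integers(1, 4, size=n)
        arr[hit] = _BASES[(code + shift) % 4]
    return arr.tobytes().decode("ascii")


@dataclass
class SyntheticPangenomeSpec:
    """Parameters of a synthetic pangenome with Heaps'-law novelty.

    ``novelty_amplitude`` (K0, bases) and ``novelty_exponent`` (a0) set the
    expected novel sequence contributed by genome i to K0 * i**(-a0);
    ``mutation_rate`` perturbs each genome's copy of the shared core.
    """

    n_genomes: int
    core_length: int = 50_000
    novelty_amplitude: float = 5_000.0
    novelty_exponent: float = 0.9
    mutation_rate: float = 1e-4
    rng_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticPangenomeSpec":
        return cls(**json.loads(text))


def synthetic_pangenome(spec: SyntheticPangenomeSpec
                        ) -> list[SequenceCollection]:
    """Generate the member genomes of a synthetic pangenome.

    Genome i (1-based) = mutated shared core + a fresh i.i.d. segment of
    length round(K0 * i**(-a0)) (deterministic length, so the power law is
    sharp).  Returns one single-member collection per genome.
    """
    if spec.n_genomes < 1:
        raise ValueError("need at least one genome")
    rng = np.random.default_rng(spec.rng_seed)
    core = _random_bases(spec.core_length, rng, 0.5)
    genomes = []
    for i in range(1, spec.n_genomes + 1):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        body = mutate(core, spec.mutation_rate, sub_seed)
        novel_len = int(round(spec.novelty_amplitude * i
                              ** (-spec.novelty_exponent)))
        novel = _random_bases(novel_len, rng, 0.5) if novel_len else ""
        genomes.append(SequenceCollection([(f"g{i:03d}", body + novel)]))
    return genomes


def phylogeny_pangenome(n_leaves: int, genome_length: int,
                        branch_rate: float, seed: int
                        ) -> tuple[list[SequenceCollection], str]:
    """Genomes evolved along a balanced binary tree with known topology.

    The root is an i.i.d. random genome; every branch applies independent
    per-base substitution at ``branch_rate``.  Returns one single-member
    collection per leaf plus the true topology as a Newick string, so
    distance-based tree reconstruction can be scored against ground truth.
    ``n_leaves`` must be a power of two.
    """
    if n_leaves < 2 or n_leaves & (n_leaves - 1):
        raise ValueError("n_leaves must be a power of two >= 2")
    rng = np.random.default_rng(seed)
    counter = itertools.count(1)
    leaves: list[SequenceCollection] = []

    def descend(seq: str, remaining: int) -> str:
        if remaining == 1:
            label = f"L{next(counter):02d}"
            leaves.append(SequenceCollection([(label, seq)]))
            return label
        kids = []
        for _ in range(2):
            child = mutate(seq, branch_rate, int(rng.integers(0, 2**31 - 1)))
            kids.append(descend(child, remaining // 2))
        return f"({kids[0]},{kids[1]})"

    newick = descend(_random_bases(genome_length, rng, 0.5), n_leaves) + ";"
    return leaves, newick
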