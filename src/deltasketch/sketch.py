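"""HyperLogLog cardinality sketching of canonical k-mer sets.

A sketch is an array of m = 2**p small registers.  Each inserted k-mer is
hashed to 64 well-mixed bits; the top p bits select a register and the
register keeps the maximum over insertions of (number of leading zeros of
the remaining 64-p bits) + 1.  Sketches built over two collections compose:
the elementwise register maximum is bit-identical to the sketch of the
concatenated collections, which is what makes progressive pangenome unions
cheap.

Cardinality is recovered with the maximum-likelihood estimator of Ertl
(2017) under the usual Poisson model: with n distinct items and per-register
rate x = n/m, a register value K satisfies P(K <= j) = exp(-x / 2**j) for
0 <= j <= q (q = 64 - p), saturating at q + 1.  The MLE solves the score
equation of the register-value histogram; its relative standard error is
approximately 1.04 / sqrt(m).
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .sequences import SequenceCollection, member_canonical_kmers

__all__ = ["HllSketch", "build_sketch", "union_sketch", "estimate_cardinality"]

_U64 = np.uint64
_MAGIC = b"DSKH"
_VERSION = 1


def _mix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: a 64-bit avalanche permutation."""
    x = (x + _U64(0x9E3779B97F4A7C15))
    x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
    return x ^ (x >> _U64(31))


def _clz64(w: np.ndarray) -> np.ndarray:
    """Leading-zero count of each uint64 (64 for zero)."""
    clz = np.zeros(w.shape, dtype=np.int64)
    v = w.copy()
    for s in (32, 16, 8, 4, 2, 1):
        mask = v < _U64(1) << _U64(64 - s)
        clz[mask] += s
        v[mask] <<= _U64(s)
    clz[w == 0] = 64
    return clz


@dataclass
class HllSketch:
    """HyperLogLog registers for canonical k-mers of one fixed k.

    Two sketches are union-compatible iff ``k``, ``p`` and ``hash_seed``
    all match.
    """

    k: int
    p: int
    hash_seed: int = 0
    registers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 8 <= self.p <= 24:
            raise ValueError(f"precision p={self.p} outside [8, 24]")
        if self.registers is None:
            self.registers = np.zeros(1 << self.p, dtype=np.uint8)
        elif self.registers.size != 1 << self.p:
            raise ValueError("register array does not match precision")

    # -- construction -----------------------------------------------------

    @property
    def m(self) -> int:
        return 1 << self.p

    @property
    def q(self) -> int:
        return 64 - self.p

    def _seed_mix(self) -> np.uint64:
        return _mix64(np.array([self.hash_seed], dtype=_U64))[0]

    def add_packed(self, kmers: np.ndarray) -> None:
        """Insert 2-bit-packed canonical k-mers (uint64 array)."""
        if kmers.size == 0:
            return
        h = _mix64(kmers.astype(_U64) ^ self._seed_mix())
        idx = (h >> _U64(self.q)).astype(np.int64)
        w = h << _U64(self.p)  # remaining 64-p bits, left-aligned
        rho = np.minimum(_clz64(w) + 1, self.q + 1).astype(np.uint8)
        np.maximum.at(self.registers, idx, rho)

    def add_bytes(self, kmers: np.ndarray) -> None:
        """Insert long k-mers (byte-string array) via an 8-byte BLAKE2 digest."""
        if kmers.size == 0:
            return
        seed = self.hash_seed.to_bytes(8, "little", signed=False)
        vals = np.fromiter(
            (int.from_bytes(hashlib.blake2b(bytes(m), digest_size=8,
                                            salt=seed).digest(), "little")
             for m in kmers),
            dtype=_U64, count=kmers.size)
        h = _mix64(vals)
        idx = (h >> _U64(self.q)).astype(np.int64)
        rho = np.minimum(_clz64(h << _U64(self.p)) + 1, self.q + 1)
        np.maximum.at(self.registers, idx, rho.astype(np.uint8))

    def add_collection(self, collection: SequenceCollection) -> None:
        for _, seq in collection.members:
            kmers = member_canonical_kmers(seq, self.k)
            if kmers.dtype == _U64:
                self.add_packed(kmers)
            else:
                self.add_bytes(kmers)

    # -- algebra ----------------------------------------------------------

    def compatible(self, other: "HllSketch") -> bool:
        return (self.k, self.p, self.hash_seed) == (other.k, other.p,
                                                    other.hash_seed)

    def union(self, other: "HllSketch") -> "HllSketch":
        if not self.compatible(other):
            raise ValueError(
                "sketches are not union-compatible: "
                f"(k={self.k},p={self.p},seed={self.hash_seed}) vs "
                f"(k={other.k},p={other.p},seed={other.hash_seed})")
        return HllSketch(self.k, self.p, self.hash_seed,
                         np.maximum(self.registers, other.registers))

    def cardinality(self) -> float:
        return estimate_cardinality(self)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, HllSketch) and self.compatible(other)
                and np.array_equal(self.registers, other.registers))

    # -- serialization ----------------------------------------------------

    def to_bytes(self) -> bytes:
        head = _MAGIC + struct.pack("<BBBq", _VERSION, self.k if self.k < 256
                                    else 255, self.p, self.hash_seed)
        head += struct.pack("<I", self.k)
        return head + self.registers.tobytes()

    @classmethod
    def from_bytes(cls, data: bytes) -> "HllSketch":
        if data[:4] != _MAGIC:
            raise ValueError("not a sketch file (bad magic)")
        _ver, _k8, p, seed = struct.unpack("<BBBq", data[4:15])
        (k,) = struct.unpack("<I", data[15:19])
        regs = np.frombuffer(data[19:], dtype=np.uint8).copy()
        return cls(k, p, seed, regs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.write_bytes(self.to_bytes())
        sidecar = {"format": "deltasketch-hll", "version": _VERSION,
                   "k": self.k, "p": self.p, "hash_seed": self.hash_seed,
                   "registers": self.m}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "HllSketch":
        return cls.from_bytes(Path(path).read_bytes())


def build_sketch(collection: SequenceCollection, k: int, p: int = 14,
                 hash_seed: int = 0) -> HllSketch:
    """Sketch the distinct canonical k-mers of a collection."""
    s = HllSketch(k, p, hash_seed)
    s.add_collection(collection)
    return s


def union_sketch(a: HllSketch, b: HllSketch) -> HllSketch:
    """Elementwise register maximum; the sketch of the union of the inputs."""
    return a.union(b)


def estimate_cardinality(s: HllSketch) -> float:
    """Maximum-likelihood cardinality estimate from the register histogram.

    Solves the score equation of the Poisson register model with Brent's
    method; returns 0 for the empty sketch and ``inf`` if every register
    is saturated (never reached at genomic scales).
    """
    q = s.q
    m = s.m
    counts = np.bincount(s.registers, minlength=q + 2)
    if counts[0] == m:
        return 0.0
    if counts[q + 1] == m:
        return float("inf")

    mid = np.arange(1, q + 1)
    mid = mid[counts[1:q + 1] > 0]
    a_mid = np.power(2.0, -mid.astype(float))
    c_mid = counts[mid]
    c0 = float(counts[0])
    csat = float(counts[q + 1])
    c_tail = 2.0 ** (-q)

    def score(x: float) -> float:
        # d/dx of the log-likelihood at per-register rate x
        val = -c0
        if c_mid.size:
            ax = a_mid * x
            val += float(np.sum(c_mid * a_mid * (1.0 / np.expm1(ax) - 1.0)))
        if csat:
            val += csat * c_tail / np.expm1(c_tail * x)
        return val

    # score is strictly decreasing; bracket the root then refine
    lo, hi = 1e-12, 1.0
    while score(hi) > 0:
        lo = hi
        hi *= 4.0
        if hi > 1e18:
            return float("inf")
    x = brentq(score, lo, hi, rtol=1e-13, maxiter=200)
    return m * x
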