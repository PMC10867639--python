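"""DNA sequence handling and exact canonical k-mer counting.

A :class:`SequenceCollection` is the basic unit of input: an ordered list of
named DNA sequences (one genome, one haplotype assembly, or a whole pangenome
member set).  All downstream machinery — the substring-complexity measure
delta, HyperLogLog sketching, growth curves — reduces to counting *distinct
canonical k-mers* of such collections, which this module does exactly.

Canonicalization means each k-mer is identified with its reverse complement
and represented by the lexicographically smaller of the two, so counts are
strand-independent.  k-mers are packed 2 bits per base into 64-bit integers
for k <= 32 (A=0 < C=1 < G=2 < T=3, which preserves lexicographic order);
longer k-mers fall back to fixed-width byte strings.  Both representations
have identical set semantics.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SequenceCollection",
    "KmerSet",
    "reverse_complement",
    "canonical_kmer",
    "distinct_kmers",
    "exact_cardinality",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# byte -> 2-bit code; 255 marks anything that is not A/C/G/T
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i

_NORMALIZE_LUT = np.full(256, ord("N"), dtype=np.uint8)
for _b in b"ACGTN":
    _NORMALIZE_LUT[_b] = _b
    _NORMALIZE_LUT[ord(chr(_b).lower())] = _b


def _normalize(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character to N."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _NORMALIZE_LUT[raw].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement of the reversed sequence.

    Involutive: ``reverse_complement(reverse_complement(s)) == s``.
    Raises ``ValueError`` on any base outside ACGT.
    """
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"ambiguous base in sequence: {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class SequenceCollection:
    """Named DNA sequences forming one input (or one pangenome member set).

    Invariants enforced at construction: sequences are uppercase over
    {A,C,G,T,N}; labels are unique; total length is positive.
    """

    members: list[tuple[str, str]]
    source_paths: list[str] = field(default_factory=lambda: ["synthetic"])

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.members]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in collection")
        self.members = [(lab, _normalize(seq)) for lab, seq in self.members]
        if self.total_length == 0:
            raise ValueError("collection has no sequence")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.members]

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.members)

    @property
    def max_member_length(self) -> int:
        return max(len(s) for _, s in self.members)

    def __len__(self) -> int:
        return len(self.members)

    @staticmethod
    def combine(collections: Sequence["SequenceCollection"],
                source: str | None = None) -> "SequenceCollection":
        """Concatenate collections into one (labels deduplicated by suffix)."""
        members: list[tuple[str, str]] = []
        seen: dict[str, int] = {}
        paths: list[str] = []
        for coll in collections:
            paths.extend(coll.source_paths)
            for lab, seq in coll.members:
                n = seen.get(lab, 0)
                seen[lab] = n + 1
                members.append((lab if n == 0 else f"{lab}#{n + 1}", seq))
        return SequenceCollection(members, [source] if source else paths)


@dataclass
class KmerSet:
    """Distinct canonical k-mers of a collection, as a sorted unique array.

    ``members`` is ``uint64`` (2-bit packed) for k <= 32 and a fixed-width
    byte-string array for larger k; set operations behave identically.
    """

    k: int
    members: np.ndarray

    @property
    def cardinality(self) -> int:
        return int(self.members.size)

    def union(self, other: "KmerSet") -> "KmerSet":
        if other.k != self.k:
            raise ValueError(f"cannot union k={self.k} with k={other.k}")
        return KmerSet(self.k, np.union1d(self.members, other.members))

    def decode(self) -> list[str]:
        """k-mers as strings (diagnostic; small sets only)."""
        if self.members.dtype == np.uint64:
            out = []
            for v in self.members:
                v = int(v)
                out.append("".join("ACGT"[(v >> (2 * (self.k - 1 - j))) & 3]
                                   for j in range(self.k)))
            return out
        return [m.decode("ascii") for m in self.members]


def _packed_canonical(seq: str, k: int) -> np.ndarray:
    """Canonical k-mers of one string as packed uint64, k <= 32.

    Windows containing any non-ACGT base contribute nothing.
    """
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    w = n - k + 1
    if w <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = (codes == 255).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    ok = (cs[k:] - cs[:-k]) == 0
    if not ok.any():
        return np.empty(0, dtype=np.uint64)
    c64 = (codes & 3).astype(np.uint64)
    two = np.uint64(2)
    fwd = np.zeros(w, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << two) | c64[j:j + w]
    # reverse complement of window i == forward k-mer i' of the
    # complemented, reversed code array, read back-to-front
    rc64 = (np.uint64(3) - c64)[::-1]
    rev = np.zeros(w, dtype=np.uint64)
    for j in range(k):
        rev = (rev << two) | rc64[j:j + w]
    rev = rev[::-1]
    return np.minimum(fwd, rev)[ok]


def _string_canonical(seq: str, k: int) -> np.ndarray:
    """Canonical k-mers for k > 32, as a fixed-width byte-string array."""
    out: set[bytes] = set()
    for stretch in _acgt_stretches(seq):
        if len(stretch) < k:
            continue
        b = stretch.encode("ascii")
        rb = stretch.translate(_COMPLEMENT)[::-1].encode("ascii")
        L = len(b)
        for i in range(L - k + 1):
            f = b[i:i + k]
            r = rb[L - i - k:L - i]
            out.add(f if f <= r else r)
    if not out:
        return np.empty(0, dtype=f"S{k}")
    return np.sort(np.array(sorted(out), dtype=f"S{k}"))


def _acgt_stretches(seq: str) -> Iterable[str]:
    """Maximal runs of unambiguous bases (k-mers never span an N)."""
    start = None
    for i, c in enumerate(seq):
        if c in "ACGT":
            if start is None:
                start = i
        elif start is not None:
            yield seq[start:i]
            start = None
    if start is not None:
        yield seq[start:]


def member_canonical_kmers(seq: str, k: int) -> np.ndarray:
    """All canonical k-mers of one sequence (with repeats, k <= 32 packed)."""
    if k <= 32:
        return _packed_canonical(seq, k)
    return _string_canonical(seq, k)


def distinct_kmers(collection: SequenceCollection, k: int) -> KmerSet:
    """Distinct canonical k-mers over all members of a collection.

    k-mers never span member (record) boundaries.  Degenerate inputs (k
    longer than every member) yield an empty set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    parts = [member_canonical_kmers(seq, k) for _, seq in collection.members]
    parts = [p for p in parts if p.size]
    if not parts:
        dtype = np.uint64 if k <= 32 else f"S{k}"
        return KmerSet(k, np.empty(0, dtype=dtype))
    return KmerSet(k, np.unique(np.concatenate(parts)))


def exact_cardinality(collection: SequenceCollection, k: int) -> int:
    """Number of distinct canonical k-mers, d_k, of a collection."""
    return distinct_kmers(collection, k).cardinality


def read_fasta(path: str | Path, label: str | None = None) -> SequenceCollection:
    """Read one FASTA (optionally gzipped) into a SequenceCollection.

    Record IDs (text up to the first whitespace) become member labels.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    members: list[tuple[str, str]] = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            members.append((rec.id, str(rec.seq)))
    if not members:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceCollection(members, [str(path)])


def write_fasta(collection: SequenceCollection, path: str | Path,
                width: int = 70) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for lab, seq in collection.members:
            fh.write(f">{lab}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
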