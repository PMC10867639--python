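"""Shared fixtures and independent oracles.

The oracles here are deliberately naive, string-based implementations —
no 2-bit packing, no sketches — so that the package's optimized paths are
checked against an independent route.
"""

from __future__ import annotations

import numpy as np
import pytest

from deltasketch import SequenceCollection

_COMP = str.maketrans("ACGT", "TGCA")


def naive_canonical_set(collection: SequenceCollection, k: int) -> set:
    """String-based canonical k-mer set: enumerate every window."""
    out = set()
    for _, seq in collection.members:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if any(c not in "ACGT" for c in w):
                continue
            rc = w.translate(_COMP)[::-1]
            out.add(min(w, rc))
    return out


def naive_cardinality(collection: SequenceCollection, k: int) -> int:
    return len(naive_canonical_set(collection, k))


def exhaustive_delta(collection: SequenceCollection) -> tuple[float, int]:
    """Exact max_k d_k/k over every k in [1, max member length].

    Evaluates d_k/k for increasing k with the naive counter.  d_k can
    never exceed the total window count W(k) = sum(max(0, len - k + 1)),
    which is non-increasing in k, so once W(k)/k drops to or below the
    best ratio seen, no larger k can win and the scan covers the full
    range by that bound.
    """
    lengths = [len(s) for _, s in collection.members]
    kmax = max(lengths)
    best, best_k = 0.0, 0
    for k in range(1, kmax + 1):
        window_bound = sum(max(0, L - k + 1) for L in lengths)
        if window_bound / k <= best:
            break
        r = naive_cardinality(collection, k) / k
        if r > best:
            best, best_k = r, k
    return best, best_k


def random_collection(rng: np.random.Generator, n_members: int,
                      min_len: int, max_len: int) -> SequenceCollection:
    members = []
    for i in range(n_members):
        L = int(rng.integers(min_len, max_len + 1))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
        members.append((f"m{i}", seq))
    return SequenceCollection(members)


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture
def small_genomes(rng):
    """Four unrelated 2 kb random genomes."""
    return [random_collection(rng, 1, 2000, 2000) for _ in range(4)]
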