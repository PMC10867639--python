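"""The delta substring-complexity measure and its k* sweep.

delta(S) = max_k d_k(S) / k, where d_k(S) is the number of distinct
canonical k-mers across the members of a collection S.  The maximizing k is
written k*.  d_k/k grows roughly exponentially while k is small enough that
most arrangements of the alphabet occur, then falls once few new distinct
k-mers are gained per unit k; the maximum marks the point of diminishing
returns.  The curve is not guaranteed to be bitonic, so the search looks
for a certified local maximum:

    d_{k-1}/(k-1)  <  d_k/k  >  d_{k+1}/(k+1)

starting from a configurable initial k (default 14) and hill-climbing
outward.  Ties toward larger k are treated as non-increasing, so the left
edge of a plateau is accepted (smaller k preferred).

Cardinalities come from either backend: ``exact`` (sorted distinct k-mer
arrays) or ``sketch`` (HyperLogLog estimates).  A :class:`SketchStack`
lazily materializes and caches the per-k structure for one input or for a
union of inputs; unions of stacks reuse their components' per-k entries, so
progressive pangenome unions never re-scan the underlying sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .sequences import KmerSet, SequenceCollection, distinct_kmers
from .sketch import HllSketch

__all__ = [
    "DeltaResult",
    "SketchStack",
    "SweepError",
    "sweep_kstar",
    "delta_exact",
    "delta_sketch",
    "delta_scan",
    "delta_union",
    "union_stack",
]

DEFAULT_K_INIT = 14


class SweepError(RuntimeError):
    """No certified local maximum of d_k/k inside the allowed k range."""


@dataclass
class DeltaResult:
    """delta, the maximizing k*, and every per-k cardinality examined."""

    delta: float
    k_star: int
    cardinality_at_k: dict[int, float]
    backend: str

    def to_dict(self) -> dict:
        return {
            "delta": self.delta,
            "k_star": self.k_star,
            "backend": self.backend,
            "cardinality_at_k": {str(k): v for k, v
                                 in sorted(self.cardinality_at_k.items())},
        }


def sweep_kstar(card_fn: Callable[[int], float] | Mapping[int, float],
                k_init: int, k_max_bound: int,
                evaluated: dict[int, float] | None = None,
                ) -> tuple[int, float]:
    """Locate a certified local maximum of d_k/k by outward hill-climbing.

    ``card_fn`` maps k to a (possibly estimated) cardinality; a plain
    mapping is accepted too.  The climb starts at ``k_init`` (clamped to
    [1, k_max_bound]) and moves toward the larger-ratio neighbor until the
    local-max certificate holds; equal-ratio neighbors to the right do not
    block certification, while an equal ratio on the left pulls the climb
    left (plateau left edge wins).  Every evaluated cardinality is recorded
    in ``evaluated`` when given.

    Raises :class:`SweepError` if the climb hits the boundary without a
    certificate.
    """
    if isinstance(card_fn, Mapping):
        mapping = card_fn
        card_fn = lambda k: mapping[k]  # noqa: E731
    cache: dict[int, float] = evaluated if evaluated is not None else {}

    def ratio(k: int) -> float:
        if k < 1:
            return -np.inf
        if k not in cache:
            cache[k] = float(card_fn(k))
        return cache[k] / k

    k = min(max(k_init, 1), k_max_bound)
    for _ in range(2 * k_max_bound + 4):
        r0 = ratio(k)
        rl = ratio(k - 1)
        if k == k_max_bound:
            # cannot certify at the boundary; back off if the curve still
            # rises to the left, otherwise report failure
            if rl >= r0:
                k -= 1
                continue
            raise SweepError(
                f"no local maximum of d_k/k within [1, {k_max_bound}]"
                " (certificate would need k beyond the upper boundary)")
        rr = ratio(k + 1)
        if rl < r0 and rr <= r0:
            return k, r0
        if rr > r0 and rr >= rl:
            k += 1
        elif rl >= r0:
            k -= 1
        else:  # rl > r0 but left neighbor smaller than right: go right
            k += 1
    raise SweepError("sweep failed to terminate")  # pragma: no cover


class SketchStack:
    """Per-k cardinality structure (exact sets or sketches) for one input.

    Entries are built lazily as the sweep queries them and cached, so
    repeated sweeps — and sweeps over unions that share this stack as a
    component — are incremental.
    """

    def __init__(self, collection: SequenceCollection | None, *,
                 backend: str = "sketch", p: int = 14, hash_seed: int = 0,
                 label: str | None = None,
                 components: list["SketchStack"] | None = None,
                 k_max_bound: int | None = None,
                 content_key: str | None = None):
        if backend not in ("exact", "sketch"):
            raise ValueError(f"unknown backend {backend!r}")
        if (collection is None) == (components is None):
            raise ValueError("exactly one of collection/components required")
        self.collection = collection
        self.components = components
        self.backend = backend
        self.p = p
        self.hash_seed = hash_seed
        self.content_key = content_key
        if components is not None:
            for c in components:
                if (c.backend, c.p, c.hash_seed) != (backend, p, hash_seed):
                    raise ValueError("union components are not compatible")
            self.k_max_bound = max(c.k_max_bound for c in components)
            label = label or "|".join(c.label for c in components)
        else:
            self.k_max_bound = (k_max_bound if k_max_bound is not None
                                else collection.max_member_length)
        self.label = label or "collection"
        self._per_k: dict[int, KmerSet | HllSketch] = {}
        self._delta: DeltaResult | None = None

    # -- lazy per-k structures -------------------------------------------

    def get(self, k: int) -> KmerSet | HllSketch:
        if k not in self._per_k:
            self._per_k[k] = self._build(k)
        return self._per_k[k]

    def _build(self, k: int) -> KmerSet | HllSketch:
        if self.components is not None:
            parts = [c.get(k) for c in self.components]
            out = parts[0]
            for nxt in parts[1:]:
                out = out.union(nxt)
            return out
        if self.backend == "exact":
            return distinct_kmers(self.collection, k)
        s = HllSketch(k, self.p, self.hash_seed)
        s.add_collection(self.collection)
        return s

    def card(self, k: int) -> float:
        entry = self.get(k)
        if isinstance(entry, KmerSet):
            return float(entry.cardinality)
        return entry.cardinality()

    @property
    def k_range_examined(self) -> list[int]:
        return sorted(self._per_k)

    # -- delta ------------------------------------------------------------

    def delta(self, k_init: int = DEFAULT_K_INIT) -> DeltaResult:
        if self._delta is None:
            evaluated: dict[int, float] = {}
            k_star, d = sweep_kstar(self.card, k_init, self.k_max_bound,
                                    evaluated)
            if d <= 0:
                raise SweepError(
                    f"input {self.label!r} has no k-mer content "
                    "(delta would be 0)")
            self._delta = DeltaResult(d, k_star, evaluated, self.backend)
        return self._delta


def union_stack(stacks: list[SketchStack], label: str | None = None
                ) -> SketchStack:
    """A stack whose per-k entries are unions of the components' entries."""
    if not stacks:
        raise ValueError("need at least one stack")
    if len(stacks) == 1:
        return stacks[0]
    first = stacks[0]
    return SketchStack(None, backend=first.backend, p=first.p,
                       hash_seed=first.hash_seed, components=list(stacks),
                       label=label)


def delta_exact(collection: SequenceCollection,
                k_init: int = DEFAULT_K_INIT) -> DeltaResult:
    """delta via exact distinct-k-mer counting."""
    return SketchStack(collection, backend="exact").delta(k_init)


def delta_sketch(stack_or_collection: SketchStack | SequenceCollection,
                 k_init: int = DEFAULT_K_INIT, *, p: int = 14,
                 hash_seed: int = 0) -> DeltaResult:
    """delta via HyperLogLog cardinality estimates."""
    if isinstance(stack_or_collection, SequenceCollection):
        stack = SketchStack(stack_or_collection, backend="sketch", p=p,
                            hash_seed=hash_seed)
    else:
        stack = stack_or_collection
    return stack.delta(k_init)


def delta_scan(stack: SketchStack, mink: int = 1,
               maxk: int | None = None) -> DeltaResult:
    """delta by evaluating every k in [mink, maxk] (no early certificate).

    The outward sweep accepts the first certified local maximum, which on
    a non-bitonic ratio curve need not be global; this exhaustive variant
    takes the global maximum over the scanned range (smallest k on ties).
    """
    if maxk is None:
        maxk = stack.k_max_bound
    if not 1 <= mink <= maxk:
        raise ValueError("need 1 <= mink <= maxk")
    cards = {k: stack.card(k) for k in range(mink, maxk + 1)}
    k_star = max(cards, key=lambda k: (cards[k] / k, -k))
    d = cards[k_star] / k_star
    if d <= 0:
        raise SweepError(f"input {stack.label!r} has no k-mer content")
    return DeltaResult(d, k_star, {k: float(v) for k, v in cards.items()},
                       stack.backend)


def delta_union(stacks: list[SketchStack], k_init: int | None = None
                ) -> DeltaResult:
    """delta of the union of inputs.

    The union's k* search starts at the maximum of the components'
    previously computed k*s (computing them first if needed), which is
    where the union's maximum is overwhelmingly likely to sit.
    """
    u = union_stack(stacks)
    if u is stacks[0]:
        return u.delta(k_init if k_init is not None else DEFAULT_K_INIT)
    if k_init is None:
        k_init = max(s.delta().k_star for s in stacks)
    return u.delta(k_init)
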