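"""k-specific and k-independent Jaccard similarities and distance matrices.

The Jaccard coefficient of two k-mer sets follows from three cardinalities
by inclusion-exclusion:

    J_k(A, B) = (d_k(A) + d_k(B) - d_k(A u B)) / d_k(A u B)

The k-independent Jaccard (KIJ) replaces each d_k with delta, removing the
k choice entirely:

    KIJ(A, B) = (delta(A) + delta(B) - delta(A u B)) / delta(A u B)

Each of the three deltas may settle on its own k*.  Superset monotonicity
of delta makes the denominator at least each marginal, and subadditivity
makes the numerator non-negative, so KIJ lies in [0, 1] up to estimator
noise; sketch-backend values are clamped, with the raw value retained in
the per-pair detail table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .delta import DeltaResult, SketchStack, union_stack

__all__ = ["DistanceMatrix", "jaccard_k", "kij", "pairwise_kij",
           "pairwise_jaccard_sweep"]


@dataclass
class DistanceMatrix:
    """Symmetric all-pairs distances with labels.

    ``details`` carries the per-pair similarities and, for KIJ, the three
    k*s and the raw (unclamped) value behind every entry.
    """

    labels: list[str]
    values: np.ndarray
    metric: str
    details: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_phylip(self) -> str:
        """Square PHYLIP distance-matrix text (width-padded labels)."""
        width = max(10, max(len(l) for l in self.labels) + 2)
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            lines.append(lab.ljust(width)
                         + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"

    def to_long_tsv(self) -> str:
        rows = ["a\tb\tdistance"]
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(f"{self.labels[i]}\t{self.labels[j]}\t"
                            f"{self.values[i, j]:.6f}")
        return "\n".join(rows) + "\n"


def _jaccard_from_cards(ca: float, cb: float, cu: float,
                        clamp: bool = True) -> float:
    if cu <= 0:
        raise ValueError("union cardinality is 0; Jaccard undefined")
    j = (ca + cb - cu) / cu
    return min(1.0, max(0.0, j)) if clamp else j


def jaccard_k(a: SketchStack, b: SketchStack, union: SketchStack,
              k: int) -> float:
    """J_k from the three per-k cardinalities (clamped to [0, 1])."""
    return _jaccard_from_cards(a.card(k), b.card(k), union.card(k))


def kij(delta_a: DeltaResult, delta_b: DeltaResult,
        delta_union: DeltaResult, clamp: bool = True) -> float:
    """k-independent Jaccard from three delta results."""
    if delta_union.delta <= 0:
        raise ValueError("delta of the union is 0; KIJ undefined")
    j = (delta_a.delta + delta_b.delta - delta_union.delta) / delta_union.delta
    return min(1.0, max(0.0, j)) if clamp else j


def pairwise_kij(stacks: list[SketchStack],
                 k_init: int | None = None) -> DistanceMatrix:
    """All-pairs 1 - KIJ distance matrix.

    Marginal deltas are computed once per input; each pair's union delta
    search starts at the larger of the pair's k*s.  The detail table
    records, per pair, all three deltas and k*s plus the raw KIJ before
    clamping.
    """
    if len(stacks) < 2:
        raise ValueError("need at least two inputs")
    deltas = [s.delta() if k_init is None else s.delta(k_init)
              for s in stacks]
    n = len(stacks)
    mat = np.zeros((n, n))
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            du = union_stack([stacks[i], stacks[j]]).delta(
                max(deltas[i].k_star, deltas[j].k_star))
            raw = kij(deltas[i], deltas[j], du, clamp=False)
            val = min(1.0, max(0.0, raw))
            mat[i, j] = mat[j, i] = 1.0 - val
            rows.append((stacks[i].label, stacks[j].label,
                         deltas[i].delta, deltas[j].delta, du.delta,
                         deltas[i].k_star, deltas[j].k_star, du.k_star,
                         val, raw))
    details = pd.DataFrame(rows, columns=[
        "a", "b", "delta_a", "delta_b", "delta_union",
        "kstar_a", "kstar_b", "kstar_union", "kij", "kij_raw"])
    return DistanceMatrix([s.label for s in stacks], mat, "1-KIJ", details)


def pairwise_jaccard_sweep(stacks: list[SketchStack], mink: int,
                           maxk: int) -> dict[int, DistanceMatrix]:
    """Per-k matrices of 1 - J_k for k in [mink, maxk]."""
    if not 1 <= mink <= maxk:
        raise ValueError("need 1 <= mink <= maxk")
    if len(stacks) < 2:
        raise ValueError("need at least two inputs")
    n = len(stacks)
    out: dict[int, DistanceMatrix] = {}
    for k in range(mink, maxk + 1):
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                u = union_stack([stacks[i], stacks[j]])
                jk = jaccard_k(stacks[i], stacks[j], u, k)
                mat[i, j] = mat[j, i] = 1.0 - jk
        out[k] = DistanceMatrix([s.label for s in stacks], mat,
                                f"1-Jk({k})")
    return out
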