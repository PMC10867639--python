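"""Pangenome growth curves, Heaps'-law fitting, and openness.

A collection of genomes is accumulated one member at a time along random
orderings; delta (or, in the per-k sweep variant, the distinct-k-mer count
d_k) of the cumulative union is recorded at every step.  Averaging over
orderings gives the mean growth curve, an estimate of delta over all
size-i subsets.  The per-step increment is modeled with Heaps' law,

    increment_i = K * i**(-alpha),

and the fitted alpha classifies the pangenome as open (alpha <= 1: still
accumulating novel sequence) or closed (alpha > 1: saturating).  Fitting
delta increments gives a k-free openness statistic; fitting d_k increments
across a range of k (the k-sweep) shows how the conclusion depends on k —
tiny k saturates the 4**k space quickly and looks closed, informative k
stabilizes below 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .delta import DEFAULT_K_INIT, SketchStack, union_stack

__all__ = [
    "GrowthTable",
    "HeapsFit",
    "random_orderings",
    "progressive_deltas",
    "mean_growth",
    "mean_increments",
    "heaps_fit",
    "cardinality_growth_ksweep",
    "alpha_vs_k",
]


@dataclass
class GrowthTable:
    """Per-ordering, per-step growth records.

    ``records`` has columns ``ordering, step, added, delta,
    delta_increment`` where ``delta`` holds the measured quantity (delta
    itself, or d_k in a k-sweep) of the cumulative union after the step and
    the increment is relative to the previous step (step 0 counts as 0).
    """

    records: pd.DataFrame
    n_orderings: int
    rng_seed: int
    quantity: str = "delta"

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class HeapsFit:
    """Fitted Heaps'-law increment model K * i**(-alpha)."""

    K: float
    alpha: float
    fit_range: tuple[int, int]
    residual: float
    n_dropped: int = 0

    @property
    def openness(self) -> str:
        return "open" if self.alpha <= 1.0 else "closed"

    def to_dict(self) -> dict:
        return {"K": self.K, "alpha": self.alpha,
                "fit_range": list(self.fit_range), "residual": self.residual,
                "n_dropped": self.n_dropped, "openness": self.openness}


def random_orderings(n_items: int, n_orders: int, seed: int
                     ) -> list[tuple[int, ...]]:
    """Random permutations of range(n_items), sampled with replacement.

    Reproducible for a fixed seed.  When the collection is small enough
    (n_items <= 7) and at least n_items! orderings are requested, every
    permutation is enumerated exactly once instead.
    """
    if n_items < 1 or n_orders < 1:
        raise ValueError("n_items and n_orders must be >= 1")
    if n_items == 1:
        return [(0,)] * n_orders
    if n_items <= 7 and n_orders >= math.factorial(n_items):
        return list(itertools.permutations(range(n_items)))
    rng = np.random.default_rng(seed)
    return [tuple(int(x) for x in rng.permutation(n_items))
            for _ in range(n_orders)]


def progressive_deltas(stacks: list[SketchStack],
                       orderings: list[tuple[int, ...]],
                       k_init: int = DEFAULT_K_INIT,
                       rng_seed: int = 0) -> GrowthTable:
    """delta of progressively larger unions along each ordering.

    Step i of an ordering adds one more input to the running union and
    records delta of the new union.  Per-input per-k structures are cached
    on the stacks, and each step's union reuses the previous step's, so a
    full run scans every input sequence at most once per queried k.  The
    union k* search at each step starts from the largest k* seen so far.
    """
    rows = []
    for oid, order in enumerate(orderings):
        running: SketchStack | None = None
        prev_delta = 0.0
        k_start = k_init
        for step, idx in enumerate(order, start=1):
            nxt = stacks[idx]
            running = nxt if running is None else union_stack([running, nxt])
            res = running.delta(k_start)
            k_start = max(k_start, res.k_star)
            rows.append((oid, step, nxt.label, res.delta,
                         res.delta - prev_delta))
            prev_delta = res.delta
    df = pd.DataFrame(rows, columns=["ordering", "step", "added", "delta",
                                     "delta_increment"])
    return GrowthTable(df, n_orderings=len(orderings), rng_seed=rng_seed)


def mean_growth(table: GrowthTable) -> list[tuple[int, float]]:
    """Mean of the measured quantity at each step across orderings."""
    g = table.records.groupby("step")["delta"].mean()
    return [(int(i), float(v)) for i, v in g.items()]


def mean_increments(table: GrowthTable) -> list[tuple[int, float]]:
    """Mean per-step increment across orderings."""
    g = table.records.groupby("step")["delta_increment"].mean()
    return [(int(i), float(v)) for i, v in g.items()]


def heaps_fit(increments: list[tuple[int, float]], i_min: int = 2) -> HeapsFit:
    """Fit K * i**(-alpha) to per-step increments.

    Steps below ``i_min`` are excluded (the step-1 "increment" is an entire
    genome, not a discovery increment), as are non-positive increments
    (counted in ``n_dropped``).  An ordinary least-squares line on
    log-increment vs log-step seeds a nonlinear least-squares refinement on
    the original scale.  Requires at least three usable points.
    """
    pts = [(i, dd) for i, dd in increments if i >= i_min and dd > 0]
    n_dropped = sum(1 for i, dd in increments if i >= i_min and dd <= 0)
    if len(pts) < 3:
        raise ValueError(
            f"too few usable increments for a Heaps fit "
            f"({len(pts)} with step >= {i_min} and positive increment)")
    i_arr = np.array([p[0] for p in pts], dtype=float)
    d_arr = np.array([p[1] for p in pts], dtype=float)
    slope, intercept = np.polyfit(np.log(i_arr), np.log(d_arr), 1)
    k0, a0 = math.exp(intercept), -slope

    def model(i, K, alpha):
        return K * np.power(i, -alpha)

    try:
        popt, _ = curve_fit(model, i_arr, d_arr, p0=(k0, a0), maxfev=10000)
        K, alpha = float(popt[0]), float(popt[1])
    except RuntimeError:  # fall back to the log-scale line
        K, alpha = k0, a0
    resid = float(np.sqrt(np.mean(
        (np.log(d_arr) - np.log(np.maximum(model(i_arr, K, alpha),
                                           1e-300))) ** 2)))
    return HeapsFit(K=K, alpha=alpha,
                    fit_range=(int(i_arr.min()), int(i_arr.max())),
                    residual=resid, n_dropped=n_dropped)


def cardinality_growth_ksweep(stacks: list[SketchStack], mink: int,
                              maxk: int, n_orders: int, seed: int
                              ) -> dict[int, GrowthTable]:
    """Progressive growth of the distinct-k-mer count d_k for each k.

    The k-free delta machinery is bypassed: at each fixed k the cumulative
    union's cardinality itself is recorded, giving the k-dependent growth
    functions whose Heaps fits show how openness conclusions vary with k.
    """
    if not 1 <= mink <= maxk:
        raise ValueError("need 1 <= mink <= maxk")
    orderings = random_orderings(len(stacks), n_orders, seed)
    out: dict[int, GrowthTable] = {}
    for k in range(mink, maxk + 1):
        rows = []
        for oid, order in enumerate(orderings):
            running: SketchStack | None = None
            prev = 0.0
            for step, idx in enumerate(order, start=1):
                nxt = stacks[idx]
                running = (nxt if running is None
                           else union_stack([running, nxt]))
                card = running.card(k)
                rows.append((oid, step, nxt.label, card, card - prev))
                prev = card
        df = pd.DataFrame(rows, columns=["ordering", "step", "added",
                                         "delta", "delta_increment"])
        out[k] = GrowthTable(df, n_orderings=len(orderings), rng_seed=seed,
                             quantity=f"d_{k}")
    return out


def alpha_vs_k(tables: dict[int, GrowthTable], i_min: int = 2
               ) -> list[tuple[int, float]]:
    """Heaps alpha fitted to each k's mean growth increments.

    Saturated k (no positive increments past step 1, e.g. tiny k on any
    sizeable collection) have no defined alpha and are reported as NaN.
    """
    out = []
    for k, table in sorted(tables.items()):
        try:
            fit = heaps_fit(mean_increments(table), i_min=i_min)
            out.append((k, fit.alpha))
        except ValueError:
            out.append((k, float("nan")))
    return out
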