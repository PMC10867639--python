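"""Progressive unions, Heaps'-law fitting, openness, and the k-sweep."""

import math

import numpy as np
import pandas as pd
import pytest

from deltasketch import (SequenceCollection, SketchStack, GrowthTable,
                         alpha_vs_k, cardinality_growth_ksweep, delta_exact,
                         heaps_fit, mean_growth, mean_increments,
                         progressive_deltas, random_orderings)

from conftest import random_collection


def _stacks(colls, backend="exact"):
    return [SketchStack(c, backend=backend, label=c.labels[0])
            for c in colls]


# -- orderings ----------------------------------------------------------


def test_random_orderings_are_valid_permutations():
    orders = random_orderings(3, 6, seed=5)
    assert len(orders) == 6
    assert all(sorted(o) == [0, 1, 2] for o in orders)


def test_random_orderings_deterministic():
    assert random_orderings(9, 4, seed=11) == random_orderings(9, 4, seed=11)


def test_single_item_orderings():
    assert random_orderings(1, 5, seed=0) == [(0,)] * 5


def test_exhaustive_enumeration_for_small_collections():
    orders = random_orderings(3, 6, seed=1)
    assert sorted(set(orders)) == sorted(orders)  # each permutation once
    assert len(orders) == math.factorial(3)
    # below the factorial threshold: sampled with replacement instead
    assert len(random_orderings(3, 5, seed=1)) == 5


def test_bad_ordering_arguments_rejected():
    with pytest.raises(ValueError):
        random_orderings(0, 5, 0)
    with pytest.raises(ValueError):
        random_orderings(5, 0, 0)


# -- progressive deltas -------------------------------------------------


def test_single_genome_single_ordering(rng):
    coll = random_collection(rng, 1, 900, 900)
    table = progressive_deltas(_stacks([coll]), [(0,)])
    assert len(table.records) == 1
    row = table.records.iloc[0]
    assert row.delta == pytest.approx(delta_exact(coll).delta)
    assert row.delta_increment == row.delta


def test_identical_genomes_plateau(rng):
    coll = random_collection(rng, 1, 1000, 1000)
    copies = [SequenceCollection([(f"g{i}", coll.members[0][1])])
              for i in range(3)]
    table = progressive_deltas(_stacks(copies), random_orderings(3, 6, 1))
    later = table.records[table.records.step > 1]
    assert (later.delta_increment == 0).all()
    assert table.records.delta.nunique() == 1


def test_final_delta_order_invariant_and_matches_direct(rng):
    colls = [random_collection(rng, 1, 600, 1000) for _ in range(5)]
    orders = random_orderings(5, 3, seed=9)
    table = progressive_deltas(_stacks(colls), orders)
    finals = table.records[table.records.step == 5].delta
    assert finals.nunique() == 1
    direct = delta_exact(SequenceCollection.combine(colls))
    assert finals.iloc[0] == pytest.approx(direct.delta)


def test_delta_nondecreasing_within_ordering(rng):
    colls = [random_collection(rng, 1, 400, 900) for _ in range(5)]
    table = progressive_deltas(_stacks(colls), random_orderings(5, 4, 2))
    for _, grp in table.records.groupby("ordering"):
        deltas = grp.sort_values("step").delta.values
        assert np.all(np.diff(deltas) >= 0)
        assert np.allclose(grp.sort_values("step").delta_increment.values,
                           np.diff(np.concatenate(([0.0], deltas))))


# -- mean growth ---------------------------------------------------------


def _toy_table():
    rows = []
    curves = {0: [10.0, 14.0, 16.0], 1: [12.0, 13.0, 16.0],
              2: [8.0, 15.0, 16.0]}
    for oid, deltas in curves.items():
        prev = 0.0
        for step, d in enumerate(deltas, 1):
            rows.append((oid, step, f"g{step}", d, d - prev))
            prev = d
    df = pd.DataFrame(rows, columns=["ordering", "step", "added", "delta",
                                     "delta_increment"])
    return GrowthTable(df, n_orderings=3, rng_seed=0)


def test_mean_growth_hand_computed():
    assert mean_growth(_toy_table()) == [(1, 10.0), (2, 14.0), (3, 16.0)]


def test_mean_growth_single_ordering_is_identity():
    t = _toy_table()
    t.records = t.records[t.records.ordering == 1]
    assert mean_growth(t) == [(1, 12.0), (2, 13.0), (3, 16.0)]


def test_mean_increments_hand_computed():
    assert mean_increments(_toy_table()) == [(1, 10.0), (2, 4.0), (3, 2.0)]


# -- Heaps fitting --------------------------------------------------------


def test_heaps_fit_recovers_noiseless_power_law():
    pts = [(i, 100.0 * i ** -0.5) for i in range(2, 21)]
    fit = heaps_fit(pts)
    assert fit.alpha == pytest.approx(0.5, abs=1e-6)
    assert fit.K == pytest.approx(100.0, abs=1e-4)
    assert fit.openness == "open"


def test_heaps_fit_classifies_closed():
    pts = [(i, 50.0 * i ** -1.2) for i in range(2, 15)]
    fit = heaps_fit(pts)
    assert fit.alpha == pytest.approx(1.2, abs=1e-6)
    assert fit.openness == "closed"


def test_heaps_fit_noisy_recovery():
    """Lognormal multiplicative noise: mean fitted alpha near truth."""
    rng = np.random.default_rng(77)
    alphas = []
    for _ in range(20):
        noise = rng.lognormal(0.0, 0.1, size=39)
        pts = [(i, 40.0 * i ** -0.8 * noise[i - 2]) for i in range(2, 41)]
        alphas.append(heaps_fit(pts).alpha)
    assert abs(np.mean(alphas) - 0.8) <= 0.05


def test_heaps_fit_requires_three_points():
    with pytest.raises(ValueError):
        heaps_fit([(2, 5.0), (3, 4.0)])
    with pytest.raises(ValueError):  # zeros are dropped before fitting
        heaps_fit([(2, 5.0), (3, 0.0), (4, 0.0), (5, 0.0)])


def test_heaps_fit_excludes_step_one():
    pts = [(1, 1e6)] + [(i, 10.0 * i ** -0.7) for i in range(2, 12)]
    assert heaps_fit(pts).alpha == pytest.approx(0.7, abs=1e-6)


# -- k-sweep --------------------------------------------------------------


def test_ksweep_tables_match_exact_recomputation(rng):
    from deltasketch import exact_cardinality

    colls = [random_collection(rng, 1, 500, 700) for _ in range(4)]
    tables = cardinality_growth_ksweep(_stacks(colls), 9, 9, n_orders=3,
                                       seed=4)
    assert list(tables) == [9]
    df = tables[9].records
    for oid, order in enumerate(random_orderings(4, 3, seed=4)):
        for step in range(1, 5):
            sub = SequenceCollection.combine([colls[i]
                                              for i in order[:step]])
            got = df[(df.ordering == oid) & (df.step == step)].delta.iloc[0]
            assert got == exact_cardinality(sub, 9)


def test_ksweep_k1_saturates_at_two(rng):
    colls = [random_collection(rng, 1, 300, 400) for _ in range(3)]
    tables = cardinality_growth_ksweep(_stacks(colls), 1, 1, 2, seed=0)
    assert (tables[1].records.delta <= 2).all()  # canonical bases {A, C}


def test_alpha_vs_k_degenerate_is_nan(rng):
    seq = random_collection(rng, 1, 800, 800).members[0][1]
    copies = [SequenceCollection([(f"g{i}", seq)]) for i in range(5)]
    tables = cardinality_growth_ksweep(_stacks(copies), 8, 9, 4, seed=3)
    for k, alpha in alpha_vs_k(tables):
        assert math.isnan(alpha)


def test_ksweep_rejects_bad_range(rng):
    stacks = _stacks([random_collection(rng, 1, 200, 200)])
    with pytest.raises(ValueError):
        cardinality_growth_ksweep(stacks, 5, 4, 2, 0)
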