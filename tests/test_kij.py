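"""k-specific and k-independent Jaccard, distance matrices, tree recovery."""

import numpy as np
import pytest
import skbio

from deltasketch import (DeltaResult, SequenceCollection, SketchStack,
                         jaccard_k, kij, pairwise_jaccard_sweep,
                         pairwise_kij, phylogeny_pangenome, union_stack)

from conftest import random_collection


def _dr(delta, k_star=10):
    return DeltaResult(delta, k_star, {k_star: delta * k_star}, "exact")


def _stack(coll, label=None):
    return SketchStack(coll, backend="exact",
                       label=label or coll.labels[0])


# -- arithmetic ----------------------------------------------------------


def test_kij_inclusion_exclusion_arithmetic():
    assert kij(_dr(10), _dr(8), _dr(14)) == pytest.approx(4 / 14)


def test_kij_identical_inputs_is_one():
    x = _dr(123.4)
    assert kij(x, x, x) == 1.0


def test_kij_zero_union_rejected():
    with pytest.raises(ValueError):
        kij(_dr(0), _dr(0), _dr(0))


def test_kij_clamps_but_reports_raw():
    noisy = kij(_dr(5.0), _dr(5.0), _dr(4.9), clamp=False)
    assert noisy > 1.0
    assert kij(_dr(5.0), _dr(5.0), _dr(4.9)) == 1.0


def test_jaccard_k_identical_disjoint_and_arithmetic(rng):
    a = random_collection(rng, 1, 400, 600)
    sa, sa2 = _stack(a, "a"), _stack(a, "a2")
    u_same = union_stack([sa, sa2])
    assert jaccard_k(sa, sa2, u_same, 12) == 1.0

    b = random_collection(rng, 1, 400, 600)  # unrelated: near-disjoint 12-mers
    sb = _stack(b, "b")
    u = union_stack([sa, sb])
    assert jaccard_k(sa, sb, u, 12) == pytest.approx(0.0, abs=0.01)


def test_jaccard_k_hand_example():
    from deltasketch.kij import _jaccard_from_cards
    assert _jaccard_from_cards(5, 7, 9) == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        _jaccard_from_cards(0, 0, 0)


# -- delta-derived bounds -------------------------------------------------


@pytest.mark.parametrize("seed", range(10))
def test_kij_in_unit_interval_unclamped_exact(seed):
    """Superset monotonicity + subadditivity of delta pin KIJ to [0, 1]."""
    rng = np.random.default_rng(3000 + seed)
    a = random_collection(rng, 1, 200, 1500)
    b = random_collection(rng, 1, 200, 1500)
    sa, sb = _stack(a, "a"), _stack(b, "b")
    du = union_stack([sa, sb]).delta(max(sa.delta().k_star,
                                         sb.delta().k_star))
    raw = kij(sa.delta(), sb.delta(), du, clamp=False)
    assert 0.0 <= raw <= 1.0


def test_kij_self_similarity_exact(rng):
    coll = random_collection(rng, 1, 900, 900)
    sa, sb = _stack(coll, "a"), _stack(coll, "b")
    du = union_stack([sa, sb]).delta()
    assert kij(sa.delta(), sb.delta(), du, clamp=False) == 1.0


def test_kij_symmetry(rng):
    a, b = (random_collection(rng, 1, 500, 900) for _ in range(2))
    sa, sb = _stack(a, "a"), _stack(b, "b")
    ab = union_stack([sa, sb]).delta()
    ba = union_stack([sb, sa]).delta()
    assert kij(sa.delta(), sb.delta(), ab) == kij(sb.delta(), sa.delta(), ba)


def test_sketch_and_exact_backends_agree_on_kij():
    leaves, _ = phylogeny_pangenome(2, 30_000, 0.05, seed=21)
    exact = [SketchStack(g, backend="exact", label=g.labels[0])
             for g in leaves]
    approx = [SketchStack(g, backend="sketch", label=g.labels[0])
              for g in leaves]

    def one(stacks):
        du = union_stack(stacks).delta(max(s.delta().k_star for s in stacks))
        return kij(stacks[0].delta(), stacks[1].delta(), du)

    assert one(approx) == pytest.approx(one(exact), abs=0.02)


# -- matrices -------------------------------------------------------------


def test_pairwise_kij_matrix_structure(small_genomes):
    stacks = [_stack(g, f"g{i}") for i, g in enumerate(small_genomes)]
    mat = pairwise_kij(stacks)
    assert mat.metric == "1-KIJ"
    assert np.allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 0)
    assert ((mat.values >= 0) & (mat.values <= 1)).all()
    assert set(mat.details.columns) >= {"kstar_a", "kstar_b", "kstar_union",
                                        "kij", "kij_raw"}


def test_pairwise_kij_duplicate_input_distance_zero(rng):
    coll = random_collection(rng, 1, 1200, 1200)
    other = random_collection(rng, 1, 1200, 1200)
    stacks = [_stack(coll, "a"), _stack(coll, "a_copy"), _stack(other, "b")]
    mat = pairwise_kij(stacks)
    assert mat.values[0, 1] == 0.0
    assert mat.values[0, 2] > 0.5


def test_pairwise_needs_two_inputs(rng):
    with pytest.raises(ValueError):
        pairwise_kij([_stack(random_collection(rng, 1, 300, 300))])


def test_four_leaf_clades_closer_within_than_between():
    leaves, _ = phylogeny_pangenome(4, 3000, 0.03, seed=8)
    mat = pairwise_kij([_stack(g) for g in leaves])
    within = [mat.values[0, 1], mat.values[2, 3]]
    between = [mat.values[i, j] for i in (0, 1) for j in (2, 3)]
    assert max(within) < min(between)


def test_neighbor_joining_recovers_eight_leaf_topology():
    leaves, newick = phylogeny_pangenome(8, 4000, 0.03, seed=5)
    mat = pairwise_kij([_stack(g) for g in leaves])
    tree = skbio.tree.nj(skbio.DistanceMatrix(mat.values, ids=mat.labels))
    truth = skbio.TreeNode.read([newick])
    assert tree.compare_rfd(truth) == 0.0


def test_jaccard_sweep_single_k_and_identical_inputs(rng):
    coll = random_collection(rng, 1, 800, 800)
    stacks = [_stack(coll, "a"), _stack(coll, "b")]
    mats = pairwise_jaccard_sweep(stacks, 9, 9)
    assert list(mats) == [9]
    assert np.all(mats[9].values == 0)

    mats = pairwise_jaccard_sweep(stacks, 4, 6)
    assert sorted(mats) == [4, 5, 6]
    for mat in mats.values():
        assert np.all(mat.values == 0)


def test_jaccard_sweep_pair_ordering_matches_kij_near_kstar():
    leaves, _ = phylogeny_pangenome(4, 3000, 0.03, seed=8)
    stacks = [_stack(g) for g in leaves]
    kmat = pairwise_kij(stacks)
    k_star = int(kmat.details.kstar_union.max())
    jmat = pairwise_jaccard_sweep(stacks, k_star, k_star)[k_star]
    iu = np.triu_indices(4, 1)
    assert (np.argsort(kmat.values[iu]) == np.argsort(jmat.values[iu])).all()


def test_phylip_and_tsv_output(small_genomes):
    stacks = [_stack(g, f"g{i}") for i, g in enumerate(small_genomes)]
    mat = pairwise_kij(stacks)
    phy = mat.to_phylip().splitlines()
    assert phy[0] == "4" and len(phy) == 5
    assert phy[1].startswith("g0")
    tsv = mat.to_long_tsv().splitlines()
    assert tsv[0] == "a\tb\tdistance" and len(tsv) == 1 + 6
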