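"""Stage III: selectivity, filters, amplification and the transformation."""

import numpy as np
import pytest
import scipy.sparse as sp

from probmsa.consistency import (AGGREGATIONS, ConsistencyConfig,
                                 RelaxationPlan, TriangleFilter,
                                 amplification_coeff, build_plan,
                                 consistency_transform, default_threshold,
                                 deterministic_accept, num_transformations,
                                 relax_pair, stochastic_accept)
from probmsa.guidetree import tree_distance_matrix, upgma
from probmsa.posterior import PosteriorStore, compute_posteriors
from probmsa.testkit import FamilySpec, generate_family, oracles


def test_num_transformations_rule():
    assert num_transformations(30) == 2
    assert num_transformations(49) == 2
    assert num_transformations(50) == 1
    assert num_transformations(1000) == 1
    with pytest.raises(ValueError):
        num_transformations(1)


def test_deterministic_accept():
    assert deterministic_accept(3, 5, "max", 6)
    assert not deterministic_accept(3, 5, "max", 4)
    assert deterministic_accept(3, 5, "min", 4)
    assert not deterministic_accept(3, 5, "sum", 7)
    assert not deterministic_accept(1, 1, "max", 0)       # T=0: selectivity off
    assert deterministic_accept(1e9, 1e9, "sum", np.inf)  # T=inf: full


def test_stochastic_accept_degenerate_filters():
    rng = np.random.default_rng(0)
    assert all(stochastic_accept(0.3, lambda a: 1.0, rng) for _ in range(50))
    assert not any(stochastic_accept(0.3, lambda a: 0.0, rng)
                   for _ in range(50))


def test_triangle_filter_shapes():
    lo = TriangleFilter("low-pass", 0.10)
    assert lo(0.0) == 1.0 and lo(0.2) == 0.0 and lo(0.1) == pytest.approx(0.5)
    hi = TriangleFilter("high-pass", 0.10)
    assert hi(1.0) == 1.0 and hi(0.8) == pytest.approx(0.0, abs=1e-12)
    mid = TriangleFilter("mid-pass", 0.10)
    assert mid(0.5) == 1.0
    assert mid(0.4) == pytest.approx(0.0, abs=1e-12)
    assert mid(0.6) == pytest.approx(0.0, abs=1e-12)


def test_triangle_filter_monte_carlo_calibration():
    f = TriangleFilter("low-pass", 0.10)
    rng = np.random.default_rng(42)
    draws = rng.random(10_000)
    accepted = sum(stochastic_accept(a, f, rng) for a in draws)
    assert accepted / 10_000 == pytest.approx(f.expected_acceptance(), abs=0.02)


def test_amplification_coefficient_linear_map():
    assert amplification_coeff(0, 200, 3.0) == 1.0
    assert amplification_coeff(200, 200, 3.0) == 3.0
    assert amplification_coeff(100, 200, 3.0) == 2.0
    assert amplification_coeff(500, 200, 3.0) == 3.0  # capped
    assert amplification_coeff(7, 200, 1.0) == 1.0


def test_default_threshold_grows_with_family_size():
    assert default_threshold(20) == 9
    assert default_threshold(100) == 20


@pytest.fixture(scope="module")
def tiny_stage(hmm_params, part_params):
    seqs, _, _ = generate_family(FamilySpec(n=4, ancestor_length=15, seed=5))
    store, scores = compute_posteriors(seqs, hmm_params, part_params,
                                       cutoff=0.0)
    lengths = [len(s) for s in seqs]
    from probmsa.guidetree import distance_matrix_from_scores
    D = distance_matrix_from_scores(scores, lengths)
    tree = upgma(D, seqs.ids)
    return seqs, store, D, tree


def test_build_plan_full_mode(tiny_stage):
    seqs, store, D, tree = tiny_stage
    plan = build_plan(4, ConsistencyConfig(mode="full"))
    assert all(len(z) == 2 for z in plan.accepted.values())


def test_build_plan_deterministic_matches_brute_triple_scan(tiny_stage):
    seqs, store, D, tree = tiny_stage
    T = 3.0
    cfg = ConsistencyConfig(mode="deterministic-tree", alpha="max", T=T)
    plan = build_plan(4, cfg, tree=tree)
    M = tree_distance_matrix(tree)
    for i in range(4):
        for j in range(i + 1, 4):
            want = sorted(z for z in range(4) if z not in (i, j)
                          and max(M[i, z], M[j, z]) <= T)
            assert sorted(plan.accepted[(i, j)]) == want


def test_build_plan_stochastic_reproducible(tiny_stage):
    seqs, store, D, tree = tiny_stage
    cfg = ConsistencyConfig(mode="stochastic-score", alpha="sum", seed=9)
    p1 = build_plan(4, cfg, distances=D)
    p2 = build_plan(4, cfg, distances=D)
    assert p1.accepted == p2.accepted


def test_relax_pair_empty_accepted_is_exact_identity():
    rng = np.random.default_rng(1)
    S = sp.csr_matrix(rng.random((3, 4)) * (rng.random((3, 4)) > 0.4))
    out = relax_pair(S, [], 0.3, 0.2, 1.0, cutoff=0.0)
    assert (out != S).nnz == 0


def test_relax_pair_matches_hand_computed_dense():
    S_xy = np.array([[0.5, 0.1], [0.2, 0.6]])
    S_xz = np.array([[0.7, 0.0], [0.1, 0.8]])
    S_zy = np.array([[0.4, 0.3], [0.2, 0.5]])
    w_x, w_y, w_z, h = 0.4, 0.3, 0.3, 2.0
    want = (h * (w_x + w_y) * S_xy + w_z * (S_xz @ S_zy)) / (
        h * (w_x + w_y) + w_z)
    got = relax_pair(sp.csr_matrix(S_xy),
                     [(w_z, sp.csr_matrix(S_xz), sp.csr_matrix(S_zy))],
                     w_x, w_y, h, cutoff=0.0)
    np.testing.assert_allclose(got.toarray(), want, atol=1e-12)


def test_relax_pair_dimension_mismatch():
    S = sp.csr_matrix(np.ones((2, 2)) * 0.1)
    bad = sp.csr_matrix(np.ones((3, 2)) * 0.1)
    with pytest.raises(ValueError, match="dimensions"):
        relax_pair(S, [(0.5, bad, S)], 0.5, 0.5, 1.0)


def _dense_mats(store, n):
    return {(i, j): store.get_dense(i, j)
            for i in range(n) for j in range(i + 1, n)}


def test_full_transform_matches_dense_triple_loop(tiny_stage):
    seqs, store, D, tree = tiny_stage
    weights = tree.sequence_weights()
    wvec = [weights[s] for s in seqs.ids]
    cfg = ConsistencyConfig(mode="full", h=1.0, iterations=1)
    plan = build_plan(4, cfg)
    got = consistency_transform(store, plan, wvec, cfg)
    want = oracles.dense_consistency(_dense_mats(store, 4), wvec, h=1.0)
    for key, W in want.items():
        np.testing.assert_allclose(got.get_dense(*key), W, atol=1e-9)


def test_transform_without_relaxations_is_identity(tiny_stage):
    seqs, store, D, tree = tiny_stage
    weights = tree.sequence_weights()
    wvec = [weights[s] for s in seqs.ids]
    cfg = ConsistencyConfig(mode="deterministic-tree", T=0.0, h=1.0,
                            iterations=1)
    plan = build_plan(4, cfg, tree=tree)
    got = consistency_transform(store, plan, wvec, cfg)
    for (i, j) in store.pairs():
        assert (got.get(i, j) != store.get(i, j)).nnz == 0


def test_transform_transpose_symmetry_and_range(tiny_stage):
    seqs, store, D, tree = tiny_stage
    weights = tree.sequence_weights()
    wvec = [weights[s] for s in seqs.ids]
    cfg = ConsistencyConfig(mode="full", iterations=1)
    plan = build_plan(4, cfg)
    got = consistency_transform(store, plan, wvec, cfg)
    for i in range(4):
        for j in range(i + 1, 4):
            A = got.get_dense(i, j)
            B = got.get_dense(j, i)
            np.testing.assert_array_equal(A, B.T)
            assert A.min() >= 0 and A.max() <= 1 + 1e-9


def test_two_iterations_compose_single_transformations(tiny_stage):
    seqs, store, D, tree = tiny_stage
    weights = tree.sequence_weights()
    wvec = [weights[s] for s in seqs.ids]
    plan = build_plan(4, ConsistencyConfig(mode="full"))
    two = consistency_transform(store, plan, wvec,
                                ConsistencyConfig(mode="full", iterations=2))
    one = consistency_transform(store, plan, wvec,
                                ConsistencyConfig(mode="full", iterations=1))
    again = consistency_transform(one, plan, wvec,
                                  ConsistencyConfig(mode="full", iterations=1))
    for (i, j) in store.pairs():
        np.testing.assert_allclose(two.get_dense(i, j),
                                   again.get_dense(i, j), atol=1e-12)


def test_threshold_to_infinity_recovers_full_consistency(tiny_stage):
    seqs, store, D, tree = tiny_stage
    weights = tree.sequence_weights()
    wvec = [weights[s] for s in seqs.ids]
    sel = ConsistencyConfig(mode="deterministic-tree", T=np.inf, h=3.0,
                            iterations=1)
    full = ConsistencyConfig(mode="full", h=3.0, iterations=1)
    a = consistency_transform(store, build_plan(4, sel, tree=tree), wvec, sel)
    b = consistency_transform(store, build_plan(4, full), wvec, full)
    for (i, j) in store.pairs():
        np.testing.assert_allclose(a.get_dense(i, j), b.get_dense(i, j),
                                   atol=1e-12)


def test_resolved_defaults():
    cfg = ConsistencyConfig(mode="full").resolved(10)
    assert cfg.h == 1.0 and cfg.iterations == 2
    cfg = ConsistencyConfig(mode="deterministic-tree").resolved(60)
    assert cfg.h == 3.0 and cfg.iterations == 1
    assert cfg.T == default_threshold(60)
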