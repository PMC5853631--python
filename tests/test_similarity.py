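"""Pattern similarity, category index, boundary scan and controls."""

import dataclasses

import numpy as np
import pytest

from catring.geometry import Boundary, candidate_boundaries, pair_sets
from catring.similarity import (
    RETINOTOPY_GROUPS,
    SimilarityTable,
    attention_contrast,
    boundary_scan,
    boundary_scan_group,
    category_index,
    near_far_contrast,
    position_patterns,
    retinotopy_interaction,
    similarity_table,
)
from catring.stats import binomial_tail
from catring.synthetic import default_rois, generate_experiment
from conftest import separable_dataset, small_config


def _table_from_rho(fn) -> SimilarityTable:
    rho = np.ones((8, 8))
    for i in range(8):
        for j in range(8):
            if i != j:
                rho[i, j] = fn(*sorted((i, j)))
    return SimilarityTable(rho=rho)


def test_position_patterns_are_trial_means():
    ds = separable_dataset(n_runs=3, trials_per_pos_per_run=2, noise_sd=0.5, seed=0)
    pats = position_patterns(ds, 0.0)
    # streaming-mean oracle
    for k in range(8):
        mask = ds.position_labels == k
        acc = np.zeros(ds.data.shape[2])
        n = 0
        for row in ds.data[mask, 0, :]:
            n += 1
            acc += (row - acc) / n
        np.testing.assert_allclose(pats[k], acc, atol=1e-12)


def test_position_patterns_require_trials_and_voxels():
    ds = separable_dataset(n_runs=2, noise_sd=0.0)
    ds.correct[ds.position_labels == 3] = False
    with pytest.raises(ValueError):
        position_patterns(ds, 0.0)
    with pytest.raises(ValueError):
        position_patterns(ds, 0.0, voxel_set=np.array([], int), correct_only=False)


def test_similarity_rank_invariance_and_extremes():
    rng = np.random.default_rng(1)
    base = rng.normal(size=12)
    pats = np.stack([base, np.exp(2 * base), -base] + [rng.normal(size=12) for _ in range(5)])
    st = similarity_table(pats)
    assert st.value(0, 1) == pytest.approx(1.0)  # monotone transform
    assert st.value(0, 2) == pytest.approx(-1.0)
    assert np.allclose(st.rho, st.rho.T)
    assert np.abs(st.rho).max() <= 1.0 + 1e-12


def test_similarity_matches_brute_force_rank_correlation():
    """4-voxel worked example against exhaustive rank-based computation."""
    pats = np.array(
        [[1.0, 3.0, 2.0, 4.0], [2.0, 1.0, 4.0, 3.0]]
        + [[float(i), 1.0, 2.0, 3.0] for i in range(4, 10)]
    )
    st = similarity_table(pats)
    # by hand: ranks [1,3,2,4] vs [2,1,4,3]; d = (-1,2,-2,1); rho = 1-6*10/60
    assert st.value(0, 1) == pytest.approx(1 - 6 * 10 / (4 * 15))


def test_category_index_trivial_tables(ring, boundary):
    within_plus = _table_from_rho(
        lambda i, j: 1.0
        if boundary.side_of(ring, i) == boundary.side_of(ring, j)
        else -1.0
    )
    for steps in (1, 2, 3):
        res = category_index(within_plus, ring, boundary, steps)
        assert res.ci == pytest.approx(2.0)
        assert res.ci == res.wcs - res.bcs
    flat = _table_from_rho(lambda i, j: 0.42)
    assert category_index(flat, ring, boundary, 2).ci == pytest.approx(0.0)


def test_category_index_antisymmetric_under_role_swap(ring, boundary):
    rng = np.random.default_rng(2)
    vals = {}
    st = _table_from_rho(lambda i, j: vals.setdefault((i, j), rng.uniform(-1, 1)))
    ps = pair_sets(ring, boundary, 3)
    wcs = st.mean_over(ps.wcs_pairs)
    bcs = st.mean_over(ps.bcs_pairs)
    res = category_index(st, ring, boundary, 3)
    assert res.ci == pytest.approx(wcs - bcs)
    assert -(res.ci) == pytest.approx(bcs - wcs)


def test_category_index_constant_shift_and_voxel_order_invariance(ring, boundary):
    rng = np.random.default_rng(3)
    pats = rng.normal(size=(8, 20))
    st1 = similarity_table(pats)
    st2 = similarity_table(pats + 5.0)  # constant added to every voxel
    perm = rng.permutation(20)
    st3 = similarity_table(pats[:, perm])  # voxel reordering
    for st in (st2, st3):
        assert category_index(st, ring, boundary, 1).ci == pytest.approx(
            category_index(st1, ring, boundary, 1).ci
        )


def test_injected_category_signal_yields_positive_index(ring):
    from catring.synthetic import SyntheticConfig

    cis = []
    for seed in range(10):
        cfg = SyntheticConfig(n_subjects=1, seed=seed)  # full 15-run design
        sub = generate_experiment(cfg).subjects[0]
        st = similarity_table(position_patterns(sub.datasets["V1"], 10.0))
        cis.append(category_index(st, ring, cfg.boundary, 1).ci)
    assert np.mean(cis) > 0
    assert np.mean(cis) > 2 * np.std(cis, ddof=1) / np.sqrt(len(cis))


def test_boundary_scan_recovers_strong_injected_boundary(ring):
    """At 10x the default category amplitude the injected boundary wins the
    scan for every seed."""
    for seed in range(5):
        rois = tuple(
            dataclasses.replace(
                r, category_amplitude=tuple(10 * a for a in r.category_amplitude)
            )
            for r in default_rois()
        )
        cfg = small_config(seed=seed, rois=rois)
        sub = generate_experiment(cfg).subjects[0]
        st = similarity_table(position_patterns(sub.datasets["V1"], 10.0))
        cis, best = boundary_scan(st, ring, 1)
        assert best.axis_angle == 45.0
        assert cis[45.0] == max(cis.values())
        assert set(cis) == {0.0, 45.0, 90.0, 135.0}


def test_boundary_scan_group_binomial(ring):
    res = boundary_scan_group(np.array([True] * 9 + [False] * 3))
    assert res.p == pytest.approx(binomial_tail(9, 12, 0.25))
    assert res.statistic == 9


def test_near_far_contrast_zero_for_flat_table(ring, boundary):
    tables = [_table_from_rho(lambda i, j: 0.3) for _ in range(5)]
    near, far, _ = near_far_contrast(tables, ring, boundary)
    assert np.allclose(near - far, 0.0)


def test_near_far_contrast_detects_graded_category_similarity(ring, boundary):
    """If similarity falls with the category separation implied by boundary
    distance, near diametric pairs are more similar than far ones."""
    rng = np.random.default_rng(4)

    def graded(i, j):
        from catring.geometry import boundary_distance

        same = boundary.side_of(ring, i) == boundary.side_of(ring, j)
        gap = 0.0 if same else 0.1 * (
            boundary_distance(ring, boundary, i) + boundary_distance(ring, boundary, j)
        )
        return 0.8 - gap + rng.normal(0, 0.005)

    tables = [_table_from_rho(graded) for _ in range(6)]
    near, far, res = near_far_contrast(tables, ring, boundary)
    assert (near > far).all()
    assert res.df == 5
    assert res.statistic > 0


def test_attention_contrast_sign_and_fixed_set_sizes(ring):
    from catring.geometry import boundary_distance

    for b in candidate_boundaries(ring):
        rng = np.random.default_rng(5)

        def inv_dist(i, j):
            return 1.0 / (
                1.0
                + boundary_distance(ring, b, i)
                + boundary_distance(ring, b, j)
            ) + rng.normal(0, 1e-4)

        tables = [_table_from_rho(inv_dist) for _ in range(4)]
        d, s, res = attention_contrast(tables, ring, b)
        assert (d > s).all()  # mixed-distance pairs sit closer to the boundary
    flat = [_table_from_rho(lambda i, j: 0.1) for _ in range(4)]
    d, s, _ = attention_contrast(flat, ring, Boundary(45.0))
    assert np.allclose(d - s, 0.0)


def test_retinotopy_interaction_crossover_vs_additive():
    rng = np.random.default_rng(6)

    def tables_with_group_boost(boost_group, n=8):
        out = []
        for _ in range(n):
            def rho(i, j):
                pair = (i, j)
                for gid, pairs in RETINOTOPY_GROUPS.items():
                    if pair in pairs:
                        return 0.5 + (0.4 if gid == boost_group else 0.0) + rng.normal(0, 0.05)
                return rng.uniform(-0.2, 0.2)
            out.append(_table_from_rho(rho))
        return out

    # crossover: group 1 high in experiment 1, group 2 high in experiment 2
    res = retinotopy_interaction(tables_with_group_boost(1), tables_with_group_boost(2))
    assert res.p < 0.01
    # additive: same group profile in both experiments -> no interaction
    res0 = retinotopy_interaction(tables_with_group_boost(1), tables_with_group_boost(1))
    assert res0.statistic < res.statistic
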