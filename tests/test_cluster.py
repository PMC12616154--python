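"""Unit tests for cluster permutation inference and FDR adjustment."""

import numpy as np
import pytest
from scipy import stats

from strsa.cluster import (ClusterResult, cluster_test_1d,
                           cluster_test_spatiotemporal, fdr_adjust,
                           grid_adjacency)


def _signal_data(rng, n_sub=8, n_bins=40, lo=10, hi=20, amp=1.0):
    d = rng.standard_normal((n_sub, n_bins))
    d[:, lo:hi] += amp
    return d


# ---------------------------------------------------------------------------
# 1-D test
# ---------------------------------------------------------------------------

def test_detects_planted_cluster_and_reports_extent():
    rng = np.random.default_rng(0)
    data = _signal_data(rng, amp=1.5)
    times = np.arange(40) * 10.0
    clusters = cluster_test_1d(data, n_perm=1000, seed=1, times_ms=times)
    sig = [c for c in clusters if c.significant(0.05)]
    assert len(sig) >= 1
    big = max(sig, key=lambda c: c.mass)
    assert 10 <= big.members[0] <= 12 and 17 <= big.members[-1] <= 21
    assert big.onset_ms == times[big.members[0]]
    assert big.offset_ms == times[big.members[-1]]


def test_pure_noise_rarely_significant():
    rng = np.random.default_rng(1)
    hits = 0
    for i in range(40):
        clusters = cluster_test_1d(rng.standard_normal((8, 40)), n_perm=300,
                                   seed=i)
        hits += any(c.significant(0.05) for c in clusters)
    assert hits <= 6  # nominal 2, generous bound


def test_exact_enumeration_p_floor():
    # 2^6 = 64 <= n_perm: exact test, smallest achievable p is 1/64
    data = np.ones((6, 10)) + 0.01 * np.random.default_rng(2).standard_normal((6, 10))
    clusters = cluster_test_1d(data, n_perm=1000, seed=0)
    assert clusters
    for c in clusters:
        assert c.p >= 1.0 / 64 - 1e-12


def test_monte_carlo_p_floor():
    # 12 subjects, n_perm=200 < 2^12: add-one estimator, floor 1/201
    rng = np.random.default_rng(3)
    data = rng.standard_normal((12, 20)) + 2.0
    clusters = cluster_test_1d(data, n_perm=200, seed=0)
    assert clusters
    assert min(c.p for c in clusters) >= 1.0 / 201 - 1e-12


def test_monte_carlo_matches_exhaustive_enumeration():
    """MC p-values within 0.01 of the exact 2^10 enumeration (n=10)."""
    rng = np.random.default_rng(4)
    for rep in range(3):
        data = rng.standard_normal((10, 6))
        data[:, 2:5] += 0.8
        exact = cluster_test_1d(data, n_perm=1024, seed=0)   # 2^10 enumerated
        mc = cluster_test_1d(data, n_perm=1000, seed=rep + 1)  # random draws
        assert len(exact) == len(mc)
        for ce, cm in zip(exact, mc):
            assert np.array_equal(ce.members, cm.members)
            assert abs(ce.p - cm.p) <= 0.01


def test_negative_tail():
    rng = np.random.default_rng(5)
    data = rng.standard_normal((8, 30))
    data[:, 5:12] -= 1.5
    pos = cluster_test_1d(data, n_perm=500, seed=0, tail=1)
    neg = cluster_test_1d(data, n_perm=500, seed=0, tail=-1)
    assert not any(c.significant(0.05) for c in pos)
    assert any(c.significant(0.05) for c in neg)


def test_groups_block_flips_are_more_conservative():
    """Duplicating subjects without declaring blocks deflates the null."""
    rng = np.random.default_rng(6)
    base = rng.standard_normal((5, 30))
    base[:, 10:16] += 1.0
    dup = np.vstack([base, base])  # 10 rows, 5 independent subjects
    naive = cluster_test_1d(dup, n_perm=2000, seed=0)
    blocked = cluster_test_1d(dup, n_perm=2000, seed=0,
                              groups=np.tile(np.arange(5), 2))
    p_naive = min(c.p for c in naive)
    p_blocked = min(c.p for c in blocked)
    assert p_blocked >= p_naive
    assert p_blocked >= 1.0 / 32 - 1e-12  # exact with 2^5 patterns


def test_cluster_1d_validation():
    with pytest.raises(ValueError):
        cluster_test_1d(np.zeros((1, 10)))
    with pytest.raises(ValueError):
        cluster_test_1d(np.zeros((4, 10)), tail=0)
    with pytest.raises(ValueError):
        cluster_test_1d(np.full((4, 10), np.nan))
    with pytest.raises(ValueError):
        cluster_test_1d(np.zeros((4, 10)), n_perm=0)


def test_threshold_uses_group_degrees_of_freedom():
    # with groups, the cluster-forming threshold must come from the number of
    # independent blocks; check via a borderline t value
    rng = np.random.default_rng(7)
    n_blocks = 5
    t_lo = stats.t.ppf(0.95, df=n_blocks - 1)   # 2.13
    t_hi = stats.t.ppf(0.95, df=9)              # 1.83
    base = rng.standard_normal((n_blocks, 8))
    # craft one bin whose duplicated-sample t sits between the two thresholds
    dup = np.vstack([base, base])
    tt = dup.mean(0) / (dup.std(0, ddof=1) / np.sqrt(10))
    sel = (tt > t_hi) & (tt < t_lo)
    if sel.any():
        blocked = cluster_test_1d(dup, n_perm=64, seed=0,
                                  groups=np.tile(np.arange(n_blocks), 2))
        for c in blocked:
            assert not np.isin(np.flatnonzero(sel), c.members).any()


# ---------------------------------------------------------------------------
# spatiotemporal test
# ---------------------------------------------------------------------------

def test_grid_adjacency_neighbor_counts():
    mask = np.ones((3, 3, 3), dtype=bool)
    for conn, expected in ((6, 6), (18, 18), (26, 26)):
        A = grid_adjacency(mask, connectivity=conn)
        center = 13  # voxel (1,1,1) in flat order of a full mask
        assert A[center].getnnz() == expected
    with pytest.raises(ValueError):
        grid_adjacency(mask, connectivity=4)


def test_single_voxel_spatiotemporal_equals_1d():
    rng = np.random.default_rng(8)
    data = rng.standard_normal((8, 35))
    data[:, 12:20] += 1.2
    mask = np.ones((1, 1, 1), dtype=bool)
    adj = grid_adjacency(mask)
    st_clusters = cluster_test_spatiotemporal(data[:, None, :], adj,
                                              n_perm=500, seed=9)
    d1_clusters = cluster_test_1d(data, n_perm=500, seed=9)
    assert len(st_clusters) == len(d1_clusters)
    for cs, c1 in zip(st_clusters, d1_clusters):
        assert np.array_equal(np.sort(cs.members[:, 1]), c1.members)
        assert cs.p == c1.p
        assert cs.mass == pytest.approx(c1.mass)


def test_spatiotemporal_planted_blob():
    rng = np.random.default_rng(10)
    mask = np.ones((4, 4, 4), dtype=bool)
    n_vox = 64
    data = rng.standard_normal((8, n_vox, 12))
    blob_vox = [21, 22, 25]  # contiguous under 6-connectivity
    for v in blob_vox:
        data[:, v, 4:9] += 1.8
    clusters = cluster_test_spatiotemporal(data, grid_adjacency(mask),
                                           n_perm=300, seed=0)
    sig = [c for c in clusters if c.significant(0.05)]
    assert sig
    big = max(sig, key=lambda c: c.mass)
    got_vox = set(big.members[:, 0])
    assert set(blob_vox) <= got_vox


def test_spatiotemporal_respects_disconnection():
    # two voxels that are NOT adjacent: one simultaneous effect must form two
    # clusters, not one
    rng = np.random.default_rng(11)
    mask = np.zeros((3, 1, 1), dtype=bool)
    mask[0] = mask[2] = True  # voxels 0 and 2, separated
    data = rng.standard_normal((8, 2, 10)) * 0.1
    data[:, :, 3:7] += 2.0
    clusters = cluster_test_spatiotemporal(data, grid_adjacency(mask),
                                           n_perm=200, seed=1)
    assert len(clusters) == 2


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def test_fdr_hand_arithmetic():
    adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04)
    adj2 = fdr_adjust([0.005, 0.04, 0.9])
    # 0.005*3/1 = 0.015; 0.04*3/2 = 0.06 (cummin with 0.9) ; 0.9
    assert np.allclose(adj2, [0.015, 0.06, 0.9])


def test_fdr_validation_and_shape():
    assert fdr_adjust(np.zeros((0,))).size == 0
    out = fdr_adjust(np.array([[0.01, 0.5], [0.2, 1.0]]))
    assert out.shape == (2, 2)
    with pytest.raises(ValueError):
        fdr_adjust([0.1, 1.5])
    with pytest.raises(ValueError):
        fdr_adjust([0.1, np.nan])


def test_cluster_result_significance():
    c = ClusterResult(members=np.arange(3), mass=5.0, p=0.049)
    assert c.significant(0.05) and not c.significant(0.01)
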