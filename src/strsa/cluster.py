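"""One-sample suprathreshold-cluster permutation inference over time and over
voxel x time, plus Benjamini-Hochberg FDR adjustment.

The null is generated by random per-subject sign flips of the whole series
(the standard one-sample randomization; whole-series flips preserve temporal
autocorrelation). Clusters are formed from bins whose one-sample t exceeds
the one-tailed t threshold at ``alpha_form`` (df = n_subjects - 1); the
observed cluster mass (sum of member t values) is compared against the
distribution of the maximum cluster mass over permutations, with the add-one
estimator ``p = (1 + #{null >= observed}) / (1 + n_perm)`` so p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = ["ClusterResult", "cluster_test_1d", "cluster_test_spatiotemporal",
           "grid_adjacency", "fdr_adjust"]


@dataclass
class ClusterResult:
    """A suprathreshold cluster with its permutation p-value.

    members : bin indices (1-D test) or (voxel, bin) index pairs
    mass : sum of member t statistics
    """

    members: np.ndarray = field(repr=False)
    mass: float
    p: float
    onset_ms: float | None = None
    offset_ms: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p <= alpha


def _sign_flips(rng: np.random.Generator, n_perm: int, n_subjects: int) -> np.ndarray:
    return rng.integers(0, 2, size=(n_perm, n_subjects)) * 2.0 - 1.0


def _n_groups(groups: np.ndarray | None, n_sub: int) -> int:
    if groups is None:
        return n_sub
    groups = np.asarray(groups)
    if len(groups) != n_sub:
        raise ValueError("groups length must match the subject axis")
    return int(groups.max()) + 1


def _expand_groups(signs: np.ndarray, groups: np.ndarray | None) -> np.ndarray:
    return signs if groups is None else signs[:, np.asarray(groups)]


def _null_signs(rng: np.random.Generator, n_perm: int, n_sub: int,
                groups: np.ndarray | None) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix for the null distribution.

    When every distinct assignment fits in the permutation budget
    (2^k <= n_perm for k flip groups), all of them are enumerated and the
    test is exact; otherwise n_perm random draws are used with the add-one
    estimator. Returns (signs expanded to subjects, exact flag).
    """
    k = _n_groups(groups, n_sub)
    if 2 ** k <= n_perm:
        patterns = ((np.arange(2 ** k)[:, None] >> np.arange(k)) & 1) * 2.0 - 1.0
        return _expand_groups(patterns, groups), True
    return _expand_groups(_sign_flips(rng, n_perm, k), groups), False


def _perm_p(null_max: np.ndarray, mass: float, exact: bool) -> float:
    hits = float(np.sum(null_max >= mass))
    if exact:
        return hits / len(null_max)  # identity flip always counts: p > 0
    return (1.0 + hits) / (1.0 + len(null_max))


def _t_from_flips(data2d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t maps for every sign-flip row. data2d: subjects x points."""
    n = data2d.shape[0]
    sq = (data2d ** 2).sum(axis=0)  # invariant under sign flips
    m = signs @ data2d / n
    var = (sq - n * m ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / n)
    return t


@njit(cache=True)
def _max_run_mass(t: np.ndarray, thresh: float) -> np.ndarray:
    """Max contiguous suprathreshold mass per row of a perms x bins t matrix."""
    n_perm, n_bins = t.shape
    out = np.zeros(n_perm)
    for p in range(n_perm):
        best = 0.0
        cur = 0.0
        for b in range(n_bins):
            v = t[p, b]
            if np.isfinite(v) and v > thresh:
                cur += v
            else:
                if cur > best:
                    best = cur
                cur = 0.0
        if cur > best:
            best = cur
        out[p] = best
    return out


def _observed_runs(t: np.ndarray, thresh: float):
    """Contiguous suprathreshold runs of a 1-D t series -> (indices, mass)."""
    exceed = np.isfinite(t) & (t > thresh)
    runs = []
    start = None
    for b in range(len(t) + 1):
        on = b < len(t) and exceed[b]
        if on and start is None:
            start = b
        elif not on and start is not None:
            idx = np.arange(start, b)
            runs.append((idx, float(t[idx].sum())))
            start = None
    return runs


def cluster_test_1d(data: np.ndarray, alpha_form: float = 0.05,
                    n_perm: int = 10000, tail: int = 1, seed: int = 0,
                    times_ms: np.ndarray | None = None,
                    groups: np.ndarray | None = None) -> list[ClusterResult]:
    """One-sample cluster permutation test over a subjects x bins matrix.

    Returns every suprathreshold cluster (callers filter by
    ``ClusterResult.significant(alpha)``). ``tail=+1`` tests for positive
    deviations; ``tail=-1`` flips the sign of the data first. Zero-variance
    bins have no defined t and are excluded (with a warning).

    ``groups`` assigns rows to exchangeability blocks that share one sign per
    permutation. Bootstrap resamples that duplicate a subject must flip the
    duplicates together, otherwise copies of one subject masquerade as
    independent evidence and the null is deflated.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("data must be subjects x bins with >= 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in (1, -1):
        raise ValueError("tail must be +1 or -1")
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    if tail == -1:
        data = -data

    n_sub, n_bins = data.shape
    # duplicated rows (bootstrap resamples) do not add degrees of freedom:
    # the cluster-forming threshold uses the number of exchangeability blocks
    thresh = stats.t.ppf(1 - alpha_form, df=_n_groups(groups, n_sub) - 1)

    t_obs = _t_from_flips(data, np.ones((1, n_sub)))[0]
    if np.any(~np.isfinite(t_obs)):
        warnings.warn("zero-variance bins excluded from cluster formation",
                      stacklevel=2)
    runs = _observed_runs(t_obs, thresh)

    rng = np.random.default_rng(seed)
    signs, exact = _null_signs(rng, n_perm, n_sub, groups)
    t_null = _t_from_flips(data, signs)
    t_null = np.where(np.isfinite(t_null), t_null, -np.inf)
    null_max = _max_run_mass(t_null, thresh)

    results = []
    for idx, mass in runs:
        p = _perm_p(null_max, mass, exact)
        onset = offset = None
        if times_ms is not None:
            onset, offset = float(times_ms[idx[0]]), float(times_ms[idx[-1]])
        results.append(ClusterResult(members=idx, mass=mass, p=float(p),
                                     onset_ms=onset, offset_ms=offset))
    return results


def grid_adjacency(mask: np.ndarray, connectivity: int = 6) -> sparse.csr_matrix:
    """Voxel adjacency (in-mask voxels only) on a 3-D grid.

    connectivity 6 (faces), 18 (faces+edges) or 26 (faces+edges+corners).
    Returned matrix is indexed by position within ``np.flatnonzero(mask)``.
    """
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18, or 26")
    mask = np.asarray(mask, dtype=bool)
    flat_to_local = -np.ones(mask.size, dtype=np.int64)
    in_idx = np.flatnonzero(mask.ravel())
    flat_to_local[in_idx] = np.arange(len(in_idx))
    coords = np.array(np.unravel_index(in_idx, mask.shape)).T

    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = abs(dx) + abs(dy) + abs(dz)
                if d == 0:
                    continue
                if connectivity == 6 and d > 1:
                    continue
                if connectivity == 18 and d > 2:
                    continue
                offsets.append((dx, dy, dz))
    rows, cols = [], []
    for off in offsets:
        nb = coords + np.array(off)
        ok = np.all((nb >= 0) & (nb < np.array(mask.shape)), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, mask.shape)
        local = flat_to_local[nb_flat]
        valid = local >= 0
        rows.extend(np.flatnonzero(ok)[valid])
        cols.extend(local[valid])
    n = len(in_idx)
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return A


def _spatiotemporal_graph(adjacency: sparse.spmatrix, n_vox: int,
                          n_bins: int) -> sparse.csr_matrix:
    """Node graph over voxel x bin: spatial edges within a bin, temporal
    edges between consecutive bins of the same voxel."""
    A = sparse.csr_matrix(adjacency)
    if A.shape != (n_vox, n_vox):
        raise ValueError(f"adjacency shape {A.shape} does not match {n_vox} voxels")
    spatial = sparse.kron(sparse.eye(n_bins, format="csr"), A, format="csr")
    shift = sparse.diags([np.ones(n_bins - 1)], [1], format="csr")
    temporal = sparse.kron(shift + shift.T, sparse.eye(n_vox, format="csr"),
                           format="csr")
    return (spatial + temporal).tocsr()


def _max_component_mass(graph: sparse.csr_matrix, tflat: np.ndarray,
                        thresh: float) -> float:
    nodes = np.flatnonzero(np.isfinite(tflat) & (tflat > thresh))
    if len(nodes) == 0:
        return 0.0
    sub = graph[nodes][:, nodes]
    _, labels = connected_components(sub, directed=False)
    masses = np.bincount(labels, weights=tflat[nodes])
    return float(masses.max())


def cluster_test_spatiotemporal(data: np.ndarray, adjacency,
                                alpha_form: float = 0.05, n_perm: int = 1000,
                                tail: int = 1, seed: int = 0,
                                times_ms: np.ndarray | None = None,
                                groups: np.ndarray | None = None
                                ) -> list[ClusterResult]:
    """One-sample cluster permutation test over subjects x voxels x bins.

    Clusters are connected components in the graph (voxel adjacency) x
    (temporal contiguity). With a single voxel and the same seed this
    reproduces :func:`cluster_test_1d` exactly. Disconnected masks are
    allowed: components simply cannot span the disconnection.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("data must be subjects x voxels x bins, >= 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail == -1:
        data = -data
    elif tail != 1:
        raise ValueError("tail must be +1 or -1")

    n_sub, n_vox, n_bins = data.shape
    thresh = stats.t.ppf(1 - alpha_form, df=_n_groups(groups, n_sub) - 1)
    graph = _spatiotemporal_graph(adjacency, n_vox, n_bins)

    # node index = bin * n_vox + vox, matching the kron ordering above
    flat = np.ascontiguousarray(data.transpose(0, 2, 1).reshape(n_sub, -1))

    t_obs = _t_from_flips(flat, np.ones((1, n_sub)))[0]
    if np.any(~np.isfinite(t_obs)):
        warnings.warn("zero-variance voxel/bin cells excluded from clusters",
                      stacklevel=2)

    nodes = np.flatnonzero(np.isfinite(t_obs) & (t_obs > thresh))
    clusters = []
    if len(nodes):
        sub = graph[nodes][:, nodes]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members_flat = nodes[labels == c]
            bins = members_flat // n_vox
            voxels = members_flat % n_vox
            mass = float(t_obs[members_flat].sum())
            onset = offset = None
            if times_ms is not None:
                onset = float(times_ms[bins.min()])
                offset = float(times_ms[bins.max()])
            clusters.append((np.column_stack([voxels, bins]), mass, onset, offset))

    rng = np.random.default_rng(seed)
    signs, exact = _null_signs(rng, n_perm, n_sub, groups)
    t_null = _t_from_flips(flat, signs)
    null_max = np.array([
        _max_component_mass(graph, t_null[p], thresh)
        for p in range(signs.shape[0])
    ])

    results = []
    for members, mass, onset, offset in clusters:
        p = _perm_p(null_max, mass, exact)
        results.append(ClusterResult(members=members, mass=mass, p=float(p),
                                     onset_ms=onset, offset_ms=offset))
    return results


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
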