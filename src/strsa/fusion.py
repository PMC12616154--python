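"""fMRI searchlight RDM mapping, EEG-fMRI fusion, and fusion-based RSA.

Searchlight: for every in-mask voxel, the condition beta patterns of all
voxels within a Euclidean sphere are compared pairwise by Spearman
correlation and stored as ``1 - r`` dissimilarities at the center voxel, per
subject; the subject-averaged map is block-mean resampled to a coarser output
grid. Fusion: each EEG subject's time-resolved RDM is rank-correlated with
the group fMRI-RDM of every voxel, Fisher-z transformed, giving a subjects x
voxels x time map fed to the spatiotemporal cluster test. Fusion-based RSA
then relates cluster-restricted fMRI RDMs (per fMRI subject) to model RDMs,
time-averaged over the cluster's union mask or time-resolved over its
per-bin spatial extent, with BH-FDR over all (cluster, model) tests.

Note the design is asymmetric by construction: EEG and fMRI come from
different samples, so fusion is computed per EEG subject against the
group-average fMRI map, while fusion-based RSA uses per-subject fMRI RDMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .cluster import (ClusterResult, cluster_test_1d,
                      cluster_test_spatiotemporal, fdr_adjust, grid_adjacency)
from .containers import NeuralRDMStack
from .rdm import ModelSet, fisher_z
from .rsa import _rank_rows
from .synth import BetaImages

__all__ = ["VoxelRDMMap", "FusionMap", "searchlight_rdms", "fuse",
           "fusion_cluster_test", "cluster_masks", "fusion_rsa_timeaveraged",
           "fusion_rsa_timeresolved"]


@dataclass
class VoxelRDMMap:
    """Group-averaged searchlight RDMs on an output grid.

    vectors : in-mask voxels x n_pairs, 1 - Spearman dissimilarities in [0, 2]
    mask : boolean output grid; vectors rows follow np.flatnonzero(mask)
    """

    vectors: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    affine: np.ndarray
    voxel_size_mm: float
    n_skipped: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.vectors.shape[0] != int(self.mask.sum()):
            raise ValueError("one RDM vector per in-mask voxel required")


@dataclass
class FusionMap:
    """EEG-subject x voxel x time-bin map of Fisher-z Spearman correlations."""

    z: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    times_ms: np.ndarray
    affine: np.ndarray
    voxel_size_mm: float


def _sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    r_vox = int(np.floor(radius_mm / voxel_size_mm))
    rng = np.arange(-r_vox, r_vox + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    d = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2) * voxel_size_mm
    keep = d <= radius_mm + 1e-9
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def _spearman_rdm_vectors(patterns: np.ndarray) -> np.ndarray:
    """1 - Spearman pairwise dissimilarity vector(s) from condition patterns.

    patterns: ... x n_cond x n_features; returns ... x n_pairs in tril order.
    Rank-degenerate patterns (constant across features) give NaN entries.
    """
    ranks = rankdata(patterns, axis=-1).astype(float)
    ranks -= ranks.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(ranks, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ranks = ranks / norm
    corr = ranks @ np.swapaxes(ranks, -1, -2)
    n = patterns.shape[-2]
    i, j = np.tril_indices(n, -1)
    return 1.0 - corr[..., i, j]


def searchlight_rdms(betas: BetaImages, radius_mm: float = 6.0,
                     out_voxel_mm: float = 4.0) -> VoxelRDMMap:
    """Whole-brain searchlight RDM map, subject-averaged and resampled.

    Per center voxel and subject, the RDM over conditions is computed from
    the in-mask voxels within ``radius_mm`` (center included; centers with
    fewer than 2 in-mask sphere voxels are skipped). Rank-degenerate spheres
    yield missing RDMs and are excluded from the subject average. Resampling
    to ``out_voxel_mm`` is a block mean over child voxels carrying data.
    """
    vs = betas.voxel_size_mm
    factor = out_voxel_mm / vs
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("output voxel size must be an integer multiple of "
                         "the input voxel size")
    factor = int(round(factor))
    mask = betas.mask
    shape = mask.shape
    S, C = betas.n_subjects, betas.n_conditions
    n_pairs = C * (C - 1) // 2

    offsets = _sphere_offsets(radius_mm, vs)
    centers = np.array(np.nonzero(mask)).T
    flat = betas.data.reshape(S, C, -1)

    fine = np.full((len(centers), n_pairs), np.nan)
    n_skipped = 0
    degenerate = 0
    for ci, c in enumerate(centers):
        nb = c + offsets
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb = nb[ok]
        nb_flat = np.ravel_multi_index(nb.T, shape)
        nb_flat = nb_flat[mask.ravel()[nb_flat]]
        if len(nb_flat) < 2:
            n_skipped += 1
            continue
        rdms = _spearman_rdm_vectors(flat[:, :, nb_flat])  # S x pairs
        bad = np.any(~np.isfinite(rdms), axis=1)
        degenerate += int(bad.sum())
        if bad.all():
            n_skipped += 1
            continue
        fine[ci] = rdms[~bad].mean(axis=0)
    if n_skipped or degenerate:
        warnings.warn(f"searchlight: {n_skipped} centers skipped, "
                      f"{degenerate} rank-degenerate subject RDMs excluded",
                      stacklevel=2)

    # block-mean resampling to the output grid
    out_shape = tuple(int(np.ceil(s / factor)) for s in shape)
    parent = (centers // factor)
    parent_flat = np.ravel_multi_index(parent.T, out_shape)
    out_mask = np.zeros(out_shape, dtype=bool)
    sums = np.zeros((int(np.prod(out_shape)), n_pairs))
    counts = np.zeros(int(np.prod(out_shape)))
    has_data = np.all(np.isfinite(fine), axis=1)
    np.add.at(sums, parent_flat[has_data], fine[has_data])
    np.add.at(counts, parent_flat[has_data], 1)
    out_mask.ravel()[parent_flat[has_data]] = True
    out_idx = np.flatnonzero(out_mask.ravel())
    vectors = sums[out_idx] / counts[out_idx, None]

    T = np.eye(4)
    T[:3, :3] *= factor
    T[:3, 3] = (factor - 1) / 2.0
    return VoxelRDMMap(vectors=vectors, mask=out_mask,
                       affine=betas.affine @ T,
                       voxel_size_mm=vs * factor, n_skipped=n_skipped)


def fuse(stacks: list[NeuralRDMStack], vmap: VoxelRDMMap,
         window_ms: tuple = (-100.0, 700.0)) -> FusionMap:
    """Correlate every EEG subject's time-resolved RDMs with every voxel's
    group fMRI-RDM (Spearman, Fisher-z), restricted to a time window.

    Rank-degenerate vectors on either side contribute z = 0 (warned).
    """
    ref = stacks[0]
    n = len(ref.labels)
    if vmap.vectors.shape[1] != n * (n - 1) // 2:
        raise ValueError("EEG and fMRI RDMs disagree on condition count")
    for s in stacks[1:]:
        if not np.array_equal(s.labels, ref.labels):
            raise ValueError("EEG subjects disagree on condition labels")
    sel = (ref.times_ms >= window_ms[0]) & (ref.times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("window does not intersect the EEG time axis")
    times = ref.times_ms[sel]

    rv = _rank_rows(vmap.vectors)  # V x P (zero rows where degenerate)
    if np.any(np.all(rv == 0, axis=1)):
        warnings.warn("rank-degenerate voxel RDMs contribute z = 0",
                      stacklevel=2)
    z = np.empty((len(stacks), vmap.vectors.shape[0], sel.sum()))
    for si, s in enumerate(stacks):
        re = _rank_rows(s.vectors[sel])  # B x P
        rho = rv @ re.T  # V x B
        z[si] = fisher_z(np.clip(rho, -1.0, 1.0))
    return FusionMap(z=z, mask=vmap.mask, times_ms=times, affine=vmap.affine,
                     voxel_size_mm=vmap.voxel_size_mm)


def fusion_cluster_test(fmap: FusionMap, connectivity: int = 6,
                        alpha_form: float = 0.05, n_perm: int = 1000,
                        seed: int = 0, test_window_ms: tuple | None = (0.0, 700.0)
                        ) -> list[ClusterResult]:
    """Spatiotemporal cluster test of the fusion map against zero.

    Cluster member bin indices refer to the tested window's time axis
    (``fmap.times_ms`` filtered by ``test_window_ms``).
    """
    adj = grid_adjacency(fmap.mask, connectivity=connectivity)
    if test_window_ms is None:
        sel = np.ones(len(fmap.times_ms), dtype=bool)
    else:
        sel = (fmap.times_ms >= test_window_ms[0]) & \
              (fmap.times_ms <= test_window_ms[1])
    return cluster_test_spatiotemporal(
        fmap.z[:, :, sel], adj, alpha_form=alpha_form, n_perm=n_perm,
        seed=seed, times_ms=fmap.times_ms[sel])


def cluster_masks(fmap: FusionMap, clusters: list[ClusterResult],
                  alpha: float = 0.05) -> list[dict]:
    """Binary masks for each significant spatiotemporal cluster.

    Per cluster: ``union`` (voxels belonging to the cluster at any bin) and
    ``per_bin`` (bin index -> spatial extent at that bin; always a subset of
    the union). Returns an empty list when nothing is significant.
    """
    in_mask_idx = np.flatnonzero(fmap.mask.ravel())
    out = []
    for c in clusters:
        if not c.significant(alpha):
            continue
        voxels = c.members[:, 0]
        bins = c.members[:, 1]
        union = np.zeros(fmap.mask.shape, dtype=bool)
        union.ravel()[in_mask_idx[np.unique(voxels)]] = True
        per_bin = {}
        for b in np.unique(bins):
            m = np.zeros(fmap.mask.shape, dtype=bool)
            m.ravel()[in_mask_idx[voxels[bins == b]]] = True
            per_bin[int(b)] = m
        out.append({"union": union, "per_bin": per_bin, "cluster": c})
    return out


def _map_mask_to_betas(mask_coarse: np.ndarray, factor: int,
                       betas: BetaImages) -> np.ndarray:
    """Expand an output-grid mask back to the beta grid (block children)."""
    fine = np.kron(mask_coarse, np.ones((factor,) * 3, dtype=bool))
    fine = fine[tuple(slice(0, s) for s in betas.mask.shape)]
    return fine & betas.mask


def _cluster_model_z(betas: BetaImages, voxel_mask: np.ndarray,
                     models: ModelSet) -> np.ndarray:
    """Per-subject Fisher-z Spearman of the cluster RDM with each model.

    Returns subjects x models.
    """
    idx = np.flatnonzero(voxel_mask.ravel())
    if len(idx) == 0:
        raise ValueError("empty cluster mask")
    flat = betas.data.reshape(betas.n_subjects, betas.n_conditions, -1)
    rdms = _spearman_rdm_vectors(flat[:, :, idx])  # S x pairs
    rm = _rank_rows(models.matrix().T)  # k x pairs
    rs = _rank_rows(np.nan_to_num(rdms))
    rho = rs @ rm.T
    return fisher_z(np.clip(rho, -1.0, 1.0))


def fusion_rsa_timeaveraged(masks: list[dict], betas: BetaImages,
                            models: ModelSet, beta_factor: int,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Time-averaged fusion-based RSA over each cluster's union mask.

    Per fMRI subject: the cluster RDM from all in-mask beta voxels is
    Spearman-correlated with each model, Fisher-z transformed, and the group
    of z values tested against zero (one-tailed one-sample t). P-values are
    BH-FDR adjusted over models x clusters.
    """
    rows = []
    for k, entry in enumerate(masks):
        vm = _map_mask_to_betas(entry["union"], beta_factor, betas)
        z = _cluster_model_z(betas, vm, models)  # S x k_models
        tvals = z.mean(0) / (z.std(0, ddof=1) / np.sqrt(z.shape[0]))
        pvals = t_dist.sf(tvals, df=z.shape[0] - 1)
        for j, name in enumerate(models.names):
            rows.append({"cluster": k, "model": name, "mean_z": z[:, j].mean(),
                         "t": tvals[j], "p": pvals[j]})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_fdr"] = fdr_adjust(df["p"].to_numpy())
        df["significant"] = df["p_fdr"] <= alpha
    return df


def fusion_rsa_timeresolved(masks: list[dict], betas: BetaImages,
                            models: ModelSet, beta_factor: int,
                            times_ms: np.ndarray, alpha: float = 0.05,
                            alpha_form: float = 0.05, n_perm: int = 1000,
                            seed: int = 0) -> pd.DataFrame:
    """Time-resolved fusion-based RSA over each cluster's per-bin extent.

    Per bin in a cluster's span, the bin-specific voxel set defines the
    cluster RDM; the per-subject model-correlation z time courses go through
    the temporal cluster test, and all resulting temporal-cluster p-values
    are BH-FDR adjusted jointly over models and fusion clusters. Bins whose
    expanded mask is empty on the beta grid are skipped (logged).
    """
    rows = []
    for k, entry in enumerate(masks):
        bins = sorted(entry["per_bin"].keys())
        z_tc = []  # per kept bin: S x models
        kept_bins = []
        for b in bins:
            vm = _map_mask_to_betas(entry["per_bin"][b], beta_factor, betas)
            if not vm.any():
                warnings.warn(f"cluster {k}: bin {b} has an empty beta-grid "
                              "mask; skipped", stacklevel=2)
                continue
            z_tc.append(_cluster_model_z(betas, vm, models))
            kept_bins.append(b)
        if len(kept_bins) < 2:
            continue
        z_tc = np.stack(z_tc, axis=-1)  # S x models x bins
        bin_times = times_ms[np.asarray(kept_bins)]
        for j, name in enumerate(models.names):
            clusters = cluster_test_1d(z_tc[:, j, :], alpha_form=alpha_form,
                                       n_perm=n_perm,
                                       seed=(seed + 7919 * k + j) % (2**31),
                                       times_ms=bin_times)
            for c in clusters:
                rows.append({"cluster": k, "model": name, "mass": c.mass,
                             "onset_ms": c.onset_ms, "offset_ms": c.offset_ms,
                             "p": c.p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_fdr"] = fdr_adjust(df["p"].to_numpy())
        df["significant"] = df["p_fdr"] <= alpha
    return df
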