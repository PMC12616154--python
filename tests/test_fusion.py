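"""Unit tests for the searchlight, EEG-fMRI fusion, and fusion-based RSA."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from strsa.containers import NeuralRDMStack
from strsa.fusion import (_map_mask_to_betas, _sphere_offsets, cluster_masks,
                          fuse, fusion_cluster_test, fusion_rsa_timeaveraged,
                          searchlight_rdms)
from strsa.rdm import ModelRDM, ModelSet, normalize_model
from strsa.synth import BetaImages, GeometrySpec, PlantedGeometry, \
    generate_beta_volumes


def _betas(data, mask=None, voxel_mm=2.0):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[2:], dtype=bool)
    return BetaImages(data=data, mask=mask,
                      affine=np.diag([voxel_mm] * 3 + [1.0]),
                      voxel_size_mm=voxel_mm,
                      condition_labels=np.arange(data.shape[1]))


def test_sphere_offsets_counts():
    # 6 mm radius on a 2 mm grid: all integer offsets with norm <= 3
    offs = _sphere_offsets(6.0, 2.0)
    assert len(offs) == 123
    assert (offs == 0).all(axis=1).sum() == 1  # center included
    # 6 mm radius on a 4 mm grid: norm <= 1.5 -> center, 6 faces, 12 edges
    assert len(_sphere_offsets(6.0, 4.0)) == 19
    # radius below the voxel size: center only
    assert len(_sphere_offsets(1.0, 2.0)) == 1


def test_searchlight_rdm_values_match_direct_spearman():
    rng = np.random.default_rng(0)
    shape = (5, 5, 5)
    data = rng.standard_normal((2, 4, *shape))
    betas = _betas(data)
    vmap = searchlight_rdms(betas, radius_mm=2.0, out_voxel_mm=2.0)
    assert vmap.vectors.shape == (125, 6)
    # reproduce the center voxel (2,2,2): sphere = center + 6 faces
    offs = _sphere_offsets(2.0, 2.0)
    nb = np.array([2, 2, 2]) + offs
    flat = np.ravel_multi_index(nb.T, shape)
    expected = np.zeros(6)
    for s in range(2):
        pats = data[s].reshape(4, -1)[:, flat]
        k = 0
        vec = []
        for i in range(4):
            for j in range(i):
                vec.append(1 - spearmanr(pats[i], pats[j]).statistic)
        expected += np.array(vec)
    expected /= 2
    center_row = np.ravel_multi_index((2, 2, 2), shape)
    assert np.allclose(vmap.vectors[center_row], expected, atol=1e-10)


def test_searchlight_resampling_block_mean():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((1, 3, 4, 4, 4))
    betas = _betas(data)
    fine = searchlight_rdms(betas, radius_mm=2.0, out_voxel_mm=2.0)
    coarse = searchlight_rdms(betas, radius_mm=2.0, out_voxel_mm=4.0)
    assert coarse.mask.shape == (2, 2, 2)
    assert coarse.voxel_size_mm == 4.0
    # the (0,0,0) output voxel averages the 8 fine RDMs of its child block
    children = [np.ravel_multi_index((x, y, z), (4, 4, 4))
                for x in range(2) for y in range(2) for z in range(2)]
    assert np.allclose(coarse.vectors[0],
                       fine.vectors[children].mean(axis=0), atol=1e-12)
    # affine maps output voxel (0,0,0) to the block center in mm
    assert np.allclose(coarse.affine[:3, 3], 2.0 * 0.5)


def test_searchlight_skips_isolated_centers():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[0, 0, 0] = True
    mask[4, 4, 4] = True
    data = np.random.default_rng(2).standard_normal((1, 3, 5, 5, 5))
    with pytest.warns(UserWarning):
        vmap = searchlight_rdms(_betas(data, mask), radius_mm=2.0,
                                out_voxel_mm=2.0)
    assert vmap.n_skipped == 2
    assert vmap.vectors.shape[0] == 0


def test_searchlight_rejects_non_integer_factor():
    data = np.zeros((1, 3, 4, 4, 4))
    with pytest.raises(ValueError):
        searchlight_rdms(_betas(data), out_voxel_mm=3.0)


def test_fuse_values_and_window():
    rng = np.random.default_rng(3)
    n_pairs = 10
    vox_vectors = rng.random((4, n_pairs))
    vmap_mask = np.zeros((2, 2, 1), dtype=bool)
    vmap_mask[:, :, 0] = True
    from strsa.fusion import VoxelRDMMap
    vmap = VoxelRDMMap(vectors=vox_vectors, mask=vmap_mask,
                       affine=np.eye(4), voxel_size_mm=4.0)
    times = np.arange(-100.0, 300.0, 10.0)
    stacks = [NeuralRDMStack(vectors=rng.random((len(times), n_pairs)),
                             labels=np.arange(5), times_ms=times, subject=s)
              for s in range(3)]
    fmap = fuse(stacks, vmap, window_ms=(0.0, 200.0))
    sel = (times >= 0) & (times <= 200)
    assert fmap.z.shape == (3, 4, sel.sum())
    # spot check one cell against scipy
    b = 3
    expected = np.arctanh(spearmanr(stacks[1].vectors[sel][b],
                                    vox_vectors[2]).statistic)
    assert fmap.z[1, 2, b] == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        fuse(stacks, vmap, window_ms=(9000.0, 9999.0))


def test_cluster_masks_union_and_per_bin():
    from strsa.cluster import ClusterResult
    mask = np.zeros((2, 2, 1), dtype=bool)
    mask[:, :, 0] = True
    from strsa.fusion import FusionMap
    fmap = FusionMap(z=np.zeros((2, 4, 3)), mask=mask,
                     times_ms=np.arange(3) * 10.0, affine=np.eye(4),
                     voxel_size_mm=4.0)
    members = np.array([[0, 0], [1, 0], [1, 1]])  # voxels 0,1 at bins 0,1
    sig = ClusterResult(members=members, mass=10.0, p=0.01)
    ns = ClusterResult(members=np.array([[2, 2]]), mass=2.0, p=0.5)
    out = cluster_masks(fmap, [sig, ns], alpha=0.05)
    assert len(out) == 1
    assert out[0]["union"].sum() == 2
    assert out[0]["per_bin"][0].sum() == 2
    assert out[0]["per_bin"][1].sum() == 1
    for b, m in out[0]["per_bin"].items():
        assert not (m & ~out[0]["union"]).any()


def test_map_mask_to_betas_kron_expansion():
    coarse = np.zeros((2, 2, 2), dtype=bool)
    coarse[0, 0, 0] = True
    beta_mask = np.ones((4, 4, 4), dtype=bool)
    beta_mask[0, 0, 0] = False
    betas = _betas(np.zeros((1, 3, 4, 4, 4)), mask=beta_mask)
    fine = _map_mask_to_betas(coarse, 2, betas)
    assert fine.sum() == 7  # 2x2x2 block minus the masked-out corner
    assert fine[:2, :2, :2].sum() == 7 and not fine[2:].any()


def test_fusion_rsa_flags_planted_model_in_roi():
    rng = np.random.default_rng(4)
    n_cond = 8
    target = rng.random(n_cond * (n_cond - 1) // 2)
    mask = np.ones((8, 8, 8), dtype=bool)
    roi = np.zeros_like(mask)
    roi[2:6, 2:6, 2:6] = True
    spec = GeometrySpec(models=(PlantedGeometry("m", target=target,
                                                amplitude=2.0, roi=roi),),
                        noise_sd=1.0, n_subjects=6, seed=5,
                        subject_geometry_jitter=0.3)
    betas = generate_beta_volumes(spec, mask)
    planted = normalize_model(ModelRDM("planted", target))
    foil = normalize_model(ModelRDM("foil", rng.random(len(target))))
    models = ModelSet(members=(planted, foil))
    entry = {"union": roi[::2, ::2, ::2], "per_bin": {0: roi[::2, ::2, ::2]},
             "cluster": None}
    table = fusion_rsa_timeaveraged([entry], betas, models, beta_factor=2)
    assert set(table.model) == {"planted", "foil"}
    trow = table[table.model == "planted"].iloc[0]
    assert trow.significant and trow.mean_z > 0.3
    assert "p_fdr" in table.columns


def test_fusion_cluster_test_finds_planted_spatiotemporal_cluster():
    rng = np.random.default_rng(6)
    mask = np.ones((3, 3, 1), dtype=bool)
    from strsa.fusion import FusionMap
    z = rng.standard_normal((8, 9, 12)) * 0.2
    z[:, 4, 3:8] += 1.0  # center voxel, bins 3..7
    fmap = FusionMap(z=z, mask=mask, times_ms=np.arange(12) * 10.0,
                     affine=np.eye(4), voxel_size_mm=4.0)
    clusters = fusion_cluster_test(fmap, n_perm=300, seed=0,
                                   test_window_ms=None)
    sig = [c for c in clusters if c.significant(0.05)]
    assert sig
    big = max(sig, key=lambda c: c.mass)
    assert 4 in set(big.members[:, 0])
    assert set(big.members[big.members[:, 0] == 4, 1]) >= {4, 5, 6}
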