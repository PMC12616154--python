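"""Unit and property tests for the synthetic-data generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from strsa.rdm import ModelRDM, vectorize
from strsa.synth import (ISI_CHOICES_MS, GeometrySpec, PlantedGeometry,
                         _orthonormal_projection, _raised_cosine_envelope,
                         assign_chunks, embed_geometry, embed_geometry_corr,
                         generate_beta_volumes, generate_behavioral_model_rdms,
                         generate_eeg_epochs, generate_trial_design,
                         make_correlated_model_rdms)


# ---------------------------------------------------------------------------
# Trial design
# ---------------------------------------------------------------------------

@given(n_actions=st.integers(2, 12), n_exemplars=st.sampled_from([2, 4, 6, 12]),
       n_reps=st.integers(1, 3), seed=st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None)
def test_trial_design_invariants(n_actions, n_exemplars, n_reps, seed):
    d = generate_trial_design(n_actions, n_exemplars, n_reps, seed=seed)
    t = d.trials
    assert len(t) == n_actions * n_exemplars * n_reps
    # every stimulus appears exactly n_reps times as S1
    counts = t.groupby(["s1_action", "s1_exemplar"]).size()
    assert len(counts) == n_actions * n_exemplars
    assert (counts == n_reps).all()
    # probes as even as divisibility allows
    pc = t["probe"].value_counts()
    assert pc.max() - pc.min() <= 1
    # within each probe, matches are half (rounded down)
    for probe, grp in t.groupby("probe"):
        assert grp["match"].sum() == len(grp) // 2
    # location probes draw S2 from the same action
    loc = t[t["probe"] == "location"]
    assert (loc["s1_action"] == loc["s2_action"]).all()
    # ISIs come from the study's choices
    assert set(t["isi_ms"]).issubset(set(ISI_CHOICES_MS))
    # stimulus indices in range
    assert t["s2_action"].between(0, n_actions - 1).all()
    assert t["s2_exemplar"].between(0, n_exemplars - 1).all()


def test_trial_design_deterministic():
    a = generate_trial_design(5, 4, 2, seed=11).trials
    b = generate_trial_design(5, 4, 2, seed=11).trials
    assert a.equals(b)
    c = generate_trial_design(5, 4, 2, seed=12).trials
    assert not a.equals(c)


def test_trial_design_action_probe_semantics():
    t = generate_trial_design(6, 4, 2, seed=3).trials
    act = t[t["probe"] == "action"]
    match = act[act["match"]]
    nomatch = act[~act["match"]]
    assert (match["s1_action"] == match["s2_action"]).all()
    assert (nomatch["s1_action"] != nomatch["s2_action"]).all()


def test_trial_design_rejects_bad_args():
    with pytest.raises(ValueError):
        generate_trial_design(1, 4, 2)
    with pytest.raises(ValueError):
        generate_trial_design(4, 6, 1, exemplar_factors=(2, 2, 2))


def test_trial_design_tsv_roundtrip(tmp_path):
    from strsa.synth import TrialDesign
    d = generate_trial_design(4, 4, 2, seed=0)
    p = tmp_path / "design.tsv"
    d.to_tsv(p)
    back = TrialDesign.from_tsv(p, 4, 4, 2)
    assert back.trials.equals(d.trials)


# ---------------------------------------------------------------------------
# Geometry embeddings
# ---------------------------------------------------------------------------

def test_embed_geometry_rank_exact():
    rng = np.random.default_rng(0)
    target = rng.random(45)  # 10 conditions
    X = embed_geometry(target)
    # note pdist orders pairs by upper triangle; re-vectorize to our order
    d = vectorize(squareform(pdist(X)))
    rho = spearmanr(d, target).statistic
    assert rho == pytest.approx(1.0, abs=1e-12)


def test_embed_geometry_corr_rank_exact_under_correlation_metric():
    rng = np.random.default_rng(1)
    target = rng.random(66)  # 12 conditions
    X = embed_geometry_corr(target)
    # rows are unit-norm, so 1 - X X^T is the correlation distance up to
    # centering; the construction guarantees monotonicity in the target
    assert np.allclose((X**2).sum(1), 1.0)
    dissim = vectorize(1.0 - X @ X.T)
    rho = spearmanr(dissim, target).statistic
    assert rho == pytest.approx(1.0, abs=1e-12)


def test_embed_rejects_constant_target():
    with pytest.raises(ValueError):
        embed_geometry(np.ones(6))
    with pytest.raises(ValueError):
        embed_geometry_corr(np.ones(6))


def test_orthonormal_projection_properties():
    rng = np.random.default_rng(2)
    P = _orthonormal_projection(rng, 5, 20)
    assert np.allclose(P @ P.T, np.eye(5), atol=1e-10)
    Pz = _orthonormal_projection(np.random.default_rng(2), 5, 20, zero_mean=True)
    assert np.allclose(Pz @ Pz.T, np.eye(5), atol=1e-10)
    assert np.allclose(Pz.sum(axis=1), 0.0, atol=1e-10)


def test_orthonormal_projection_warns_when_underdetermined():
    with pytest.warns(UserWarning):
        _orthonormal_projection(np.random.default_rng(0), 10, 4)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

def _small_spec(target, seed=0, **kw):
    defaults = dict(noise_sd=1.0, n_subjects=2, n_channels=8, sfreq=100.0,
                    epoch_ms=(-100.0, 400.0), seed=seed, subject_amp_sd=0.0)
    defaults.update(kw)
    return GeometrySpec(
        models=(PlantedGeometry("m", target=target, amplitude=2.0,
                                window_ms=(100.0, 200.0)),), **defaults)


def test_generate_eeg_epochs_shapes_and_determinism():
    rng = np.random.default_rng(0)
    target = rng.random(10)  # 5 conditions
    design = generate_trial_design(5, 6, 2, seed=0)
    spec = _small_spec(target)
    a = generate_eeg_epochs(spec, design)
    b = generate_eeg_epochs(spec, design)
    assert len(a) == 2
    assert a[0].data.shape == (60, 8, 51)
    assert np.array_equal(a[0].data, b[0].data)
    assert np.array_equal(a[1].data, b[1].data)
    assert not np.array_equal(a[0].data, a[1].data)  # noise is per subject


def test_planted_window_carries_geometry_noiseless():
    rng = np.random.default_rng(3)
    target = rng.random(10)
    design = generate_trial_design(5, 6, 2, seed=1)
    spec = _small_spec(target, noise_sd=0.0)
    ep = generate_eeg_epochs(spec, design)[0]
    times = ep.times_ms
    mid = np.flatnonzero((times >= 120) & (times <= 180))  # past the ramps
    out = np.flatnonzero(times < 90)
    # outside the window: zero signal
    assert np.allclose(ep.data[:, :, out], 0.0)
    # inside: per-condition patterns whose Euclidean RDM rank-matches target
    means = np.stack([ep.data[ep.conditions == c][:, :, mid].mean(axis=(0, 2))
                      for c in range(5)])
    rho = spearmanr(vectorize(squareform(pdist(means))), target).statistic
    assert rho == pytest.approx(1.0, abs=1e-12)


def test_envelope_ramps_and_window():
    t = np.arange(0.0, 500.0, 2.0)
    env = _raised_cosine_envelope(t, (100.0, 200.0))
    assert np.all(env[(t < 100) | (t > 200)] == 0)
    assert np.all(env[(t >= 110) & (t <= 190)] == 1.0)
    ramp = env[(t > 100) & (t < 110)]
    assert np.all((ramp > 0) & (ramp < 1)) and np.all(np.diff(ramp) > 0)


def test_assign_chunks_balanced():
    cond = np.repeat(np.arange(4), 12)
    chunks = assign_chunks(cond, n_chunks=6)
    for c in range(4):
        counts = np.bincount(chunks[cond == c], minlength=6)
        assert (counts == 2).all()


def test_eeg_epochs_validates_window():
    target = np.arange(3.0)
    with pytest.raises(ValueError):
        generate_eeg_epochs(
            GeometrySpec(models=(PlantedGeometry("m", target=target,
                                                 window_ms=(100.0, 900.0)),),
                         epoch_ms=(-100.0, 400.0), n_subjects=1,
                         n_channels=4, sfreq=100.0),
            generate_trial_design(3, 4, 2, seed=0))


# ---------------------------------------------------------------------------
# Beta volumes
# ---------------------------------------------------------------------------

def test_generate_beta_volumes_roi_and_mask():
    rng = np.random.default_rng(4)
    target = rng.random(15)  # 6 conditions
    mask = np.ones((8, 8, 8), dtype=bool)
    mask[0] = False
    roi = np.zeros_like(mask)
    roi[3:6, 3:6, 3:6] = True
    spec = GeometrySpec(models=(PlantedGeometry("m", target=target,
                                                amplitude=1.5, roi=roi),),
                        noise_sd=1.0, n_subjects=3, seed=7)
    betas = generate_beta_volumes(spec, mask)
    assert betas.data.shape == (3, 6, 8, 8, 8)
    assert np.all(betas.data[:, :, ~mask] == 0.0)
    # noiseless: the ROI pattern RDM under 1 - corr rank-matches the target
    spec0 = GeometrySpec(models=spec.models, noise_sd=0.0, n_subjects=1,
                         seed=7, subject_amp_sd=0.0)
    b0 = generate_beta_volumes(spec0, mask)
    pat = b0.data[0].reshape(6, -1)[:, roi.ravel()]
    c = np.corrcoef(pat)
    rho = spearmanr(vectorize(1 - c), target).statistic
    assert rho == pytest.approx(1.0, abs=1e-10)


def test_beta_volumes_validate_roi():
    target = np.arange(3.0)
    mask = np.ones((4, 4, 4), dtype=bool)
    mask[0, 0, 0] = False
    bad_roi = np.zeros_like(mask)
    bad_roi[0, 0, 0] = True  # leaves the brain mask
    with pytest.raises(ValueError):
        generate_beta_volumes(
            GeometrySpec(models=(PlantedGeometry("m", target=target,
                                                 roi=bad_roi),),
                         n_subjects=1, seed=0), mask)
    with pytest.raises(ValueError):
        generate_beta_volumes(
            GeometrySpec(models=(PlantedGeometry("m", target=target),),
                         n_subjects=1, seed=0), mask)


# ---------------------------------------------------------------------------
# Model-RDM generators
# ---------------------------------------------------------------------------

def test_make_correlated_model_rdms_exact_correlations():
    from strsa.datasets import MODEL_RDM_CORRELATIONS
    models = make_correlated_model_rdms(MODEL_RDM_CORRELATIONS, 27, seed=0)
    X = np.column_stack([m.vector for m in models])
    R = np.corrcoef(X, rowvar=False)
    assert np.allclose(R, MODEL_RDM_CORRELATIONS, atol=1e-10)
    for m in models:
        assert abs(m.vector.mean()) < 1e-10
        assert abs(m.vector.std() - 1.0) < 1e-10


def _max_transform_alignment(X):
    """Max |corr| between a power of one column (residualized on that
    column's own linear part) and any other column."""
    n, k = X.shape
    worst = 0.0
    for i in range(k):
        Qi, _ = np.linalg.qr(np.column_stack([np.ones(n), X[:, i]]))
        for f in (X[:, i] ** 2, X[:, i] ** 3):
            resid = f - Qi @ (Qi.T @ f)
            for j in range(k):
                if i != j:
                    worst = max(worst, abs(np.corrcoef(resid, X[:, j])[0, 1]))
    return worst


def test_make_correlated_model_rdms_decorrelated_transforms():
    models = make_correlated_model_rdms(np.eye(3), 16, seed=5,
                                        decorrelate_transforms=True)
    X = np.column_stack([m.vector for m in models])
    assert np.allclose(np.corrcoef(X, rowvar=False), np.eye(3), atol=1e-8)
    # chance transform alignments strongly suppressed relative to the plain
    # construction (not zero: the deflation trades off against the exact
    # Pearson structure and the Spearman polish)
    plain = make_correlated_model_rdms(np.eye(3), 16, seed=5)
    Xp = np.column_stack([m.vector for m in plain])
    assert _max_transform_alignment(X) < 0.02
    assert _max_transform_alignment(X) < 0.25 * _max_transform_alignment(Xp)
    # rank-correlation offsets also shaped toward the target (0 here)
    for i in range(3):
        for j in range(3):
            if i != j:
                rho = spearmanr(X[:, i], X[:, j]).statistic
                assert abs(rho) < 0.02


def test_generate_behavioral_model_rdms():
    base = [ModelRDM("a", np.arange(10.0)), ModelRDM("b", np.arange(10.0)[::-1].copy())]
    exact = generate_behavioral_model_rdms(base, noise_sd=0.0, seed=0)
    assert np.array_equal(exact[0].vector, base[0].vector)
    noisy = generate_behavioral_model_rdms(base, noise_sd=1.0, seed=0)
    assert not np.array_equal(noisy[0].vector, base[0].vector)


def test_subject_heterogeneity_changes_patterns_not_means():
    rng = np.random.default_rng(9)
    target = rng.random(10)
    design = generate_trial_design(5, 6, 2, seed=2)
    het = _small_spec(target, noise_sd=0.0, subject_amp_sd=0.5,
                      subject_geometry_jitter=0.3, n_subjects=3)
    eps = generate_eeg_epochs(het, design)
    # subjects differ in their planted signal when heterogeneity is on
    assert not np.allclose(eps[0].data, eps[1].data)
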