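"""Frozen end-to-end recovery benchmarks at desk scale.

Two reference protocols exercise the whole chain on synthetic data with
known ground truth, at a scale that runs on one CPU in minutes. Their
parameters are frozen here so the test suite and the analysis scripts run
the identical computation; see ``docs/methods.md`` for how the scales and
amplitudes were chosen (and why they are smaller than the emulated study).

Latency-order recovery
    Five model geometries (with the published inter-model correlation
    structure) planted at staggered latencies; the protocol decodes the
    simulated EEG, runs multiple-regression RSA, bootstraps each model's
    onset, and checks that the five 95% CIs are non-overlapping and in the
    planted order.

Fusion recovery
    One geometry planted jointly in a voxel ROI and a latency window; the
    protocol runs the searchlight, EEG-fMRI fusion, the spatiotemporal
    cluster test, and fusion-based RSA, and scores the significant cluster
    against the ground-truth (voxel, bin) set by Jaccard overlap plus
    planted-vs-foil model identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .datasets import MODEL_NAMES, MODEL_RDM_CORRELATIONS
from .decoding import bin_samples, neural_rdm_timecourse
from .fusion import (_sphere_offsets, cluster_masks, fuse, fusion_cluster_test,
                     fusion_rsa_timeaveraged, searchlight_rdms)
from .rdm import ModelSet
from .rsa import bootstrap_onset_ci
from .rsa import regression_rsa
from .synth import (GeometrySpec, PlantedGeometry, generate_beta_volumes,
                    generate_eeg_epochs, generate_trial_design,
                    make_correlated_model_rdms)

__all__ = ["LATENCY_PROTOCOL", "FUSION_PROTOCOL", "LatencyRecoveryResult",
           "FusionRecoveryResult", "latency_recovery_replicate",
           "fusion_recovery"]

#: Planted onset order and latencies (ms) for the latency-order benchmark.
LATENCIES_MS = {"alexnet": 80.0, "body": 120.0, "gist": 180.0,
                "people": 200.0, "semantic": 280.0}
#: Models sorted by planted latency.
LATENCY_ORDER = ("alexnet", "body", "gist", "people", "semantic")

LATENCY_PROTOCOL = {
    # design / simulation
    "n_conditions": 16,
    "n_exemplars": 18,
    "n_repetitions": 2,
    "n_subjects": 8,
    "n_channels": 16,
    "sfreq": 100.0,
    "epoch_ms": (-100.0, 500.0),
    "noise_sd": 1.0,
    "subject_amp_sd": 0.4,
    "window_length_ms": 60.0,
    # per-model planted amplitudes: later models get slightly more drive
    # because they onset inside earlier models' windows, where the decoding
    # accuracy sigmoid has already used up part of its sensitive range
    "amplitudes": {"alexnet": 2.2, "body": 2.4, "gist": 2.6,
                   "people": 2.8, "semantic": 2.6},
    # inference
    "n_boot": 200,
    "n_perm": 500,
    "test_window_ms": (0.0, 500.0),
}

FUSION_PROTOCOL = {
    "n_conditions": 16,
    "n_exemplars": 12,
    "n_repetitions": 2,
    # EEG arm
    "eeg_subjects": 8,
    "n_channels": 16,
    "sfreq": 100.0,
    "epoch_ms": (-100.0, 500.0),
    "eeg_amplitude": 3.0,
    "window_ms": (100.0, 300.0),
    # fMRI arm
    "fmri_subjects": 8,
    "grid": 20,
    "voxel_size_mm": 2.0,
    "roi_slice": (4, 14),          # cube ROI, inclusive-exclusive per axis
    "fmri_amplitude": 1.8,
    "subject_geometry_jitter": 0.35,
    # searchlight / fusion / inference
    "radius_mm": 6.0,
    "out_voxel_mm": 4.0,
    "noise_sd": 1.0,
    "n_perm": 300,
    "alpha": 0.05,
}


@dataclass
class LatencyRecoveryResult:
    """Outcome of one latency-order replicate."""

    cis: dict                 # model -> (ci_low_ms, ci_high_ms)
    onsets_ms: dict           # model -> observed onset
    ordered: bool             # CIs non-overlapping and in planted order

    @property
    def passed(self) -> bool:
        return self.ordered


@dataclass
class FusionRecoveryResult:
    """Outcome of one fusion-recovery run."""

    n_significant_clusters: int
    jaccard: float
    planted_flagged: bool
    foils_flagged: tuple      # names of foil models flagged at FDR alpha
    rsa_table: object         # the fusion-based RSA DataFrame

    @property
    def passed(self) -> bool:
        return (self.n_significant_clusters >= 1 and self.jaccard > 0.5
                and self.planted_flagged and not self.foils_flagged)


def latency_recovery_replicate(seed: int) -> LatencyRecoveryResult:
    """Run one latency-order recovery replicate of the frozen protocol."""
    P = LATENCY_PROTOCOL
    models = make_correlated_model_rdms(
        MODEL_RDM_CORRELATIONS, P["n_conditions"], seed=seed,
        names=MODEL_NAMES, decorrelate_transforms=True)
    plants = tuple(
        PlantedGeometry(name=m.name, target=m.vector,
                        amplitude=P["amplitudes"][m.name],
                        window_ms=(LATENCIES_MS[m.name],
                                   LATENCIES_MS[m.name] + P["window_length_ms"]),
                        projection_seed=i)
        for i, m in enumerate(models))
    spec = GeometrySpec(models=plants, noise_sd=P["noise_sd"],
                        n_subjects=P["n_subjects"],
                        n_channels=P["n_channels"], sfreq=P["sfreq"],
                        epoch_ms=P["epoch_ms"], seed=seed,
                        subject_amp_sd=P["subject_amp_sd"])
    design = generate_trial_design(P["n_conditions"], P["n_exemplars"],
                                   P["n_repetitions"], seed=seed)
    epochs = generate_eeg_epochs(spec, design)
    stacks = [neural_rdm_timecourse(bin_samples(ep, width=1, stride=1),
                                    seed=seed, subject=i)
              for i, ep in enumerate(epochs)]
    reg = regression_rsa(stacks, ModelSet(members=tuple(models)))
    cis = {name: bootstrap_onset_ci(tc, n_boot=P["n_boot"], seed=seed + 17,
                                    window_ms=P["test_window_ms"],
                                    n_perm=P["n_perm"])
           for name, tc in reg.items()}
    ordered = all(
        np.isfinite(cis[a].ci_high_ms) and np.isfinite(cis[b].ci_low_ms)
        and cis[a].ci_high_ms < cis[b].ci_low_ms
        for a, b in zip(LATENCY_ORDER[:-1], LATENCY_ORDER[1:]))
    return LatencyRecoveryResult(
        cis={n: (cis[n].ci_low_ms, cis[n].ci_high_ms) for n in LATENCY_ORDER},
        onsets_ms={n: cis[n].onset_ms for n in LATENCY_ORDER},
        ordered=bool(ordered))


def _fusion_truth(roi: np.ndarray, vmap_mask: np.ndarray, times_ms: np.ndarray,
                  window_ms: tuple, radius_mm: float,
                  voxel_size_mm: float) -> set:
    """Ground-truth (voxel, bin) set for the planted fusion cluster.

    A searchlight center carries planted signal whenever its sphere touches
    the ROI, so the spatial truth is the ROI dilated by the sphere, mapped to
    the output grid; the temporal truth is the planted latency window.
    """
    offs = _sphere_offsets(radius_mm, voxel_size_mm)
    r = int(np.abs(offs).max())
    struct = np.zeros((2 * r + 1,) * 3, dtype=bool)
    for o in offs:
        struct[tuple(o + r)] = True
    touched = binary_dilation(roi, structure=struct)
    factor = int(round(roi.shape[0] / vmap_mask.shape[0]))
    parents = np.unique(np.array(np.nonzero(touched)).T // factor, axis=0)
    in_idx = np.flatnonzero(vmap_mask.ravel())
    pflat = np.ravel_multi_index(parents.T, vmap_mask.shape)
    local = np.flatnonzero(np.isin(in_idx, pflat))
    wbins = np.flatnonzero((times_ms >= window_ms[0]) &
                           (times_ms <= window_ms[1]))
    return {(int(v), int(b)) for v in local for b in wbins}


def fusion_recovery(seed: int = 0) -> FusionRecoveryResult:
    """Run the frozen fusion-recovery protocol once."""
    P = FUSION_PROTOCOL
    models = make_correlated_model_rdms(
        np.eye(5), P["n_conditions"], seed=seed,
        names=("planted", "foil1", "foil2", "foil3", "foil4"),
        decorrelate_transforms=True)
    target = models[0]

    grid = P["grid"]
    mask = np.ones((grid,) * 3, dtype=bool)
    roi = np.zeros_like(mask)
    a, b = P["roi_slice"]
    roi[a:b, a:b, a:b] = True

    eeg_spec = GeometrySpec(
        models=(PlantedGeometry("planted", target=target.vector,
                                amplitude=P["eeg_amplitude"],
                                window_ms=P["window_ms"]),),
        noise_sd=P["noise_sd"], n_subjects=P["eeg_subjects"],
        n_channels=P["n_channels"], sfreq=P["sfreq"],
        epoch_ms=P["epoch_ms"], seed=seed)
    design = generate_trial_design(P["n_conditions"], P["n_exemplars"],
                                   P["n_repetitions"], seed=seed)
    epochs = generate_eeg_epochs(eeg_spec, design)
    stacks = [neural_rdm_timecourse(bin_samples(ep, width=1, stride=1),
                                    seed=seed, subject=i)
              for i, ep in enumerate(epochs)]

    fmri_spec = GeometrySpec(
        models=(PlantedGeometry("planted", target=target.vector,
                                amplitude=P["fmri_amplitude"], roi=roi),),
        noise_sd=P["noise_sd"], n_subjects=P["fmri_subjects"], seed=seed + 1,
        subject_geometry_jitter=P["subject_geometry_jitter"])
    betas = generate_beta_volumes(fmri_spec, mask,
                                  voxel_size_mm=P["voxel_size_mm"])
    vmap = searchlight_rdms(betas, radius_mm=P["radius_mm"],
                            out_voxel_mm=P["out_voxel_mm"])
    fmap = fuse(stacks, vmap, window_ms=P["epoch_ms"])
    clusters = fusion_cluster_test(fmap, n_perm=P["n_perm"], seed=seed + 5,
                                   test_window_ms=None)

    truth = _fusion_truth(roi, vmap.mask, fmap.times_ms, P["window_ms"],
                          P["radius_mm"], P["voxel_size_mm"])
    sig = [c for c in clusters if c.significant(P["alpha"])]
    jaccard = 0.0
    if sig:
        biggest = max(sig, key=lambda c: c.mass)
        members = set(map(tuple, biggest.members))
        jaccard = len(members & truth) / len(members | truth)

    masks = cluster_masks(fmap, clusters, alpha=P["alpha"])
    factor = int(round(P["out_voxel_mm"] / P["voxel_size_mm"]))
    table = fusion_rsa_timeaveraged(masks, betas,
                                    ModelSet(members=tuple(models)),
                                    beta_factor=factor, alpha=P["alpha"])
    planted = bool(len(table) and
                   table.loc[table.model == "planted", "significant"].any())
    foils = tuple(sorted(
        table.loc[(table.model != "planted") & table.significant, "model"]
        .unique())) if len(table) else ()
    return FusionRecoveryResult(
        n_significant_clusters=len(sig), jaccard=float(jaccard),
        planted_flagged=planted, foils_flagged=foils, rsa_table=table)
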