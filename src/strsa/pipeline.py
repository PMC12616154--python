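"""End-to-end orchestration: one config, one reproducible run directory.

A run simulates a planted-geometry EEG study, decodes it into neural RDM
stacks, relates them to the generating model RDMs by standard and multiple
regression RSA with cluster permutation inference and bootstrap onset CIs,
and (optionally) simulates matching fMRI betas and runs the fusion stage.
Every output carries provenance (package version, seed, config hash); a run
with the same config and seed writes an identical summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .cluster import cluster_test_1d
from .datasets import MODEL_NAMES, MODEL_RDM_CORRELATIONS
from .decoding import bin_samples, neural_rdm_timecourse
from .fusion import (cluster_masks, fuse, fusion_cluster_test,
                     fusion_rsa_timeaveraged, fusion_rsa_timeresolved,
                     searchlight_rdms)
from .rdm import ModelSet
from .rsa import bootstrap_onset_ci, noise_ceiling, regression_rsa, standard_rsa
from .synth import (GeometrySpec, PlantedGeometry, generate_beta_volumes,
                    generate_eeg_epochs, generate_trial_design,
                    make_correlated_model_rdms)

__all__ = ["RunConfig", "PlantSpec", "run_pipeline"]


@dataclass
class PlantSpec:
    """Where and how strongly one model's geometry is planted."""

    name: str
    window_ms: tuple
    amplitude: float
    roi_center: tuple | None = None   # fusion stage: ROI cube center (voxels)
    roi_half_width: int = 2


@dataclass
class RunConfig:
    """All parameters of a pipeline run. Defaults are a reduced demo scale;
    the emulated study's own scale is 27 conditions, 24 EEG / 20 fMRI
    subjects, 63 channels, 500 Hz, 10 000 / 1 000 permutations."""

    seed: int = 0
    # design / simulation
    n_conditions: int = 10
    n_exemplars: int = 6
    n_repetitions: int = 2
    n_subjects: int = 8
    n_channels: int = 16
    sfreq: float = 100.0
    epoch_ms: tuple = (-100.0, 500.0)
    noise_sd: float = 1.0
    model_correlations: str = "study"   # 'study' (published table) or 'identity'
    # shape the model basis so chance transform alignments are suppressed
    # (see strsa.synth.make_correlated_model_rdms); keeps planted latencies
    # identifiable for the regression stage
    decorrelate_transforms: bool = True
    plants: tuple = (
        PlantSpec("alexnet", (80.0, 230.0), 2.0),
        PlantSpec("body", (120.0, 270.0), 2.0),
        PlantSpec("gist", (180.0, 330.0), 2.2),
        PlantSpec("people", (200.0, 350.0), 2.4),
        PlantSpec("semantic", (280.0, 430.0), 2.2),
    )
    # decoding
    bin_width: int = 1
    bin_stride: int = 1
    n_chunks: int = 6
    svm_cost: float = 1.0
    # inference
    n_perm: int = 1000
    alpha: float = 0.05
    alpha_form: float = 0.05
    test_window_ms: tuple = (0.0, 800.0)
    n_boot: int = 200
    # fusion stage (None disables it)
    fusion_enabled: bool = False
    fmri_subjects: int = 8
    fmri_grid: int = 20
    fmri_voxel_mm: float = 2.0
    searchlight_radius_mm: float = 6.0
    out_voxel_mm: float = 4.0
    fusion_window_ms: tuple = (-100.0, 700.0)
    fusion_n_perm: int = 500

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["plants"] = [dataclasses.asdict(p) for p in self.plants]
        text = yaml.safe_dump(_to_builtin(d), sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(pathlib.Path(path).read_text())
        d["plants"] = tuple(
            PlantSpec(**{**p, "window_ms": tuple(p["window_ms"]),
                         "roi_center": None if p.get("roi_center") is None
                         else tuple(p["roi_center"])})
            for p in d.get("plants", ()))
        for key in ("epoch_ms", "test_window_ms", "fusion_window_ms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.n_exemplars * self.n_repetitions < self.n_chunks:
            raise ValueError("not enough trials per condition for the chunks")
        for p in self.plants:
            if p.window_ms[0] < self.epoch_ms[0] or p.window_ms[1] > self.epoch_ms[1]:
                raise ValueError(f"plant '{p.name}' window outside the epoch")
        if self.model_correlations not in ("study", "identity"):
            raise ValueError("model_correlations must be 'study' or 'identity'")
        if self.model_correlations == "study" and len(self.plants) > 5:
            raise ValueError("the published correlation table covers 5 models")


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _model_set_for(config: RunConfig) -> ModelSet:
    k = len(config.plants)
    names = tuple(p.name for p in config.plants)
    if config.model_correlations == "study":
        idx = [MODEL_NAMES.index(n) if n in MODEL_NAMES else None for n in names]
        if None in idx:
            R = MODEL_RDM_CORRELATIONS[:k, :k]
        else:
            R = MODEL_RDM_CORRELATIONS[np.ix_(idx, idx)]
    else:
        R = np.eye(k)
    members = make_correlated_model_rdms(
        R, config.n_conditions, seed=config.seed, names=names,
        decorrelate_transforms=config.decorrelate_transforms)
    return ModelSet(members=tuple(members))


def run_pipeline(config: RunConfig, out_dir, dry_run: bool = False) -> dict:
    """Execute simulate -> decode -> RSA (-> fusion) and write a run directory.

    Returns the machine-readable summary (also written as summary.json).
    ``dry_run`` validates the configuration and writes only the provenance
    block.
    """
    config.validate()
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"package_version": __version__, "seed": config.seed,
                  "config_hash": config.config_hash()}
    config.to_yaml(out / "config.yaml")
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    if dry_run:
        return {"provenance": provenance, "dry_run": True}

    summary = {"provenance": provenance}

    # --- simulate ---------------------------------------------------------
    models = _model_set_for(config)
    design = generate_trial_design(config.n_conditions, config.n_exemplars,
                                   config.n_repetitions, seed=config.seed)
    design.to_tsv(out / "trial_design.tsv")
    plants = tuple(
        PlantedGeometry(name=p.name,
                        target=models.members[i].vector,
                        amplitude=p.amplitude, window_ms=p.window_ms,
                        projection_seed=i)
        for i, p in enumerate(config.plants))
    spec = GeometrySpec(models=plants, noise_sd=config.noise_sd,
                        n_subjects=config.n_subjects,
                        n_channels=config.n_channels, sfreq=config.sfreq,
                        epoch_ms=config.epoch_ms, seed=config.seed)
    epochs = generate_eeg_epochs(spec, design, n_chunks=config.n_chunks)

    # --- decode -----------------------------------------------------------
    stacks = []
    for s, ep in enumerate(epochs):
        binned = bin_samples(ep, width=config.bin_width, stride=config.bin_stride)
        stacks.append(neural_rdm_timecourse(
            binned, n_chunks=config.n_chunks, C=config.svm_cost,
            seed=config.seed, subject=s))

    # --- RSA --------------------------------------------------------------
    nc = noise_ceiling(stacks)
    times = stacks[0].times_ms
    rng = np.random.default_rng((config.seed, 1))
    summary["noise_ceiling"] = {
        "times_ms": times.tolist(),
        "lower": np.round(nc.lower, 6).tolist(),
        "upper": np.round(nc.upper, 6).tolist(),
    }

    standard = {}
    for m in models.members:
        tc = standard_rsa(stacks, m)
        clusters = cluster_test_1d(
            tc.values, alpha_form=config.alpha_form, n_perm=config.n_perm,
            seed=int(rng.integers(2**31)), times_ms=times)
        standard[m.name] = [
            {"onset_ms": c.onset_ms, "offset_ms": c.offset_ms,
             "mass": round(c.mass, 6), "p": c.p}
            for c in clusters if c.significant(config.alpha)]
    summary["standard_rsa_clusters"] = standard

    regression = regression_rsa(stacks, models)
    onsets = {}
    for name, tc in regression.items():
        ci = bootstrap_onset_ci(
            tc, n_boot=config.n_boot, seed=int(rng.integers(2**31)),
            window_ms=config.test_window_ms, alpha_cluster=config.alpha,
            alpha_form=config.alpha_form, n_perm=config.n_perm)
        onsets[name] = {"onset_ms": ci.onset_ms, "mean_ms": ci.mean_ms,
                        "ci_low_ms": ci.ci_low_ms, "ci_high_ms": ci.ci_high_ms,
                        "missing_fraction": ci.missing_fraction}
    summary["regression_onsets"] = onsets

    # --- fusion (optional) -------------------------------------------------
    if config.fusion_enabled:
        summary["fusion"] = _run_fusion(config, models, stacks, out, rng)

    _write_json(out / "summary.json", summary)
    return summary


def _run_fusion(config: RunConfig, models: ModelSet, stacks, out, rng) -> dict:
    g = config.fmri_grid
    mask = np.ones((g, g, g), dtype=bool)
    plants = []
    for i, p in enumerate(config.plants):
        if p.roi_center is None:
            continue
        roi = np.zeros_like(mask)
        c, h = p.roi_center, p.roi_half_width
        roi[max(c[0]-h, 0):c[0]+h+1, max(c[1]-h, 0):c[1]+h+1,
            max(c[2]-h, 0):c[2]+h+1] = True
        plants.append(PlantedGeometry(
            name=p.name, target=models.members[i].vector,
            amplitude=p.amplitude, roi=roi, projection_seed=100 + i))
    if not plants:
        warnings.warn("fusion enabled but no plant has an ROI", stacklevel=2)
        return {}
    spec = GeometrySpec(models=tuple(plants), noise_sd=config.noise_sd,
                        n_subjects=config.fmri_subjects, seed=config.seed + 1)
    betas = generate_beta_volumes(spec, mask, voxel_size_mm=config.fmri_voxel_mm)
    vmap = searchlight_rdms(betas, radius_mm=config.searchlight_radius_mm,
                            out_voxel_mm=config.out_voxel_mm)
    fmap = fuse(stacks, vmap, window_ms=config.fusion_window_ms)
    clusters = fusion_cluster_test(fmap, n_perm=config.fusion_n_perm,
                                   alpha_form=config.alpha_form,
                                   seed=int(rng.integers(2**31)),
                                   test_window_ms=None)
    masks = cluster_masks(fmap, clusters, alpha=config.alpha)
    factor = int(round(config.out_voxel_mm / config.fmri_voxel_mm))
    ta = fusion_rsa_timeaveraged(masks, betas, models, beta_factor=factor,
                                 alpha=config.alpha)
    result = {
        "n_clusters_significant": len(masks),
        "clusters": [{"mass": round(m["cluster"].mass, 6),
                      "p": m["cluster"].p,
                      "onset_ms": m["cluster"].onset_ms,
                      "offset_ms": m["cluster"].offset_ms,
                      "n_voxels_union": int(m["union"].sum())}
                     for m in masks],
        "time_averaged_rsa": ta.to_dict(orient="records") if len(ta) else [],
    }
    if len(masks):
        tr = fusion_rsa_timeresolved(masks, betas, models, beta_factor=factor,
                                     times_ms=fmap.times_ms, alpha=config.alpha,
                                     alpha_form=config.alpha_form,
                                     n_perm=config.fusion_n_perm,
                                     seed=int(rng.integers(2**31)))
        result["time_resolved_rsa"] = (tr.to_dict(orient="records")
                                       if len(tr) else [])
    return result


def _write_json(path, obj) -> None:
    pathlib.Path(path).write_text(
        json.dumps(_to_builtin(obj), indent=2, sort_keys=True,
                   default=lambda o: None if (isinstance(o, float) and np.isnan(o))
                   else str(o)))
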