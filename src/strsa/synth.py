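"""Synthetic study generator: trial designs, multi-subject epoched EEG, fMRI
beta volumes, and behavioral model RDMs with known planted representational
geometry.

The generator emulates a delayed match-to-sample study on static action
images: 27 basic-level actions x 12 exemplars (2 actors x 2 location
exemplars x 3 viewpoints) shown twice each as the first stimulus, 648 trials,
with action / location / actor probes evenly split and a 50/50 match rate per
probe. Neural data are simulated by embedding a target RDM exactly into a
latent configuration (classical multidimensional scaling with the additive
constant that makes the doubly-centered squared-distance matrix positive
semidefinite, so embedded distances are a strictly monotone transform of the
target dissimilarities), projecting the configuration through a seeded
orthonormal map into channels or voxels, and adding white Gaussian noise.
Orthonormal projection preserves pairwise pattern distances, so the planted
geometry rank-matches the target RDM by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet
from .rdm import n_conditions_from_vector, unvectorize

__all__ = [
    "TrialDesign",
    "PlantedGeometry",
    "GeometrySpec",
    "BetaImages",
    "generate_trial_design",
    "embed_geometry",
    "generate_eeg_epochs",
    "generate_beta_volumes",
    "generate_behavioral_model_rdms",
    "make_correlated_model_rdms",
]

ISI_CHOICES_MS = (500, 667, 833, 1000, 1167, 1333)
PROBES = ("action", "location", "actor")

#: Duration of the raised-cosine onset/offset ramps on planted EEG signals.
RAMP_MS = 10.0


# ---------------------------------------------------------------------------
# Trial design
# ---------------------------------------------------------------------------

@dataclass
class TrialDesign:
    """A full trial table plus the stimulus enumeration it draws from.

    trials: one row per trial with columns
        s1_action, s1_exemplar, s2_action, s2_exemplar, probe, match, isi_ms
    exemplar attributes factorize as actors x location-exemplars x viewpoints.
    """

    trials: pd.DataFrame = field(repr=False)
    n_actions: int
    n_exemplars: int
    n_repetitions: int
    exemplar_factors: tuple = (2, 2, 3)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_stimuli(self) -> int:
        """Number of distinct images in the stimulus set."""
        return self.n_actions * self.n_exemplars

    def probe_counts(self) -> dict:
        return self.trials["probe"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.trials.to_csv(path, sep="\t", index=False)

    @staticmethod
    def from_tsv(path, n_actions, n_exemplars, n_repetitions) -> "TrialDesign":
        return TrialDesign(pd.read_csv(path, sep="\t"), n_actions, n_exemplars,
                           n_repetitions)


def _exemplar_attrs(exemplar: np.ndarray, factors: tuple) -> tuple:
    """Split exemplar index into (actor, location, viewpoint) attributes."""
    n_act, n_loc, n_view = factors
    view = exemplar % n_view
    loc = (exemplar // n_view) % n_loc
    actor = exemplar // (n_view * n_loc)
    return actor, loc, view


def generate_trial_design(n_actions: int, n_exemplars: int, n_repetitions: int,
                          seed: int = 0,
                          exemplar_factors: tuple | None = None) -> TrialDesign:
    """Build a delayed match-to-sample trial table.

    Every (action, exemplar) stimulus appears exactly ``n_repetitions`` times
    as the first stimulus S1. Probes (action / location / actor) are as
    evenly distributed over trials as divisibility allows (counts differ by
    at most 1; earlier probes in :data:`PROBES` order receive the remainder),
    and within each probe half the trials are matches (the match half rounds
    down). Location probes draw S2 from the same action as S1.
    """
    # n_exemplars >= 2: a non-match location probe needs a second exemplar
    # of the same action to draw S2 from
    if n_actions < 2 or n_exemplars < 2 or n_repetitions < 1:
        raise ValueError("need n_actions >= 2, n_exemplars >= 2, n_repetitions >= 1")
    if exemplar_factors is None:
        exemplar_factors = _default_factors(n_exemplars)
    if int(np.prod(exemplar_factors)) != n_exemplars:
        raise ValueError(f"exemplar factors {exemplar_factors} do not multiply "
                         f"to {n_exemplars}")

    rng = np.random.default_rng(seed)
    n_trials = n_actions * n_exemplars * n_repetitions

    # S1 sequence: every stimulus n_repetitions times, shuffled.
    actions = np.repeat(np.arange(n_actions), n_exemplars * n_repetitions)
    exemplars = np.tile(np.repeat(np.arange(n_exemplars), n_repetitions), n_actions)
    order = rng.permutation(n_trials)
    s1_action, s1_exemplar = actions[order], exemplars[order]

    # Probe assignment: balanced, remainder to earlier probe types.
    base, extra = divmod(n_trials, len(PROBES))
    probe_pool = np.concatenate([
        np.full(base + (1 if k < extra else 0), k) for k in range(len(PROBES))
    ])
    probe_idx = rng.permutation(probe_pool)

    # Match flags: within each probe, half matches (rounded down).
    match = np.zeros(n_trials, dtype=bool)
    for k in range(len(PROBES)):
        idx = np.flatnonzero(probe_idx == k)
        n_match = len(idx) // 2
        match[rng.permutation(idx)[:n_match]] = True

    s2_action = np.empty(n_trials, dtype=int)
    s2_exemplar = np.empty(n_trials, dtype=int)
    for t in range(n_trials):
        s2_action[t], s2_exemplar[t] = _draw_s2(
            rng, PROBES[probe_idx[t]], bool(match[t]),
            int(s1_action[t]), int(s1_exemplar[t]),
            n_actions, n_exemplars, exemplar_factors)

    trials = pd.DataFrame({
        "s1_action": s1_action,
        "s1_exemplar": s1_exemplar,
        "s2_action": s2_action,
        "s2_exemplar": s2_exemplar,
        "probe": np.array(PROBES)[probe_idx],
        "match": match,
        "isi_ms": rng.choice(ISI_CHOICES_MS, size=n_trials),
    })
    return TrialDesign(trials, n_actions, n_exemplars, n_repetitions,
                       exemplar_factors)


def _default_factors(n_exemplars: int) -> tuple:
    if n_exemplars == 12:
        return (2, 2, 3)  # the study's actors x locations x viewpoints
    # fall back to (2, ..., rest) when even, else a single-factor axis
    if n_exemplars % 4 == 0:
        return (2, 2, n_exemplars // 4)
    if n_exemplars % 2 == 0:
        return (2, 1, n_exemplars // 2)
    return (1, 1, n_exemplars)


def _draw_s2(rng, probe, match, a1, e1, n_actions, n_exemplars, factors):
    """Pick the second stimulus according to probe type and match flag."""
    actor1, loc1, _ = _exemplar_attrs(np.array(e1), factors)
    n_act, n_loc, n_view = factors
    if probe == "action":
        if match:
            a2 = a1
            e2 = _other_choice(rng, n_exemplars, e1) if n_exemplars > 1 else e1
        else:
            a2 = _other_choice(rng, n_actions, a1)
            e2 = int(rng.integers(n_exemplars))
        return a2, e2
    if probe == "location":
        # S2 always from the same action as S1; match on the location attribute
        a2 = a1
        if n_loc == 1:
            return a2, (e1 if match else _other_choice(rng, n_exemplars, e1))
        cand = np.arange(n_exemplars)
        _, locs, _ = _exemplar_attrs(cand, factors)
        pool = cand[(locs == loc1) if match else (locs != loc1)]
        pool = pool[pool != e1] if (match and len(pool) > 1) else pool
        return a2, int(rng.choice(pool))
    # actor probe: any action, exemplar with matching / differing actor
    a2 = int(rng.integers(n_actions))
    cand = np.arange(n_exemplars)
    actors, _, _ = _exemplar_attrs(cand, factors)
    if n_act == 1:
        return a2, int(rng.choice(cand))
    pool = cand[(actors == actor1) if match else (actors != actor1)]
    return a2, int(rng.choice(pool))


def _other_choice(rng, n, exclude):
    v = int(rng.integers(n - 1))
    return v + 1 if v >= exclude else v


# ---------------------------------------------------------------------------
# Geometry embedding
# ---------------------------------------------------------------------------

def embed_geometry(target_vector: np.ndarray) -> np.ndarray:
    """Embed a target RDM vector as a latent configuration (n x k).

    The target is shifted to strictly positive dissimilarities, converted to
    squared distances, and classically scaled; a constant is added to the
    squared distances when needed (shifting centered eigenvalues up) so the
    Gram matrix is positive semidefinite and the embedding is exact. Since
    ``sqrt(d^2 + c)`` is strictly increasing in d, the embedded Euclidean
    distances preserve the target's rank order (and ties) exactly.
    """
    v = np.asarray(target_vector, dtype=float)
    n = n_conditions_from_vector(v)
    if np.ptp(v) == 0:
        raise ValueError("cannot embed a constant target RDM")
    d = v - v.min() + 0.25 * np.ptp(v)  # strictly positive dissimilarities
    D2 = unvectorize(d) ** 2
    np.fill_diagonal(D2, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w = np.linalg.eigvalsh(B)
    if w[0] < -1e-12 * max(1.0, w[-1]):
        c = -2.0 * w[0] * 1.0000001
        D2 = D2 + c * (1 - np.eye(n))
        B = -0.5 * J @ D2 @ J
    w, V = np.linalg.eigh(B)
    keep = w > max(1e-12, 1e-12 * w[-1])
    X = V[:, keep] * np.sqrt(w[keep])
    # normalize overall scale: unit RMS pairwise distance
    from scipy.spatial.distance import pdist
    X = X - X.mean(axis=0)
    rms = np.sqrt((pdist(X) ** 2).mean())
    return X / rms


def embed_geometry_corr(target_vector: np.ndarray) -> np.ndarray:
    """Embed a target RDM as equal-norm latent patterns whose pairwise
    *correlation distances* (1 - r) realize the target's rank order exactly.

    Searchlight fMRI RDMs use 1 - Spearman of voxel patterns, so the planted
    geometry must be rank-faithful under the correlation metric rather than
    Euclidean distance. The target is shifted to nonnegative dissimilarities
    T (max 1) and a Gram matrix G = I + s(J - I - T) ... concretely
    ``G_ij = 1 - s T_ij`` with unit diagonal; s is halved until G is positive
    semidefinite, then G is factorized into unit-norm rows. For zero-mean,
    equal-norm patterns, 1 - corr is strictly increasing in T.
    """
    v = np.asarray(target_vector, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("cannot embed a constant target RDM")
    d = v - v.min() + 0.25 * np.ptp(v)
    T = unvectorize(d / d.max())
    np.fill_diagonal(T, 0.0)
    n = T.shape[0]
    s = 0.95
    for _ in range(60):
        G = np.eye(n) + s * (1.0 - np.eye(n)) - s * T
        w = np.linalg.eigvalsh(G)
        if w[0] > 1e-10:
            break
        s *= 0.7
    else:
        raise RuntimeError("could not find a PSD correlation embedding")
    w, V = np.linalg.eigh(G)
    keep = w > 1e-12
    return V[:, keep] * np.sqrt(w[keep])


def _orthonormal_projection(rng, k: int, n_out: int,
                            zero_mean: bool = False) -> np.ndarray:
    """Seeded k x n_out matrix with orthonormal rows (distance-preserving).

    ``zero_mean`` additionally makes every row orthogonal to the constant
    vector, so projected patterns have exactly zero mean across outputs
    (required when correlations, which center, must be preserved exactly).
    """
    if k + int(zero_mean) > n_out:
        warnings.warn(
            f"latent dimension {k} exceeds output dimension {n_out}; planted "
            "geometry is only approximately preserved", stacklevel=2)
        A = rng.standard_normal((k, n_out))
        return A / np.sqrt(k)
    if zero_mean:
        base = np.column_stack([np.ones(n_out), rng.standard_normal((n_out, k))])
        Q, _ = np.linalg.qr(base)
        return Q[:, 1:k + 1].T
    A = rng.standard_normal((n_out, k))
    Q, _ = np.linalg.qr(A)
    return Q[:, :k].T


# ---------------------------------------------------------------------------
# Geometry specs
# ---------------------------------------------------------------------------

@dataclass
class PlantedGeometry:
    """One model geometry to plant: where (latency window or voxel ROI),
    how strongly, and from which target RDM."""

    name: str
    target: np.ndarray = field(repr=False)  # RDM vector, length n(n-1)/2
    amplitude: float = 1.0
    window_ms: tuple | None = None          # EEG: (start, stop)
    roi: np.ndarray | None = None           # fMRI: boolean volume
    projection_seed: int = 0
    #: transient-plus-sustained envelope: full amplitude for plateau_ms after
    #: the onset ramp, then decay to sustain x amplitude for the rest of the
    #: window (sustain=1.0 keeps a flat boxcar)
    plateau_ms: float | None = None
    sustain: float = 1.0

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=float)
        n_conditions_from_vector(self.target)
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class GeometrySpec:
    """Ground-truth plan for a synthetic dataset.

    EEG fields (n_channels, sfreq, epoch_ms) drive
    :func:`generate_eeg_epochs`; fMRI fields (grid shape/voxel size via the
    mask argument) drive :func:`generate_beta_volumes`. Defaults mirror the
    emulated study: 24 EEG subjects, 63 channels, 500 Hz, epochs -500..3000
    ms; 20 fMRI subjects on a 2 mm grid.
    """

    models: tuple
    noise_sd: float = 1.0
    n_subjects: int = 24
    n_channels: int = 63
    sfreq: float = 500.0
    epoch_ms: tuple = (-500.0, 3000.0)
    seed: int = 0
    #: Relative between-subject variability of planted effect amplitude:
    #: each subject scales each model's amplitude by a mean-1 lognormal
    #: factor exp(sigma*z - sigma^2/2). Human decoding effect sizes vary
    #: severalfold across participants; 0.4 keeps subjects within roughly a
    #: factor of two of each other.
    subject_amp_sd: float = 0.4
    #: Relative between-subject variability of the planted geometry itself:
    #: each subject's target RDM vector is perturbed by Gaussian noise of
    #: this sd (relative to the target's sd) before embedding. Real subjects
    #: do not share one representational geometry — this is what noise
    #: ceilings quantify — and group t-tests on RDM correlations are only
    #: calibrated when geometry varies between subjects.
    subject_geometry_jitter: float = 0.0

    def __post_init__(self):
        self.models = tuple(self.models)
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        lengths = {len(m.target) for m in self.models}
        if len(lengths) > 1:
            raise ValueError("planted targets disagree on condition count")

    @property
    def n_conditions(self) -> int:
        return n_conditions_from_vector(self.models[0].target)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

def _subject_target(spec: GeometrySpec, m: PlantedGeometry, model_index: int,
                    subject: int) -> np.ndarray:
    """The subject's own target RDM vector (jittered when configured)."""
    if spec.subject_geometry_jitter <= 0:
        return m.target
    rng = np.random.default_rng((spec.seed, subject, model_index, 55))
    j = spec.subject_geometry_jitter * m.target.std()
    return m.target + j * rng.standard_normal(len(m.target))


def _subject_gain(spec: GeometrySpec, subject: int, model_index: int) -> float:
    """Mean-1 lognormal per-(subject, model) amplitude gain."""
    if spec.subject_amp_sd <= 0:
        return 1.0
    rng = np.random.default_rng((spec.seed, subject, model_index, 77))
    s = spec.subject_amp_sd
    return float(np.exp(s * rng.standard_normal() - s * s / 2.0))


def assign_chunks(conditions: np.ndarray, n_chunks: int = 6) -> np.ndarray:
    """Round-robin chunk assignment within each condition (balanced partitions)."""
    chunks = np.empty(len(conditions), dtype=int)
    for c in np.unique(conditions):
        idx = np.flatnonzero(conditions == c)
        chunks[idx] = np.arange(len(idx)) % n_chunks
    return chunks


def _raised_cosine_envelope(times_ms, window_ms, ramp_ms=RAMP_MS,
                            plateau_ms=None, sustain=1.0):
    """Signal envelope inside a latency window.

    Raised-cosine ramps (``ramp_ms``) at both edges. With ``plateau_ms`` set
    and ``sustain < 1`` the envelope holds full amplitude for ``plateau_ms``
    after onset, then decays (raised-cosine, over ``plateau_ms``) to the
    ``sustain`` level for the rest of the window — a sharp transient followed
    by a sustained response, as in evoked EEG, which keeps onsets crisp while
    giving clusters temporal extent.
    """
    t0, t1 = window_ms
    env = np.zeros_like(times_ms, dtype=float)
    inside = (times_ms >= t0) & (times_ms <= t1)
    env[inside] = 1.0
    if plateau_ms is not None and sustain < 1.0:
        decay_start = t0 + ramp_ms + plateau_ms
        decay_end = decay_start + plateau_ms
        dec = inside & (times_ms >= decay_start) & (times_ms < decay_end)
        frac = (times_ms[dec] - decay_start) / max(decay_end - decay_start, 1e-9)
        env[dec] = sustain + (1 - sustain) * 0.5 * (1 + np.cos(np.pi * frac))
        env[inside & (times_ms >= decay_end)] = sustain
    if ramp_ms > 0:
        up = inside & (times_ms < t0 + ramp_ms)
        env[up] = 0.5 * (1 - np.cos(np.pi * (times_ms[up] - t0) / ramp_ms))
        down = inside & (times_ms > t1 - ramp_ms)
        env[down] = np.minimum(
            env[down],
            0.5 * (1 - np.cos(np.pi * (t1 - times_ms[down]) / ramp_ms)))
    return env


def generate_eeg_epochs(spec: GeometrySpec, design: TrialDesign,
                        n_chunks: int = 6) -> list[EpochSet]:
    """Simulate one :class:`EpochSet` per subject with planted geometry.

    Within each planted model's latency window, condition-mean channel
    patterns realize that model's target RDM (scaled by its amplitude) on top
    of white sensor noise. Projections into channel space are orthonormal and
    seeded per (model, subject); the same seed always reproduces the same
    data bit for bit.
    """
    times_ms = np.arange(spec.epoch_ms[0], spec.epoch_ms[1] + 1e-9,
                         1000.0 / spec.sfreq)
    for m in spec.models:
        if m.window_ms is None:
            raise ValueError(f"planted model '{m.name}' has no latency window")
        if m.window_ms[0] < spec.epoch_ms[0] or m.window_ms[1] > spec.epoch_ms[1]:
            raise ValueError(f"window {m.window_ms} outside epoch {spec.epoch_ms}")

    conditions = design.trials["s1_action"].to_numpy()
    if design.n_actions != spec.n_conditions:
        raise ValueError("design and spec disagree on condition count")
    chunks = assign_chunks(conditions, n_chunks)
    n_trials = len(conditions)

    configs = {m.name: embed_geometry(m.target) for m in spec.models}
    envelopes = {m.name: _raised_cosine_envelope(times_ms, m.window_ms,
                                                 plateau_ms=m.plateau_ms,
                                                 sustain=m.sustain)
                 for m in spec.models}

    subjects = []
    root = np.random.default_rng(spec.seed)
    noise_seeds = root.integers(2**31, size=spec.n_subjects)
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(noise_seeds[s])
        data = rng.normal(0.0, spec.noise_sd,
                          size=(n_trials, spec.n_channels, len(times_ms)))
        for mi, m in enumerate(spec.models):
            proj_rng = np.random.default_rng((m.projection_seed, spec.seed, s))
            if spec.subject_geometry_jitter > 0:
                X = embed_geometry(_subject_target(spec, m, mi, s))
            else:
                X = configs[m.name]
            P = _orthonormal_projection(proj_rng, X.shape[1], spec.n_channels)
            gain = _subject_gain(spec, s, mi)
            patterns = gain * m.amplitude * (X @ P)  # n_cond x n_channels
            data += patterns[conditions][:, :, None] * envelopes[m.name][None, None, :]
        subjects.append(EpochSet(data=data, conditions=conditions, chunks=chunks,
                                 sfreq=spec.sfreq, times_ms=times_ms))
    return subjects


# ---------------------------------------------------------------------------
# fMRI beta volumes
# ---------------------------------------------------------------------------

@dataclass
class BetaImages:
    """Per-subject, per-condition GLM beta volumes on a shared grid.

    data : subjects x conditions x nx x ny x nz
    """

    data: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    affine: np.ndarray
    voxel_size_mm: float
    condition_labels: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 5:
            raise ValueError("beta data must be subjects x conditions x X x Y x Z")
        if self.data.shape[2:] != self.mask.shape:
            raise ValueError("mask grid does not match beta grid")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    def to_nifti(self, out_dir) -> None:
        """Write one NIfTI per subject/condition plus the mask."""
        import pathlib

        import nibabel as nib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), self.affine),
                 out / "mask.nii")
        for s in range(self.n_subjects):
            for c, lab in enumerate(self.condition_labels):
                img = nib.Nifti1Image(self.data[s, c].astype(np.float32),
                                      self.affine)
                nib.save(img, out / f"sub-{s:02d}_cond-{int(lab):02d}_beta.nii")


def generate_beta_volumes(spec: GeometrySpec, mask: np.ndarray,
                          voxel_size_mm: float = 2.0) -> BetaImages:
    """Simulate beta volumes with target geometries planted in voxel ROIs.

    Inside each planted model's ROI the condition beta patterns realize the
    model's target RDM (orthonormal voxel projection, amplitude-scaled);
    everywhere else, and additively on top, voxels carry i.i.d. Gaussian
    noise that is independent across subjects.
    """
    mask = np.asarray(mask, dtype=bool)
    for m in spec.models:
        if m.roi is None:
            raise ValueError(f"planted model '{m.name}' has no ROI")
        roi = np.asarray(m.roi, dtype=bool)
        if roi.shape != mask.shape:
            raise ValueError("ROI grid does not match mask grid")
        if not roi.any():
            raise ValueError(f"planted model '{m.name}' has an empty ROI")
        if (roi & ~mask).any():
            raise ValueError(f"ROI of '{m.name}' leaves the brain mask")

    n_cond = spec.n_conditions
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    # correlation-metric embedding: searchlight RDMs are 1 - Spearman of
    # voxel patterns, so rank fidelity must hold under that metric
    configs = {m.name: embed_geometry_corr(m.target) for m in spec.models}

    root = np.random.default_rng(spec.seed)
    noise_seeds = root.integers(2**31, size=spec.n_subjects)
    data = np.zeros((spec.n_subjects, n_cond) + mask.shape)
    for s in range(spec.n_subjects):
        rng = np.random.default_rng(noise_seeds[s])
        vol = rng.normal(0.0, spec.noise_sd, size=(n_cond,) + mask.shape)
        vol[:, ~mask] = 0.0
        for mi, m in enumerate(spec.models):
            roi_idx = np.flatnonzero(np.asarray(m.roi, dtype=bool).ravel())
            proj_rng = np.random.default_rng((m.projection_seed, spec.seed, s, 1))
            if spec.subject_geometry_jitter > 0:
                X = embed_geometry_corr(_subject_target(spec, m, mi, s))
            else:
                X = configs[m.name]
            P = _orthonormal_projection(proj_rng, X.shape[1], len(roi_idx),
                                        zero_mean=True)
            gain = _subject_gain(spec, s, mi)
            # amplitude is the per-voxel pattern scale: rows of X @ P have
            # unit norm spread over the ROI, hence the sqrt(len(roi)) factor
            patterns = (gain * m.amplitude * np.sqrt(len(roi_idx))) * (X @ P)
            flat = vol.reshape(n_cond, -1)
            flat[:, roi_idx] += patterns
        data[s] = vol
    return BetaImages(data=data, mask=mask, affine=affine,
                      voxel_size_mm=voxel_size_mm,
                      condition_labels=np.arange(n_cond))


# ---------------------------------------------------------------------------
# Behavioral model RDMs
# ---------------------------------------------------------------------------

def generate_behavioral_model_rdms(true_rdms: list, noise_sd: float,
                                   seed: int = 0) -> list:
    """Noisy stand-ins for multi-arrangement behavioral RDMs.

    Adds i.i.d. Gaussian noise to each true model vector; ``noise_sd = 0``
    returns exact copies. Larger noise attenuates inter-model correlations
    toward zero.
    """
    from .rdm import ModelRDM
    rng = np.random.default_rng(seed)
    out = []
    for m in true_rdms:
        v = m.vector + rng.normal(0.0, noise_sd, size=len(m.vector))
        out.append(ModelRDM(name=m.name, vector=v, normalized=False))
    return out


def make_correlated_model_rdms(corr_matrix: np.ndarray, n_conditions: int,
                               seed: int = 0, names: tuple | None = None,
                               decorrelate_transforms: bool = False) -> list:
    """Construct model RDM vectors whose *sample* correlations equal a target
    correlation matrix exactly.

    A seeded Gaussian basis is mean-centered and whitened (exactly
    orthonormal columns), then recolored by the Cholesky factor of the target
    matrix; the empirical Pearson correlations of the returned vectors match
    the target to machine precision. Vectors are returned normalized
    (mean 0, population sd 1).

    With ``decorrelate_transforms`` the basis is additionally shaped so that
    low-order transforms (squares, cubes, fourth powers, ranks, pairwise
    products) of each model, beyond their own linear part, have strongly
    suppressed sample correlation with every other model. Pairwise decoding
    maps planted pattern distances through a compressive nonlinearity; if a
    chance sample correlation links a transform of model A to model B, every
    simulated subject inherits the same spurious "model B" signal during
    model A's latency window. Suppressing those alignments makes the planted
    design identifiable for linear multiple-regression RSA, which is the
    property the recovery suites are meant to probe. Residual alignments are
    an order of magnitude below finite-n chance level, not machine zero: the
    deflation trades off against the exact Pearson structure and the Spearman
    shaping, and structural correlations (transforms of A genuinely related
    to B through R itself) are preserved, not removed. See
    :func:`_shape_basis`.
    """
    from .rdm import ModelRDM
    R = np.asarray(corr_matrix, dtype=float)
    k = R.shape[0]
    n_pairs = n_conditions * (n_conditions - 1) // 2
    if n_pairs <= k:
        raise ValueError("need more condition pairs than models")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_pairs, k))
    X = _recolor(Z, R)
    if decorrelate_transforms:
        X = _shape_basis(X, R)
    if names is None:
        names = tuple(f"model_{i}" for i in range(k))
    return [ModelRDM(name=names[i], vector=X[:, i], normalized=True)
            for i in range(k)]


def _recolor(Z: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Whiten columns of Z exactly, then impose sample correlation R."""
    Z = Z - Z.mean(axis=0)
    U, _, Vt = np.linalg.svd(Z, full_matrices=False)
    W = U @ Vt
    W -= W.mean(axis=0)
    cov = W.T @ W / Z.shape[0]
    W = W @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return W @ np.linalg.cholesky(R).T


def _shape_basis(X: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Jointly suppress chance transform alignments and rank-correlation
    offsets, keeping the Pearson structure exact.

    Each iteration takes one damped deflation step (remove, from every other
    column, the component along the polynomial transforms of a source column
    residualized on the source's own linear part — residualizing on the
    source only, never on the full span, is what leaves the structural,
    R-mediated relations intact while the chance part shrinks), one damped
    gradient step on the Spearman discrepancy (ranking is nonlinear, so even
    exact Pearson structure carries rank-correlation sampling offsets every
    simulated subject would share), and an exact Pearson recoloring. The two
    small corrections interleaved converge together; applied sequentially at
    full strength each destroys the other's work. Typical residuals at ~100
    pairs: transform alignments below 0.02 (vs ~0.15-0.2 raw chance) and
    Spearman offsets below ~0.02 (structural targets bind harder than
    identity targets).
    """
    from scipy.stats import rankdata
    n, k = X.shape
    for iters, step in ((300, 0.2), (300, 0.1)):
        for _ in range(iters):
            Xn = X.copy()
            for i in range(k):
                Qf, _ = np.linalg.qr(_transform_features(X, i))
                others = [j for j in range(k) if j != i]
                Xn[:, others] -= step * (Qf @ (Qf.T @ Xn[:, others]))
            Rk = rankdata(X, axis=0)
            Rk = (Rk - Rk.mean(0)) / Rk.std(0)
            E = (Rk.T @ Rk) / n - R
            np.fill_diagonal(E, 0.0)
            Xn -= 0.5 * (Rk @ E)
            X = _recolor(Xn, R)
    return X


def _transform_features(X: np.ndarray, i: int) -> np.ndarray:
    """Polynomial transforms of column i, residualized on {1, X_i} (and, for
    pairwise products X_i * X_j, on {1, X_i, X_j}).

    Products matter because concurrently planted models mix through the
    root-sum-of-squares of their pattern distances. Ranks are deliberately
    not deflated: rank directions are how the Spearman structure is
    adjusted, and the decoding nonlinearity is smooth, so low-order
    polynomials capture the leakage mechanism.
    """
    n, k = X.shape
    v = X[:, i]
    Qi, _ = np.linalg.qr(np.column_stack([np.ones(n), v]))
    feats = [f - Qi @ (Qi.T @ f) for f in (v ** 2, v ** 3, v ** 4)]
    for j in range(k):
        if j == i:
            continue
        Qij, _ = np.linalg.qr(np.column_stack([np.ones(n), v, X[:, j]]))
        f = v * X[:, j]
        feats.append(f - Qij @ (Qij.T @ f))
    return np.column_stack(feats)
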