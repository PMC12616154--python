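"""Relating neural RDM stacks to model RDMs over time.

Standard RSA: per subject and time bin, the Spearman correlation between the
neural RDM vector and a normalized model RDM vector, Fisher z-transformed
immediately (all later aggregation happens on the z scale). Multiple
regression RSA: per subject and bin, ordinary least-squares of the neural
vector on the normalized model vectors plus a constant. Group inference on
either time course goes through the one-sample cluster permutation test; the
onset of a model is the first bin of its first significant positive cluster
inside the test window, and onset uncertainty comes from bootstrapping the
subject sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .cluster import cluster_test_1d
from .containers import NeuralRDMStack
from .rdm import CollinearityError, ModelRDM, ModelSet, fisher_z

__all__ = ["RSATimecourse", "NoiseCeiling", "OnsetCI", "standard_rsa",
           "noise_ceiling", "regression_rsa", "first_cluster_onset",
           "bootstrap_onset_ci"]


@dataclass
class RSATimecourse:
    """Per-subject, per-bin statistic relating one model to the neural data.

    kind is 'z' (Fisher-z Spearman correlation) or 'beta' (regression weight).
    """

    model: str
    values: np.ndarray = field(repr=False)  # subjects x bins
    times_ms: np.ndarray
    kind: str = "z"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x bins")
        if self.values.shape[1] != len(self.times_ms):
            raise ValueError("time axis mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite RSA values")


@dataclass
class NoiseCeiling:
    """Lower/upper bounds on attainable model correlation, in r units."""

    lower: np.ndarray
    upper: np.ndarray
    times_ms: np.ndarray


@dataclass
class OnsetCI:
    """Bootstrap summary of a model's first-cluster onset latency."""

    model: str
    onset_ms: float          # onset in the observed (non-resampled) sample
    mean_ms: float           # mean over bootstrap replicates
    ci_low_ms: float
    ci_high_ms: float
    n_boot: int
    missing_fraction: float  # replicates with no significant cluster


def _check_alignment(stacks: list[NeuralRDMStack]) -> None:
    ref = stacks[0]
    for s in stacks[1:]:
        if not np.array_equal(s.labels, ref.labels):
            raise ValueError("subjects disagree on condition labels/order")
        if not np.array_equal(s.times_ms, ref.times_ms):
            raise ValueError("subjects disagree on the time axis")


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average-tie ranks along the last axis, centered and unit-normalized.

    Rows with zero variance come back as all-zero (their correlation with
    anything is undefined; callers map that to 0).
    """
    r = rankdata(x, axis=-1)
    r = r - r.mean(axis=-1, keepdims=True)
    norm = np.sqrt((r ** 2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, r / norm, 0.0)
    return out


def _spearman_vs_vector(mat: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Spearman of each row of ``mat`` against ``vec`` (vectorized)."""
    rm = _rank_rows(mat)
    rv = _rank_rows(vec[None, :])[0]
    return rm @ rv


def standard_rsa(stacks: list[NeuralRDMStack], model: ModelRDM) -> RSATimecourse:
    """Fisher-z Spearman correlation time course, one row per subject.

    Bins where the neural RDM is rank-degenerate (constant accuracies)
    contribute z = 0 with a warning.
    """
    _check_alignment(stacks)
    n = len(stacks[0].labels)
    if len(model.vector) != n * (n - 1) // 2:
        raise ValueError(f"model '{model.name}' does not match {n} conditions")
    if np.ptp(model.vector) == 0:
        raise ValueError("model RDM is constant")
    rows = []
    degenerate = False
    for s in stacks:
        rho = _spearman_vs_vector(s.vectors, model.vector)
        if np.any(np.ptp(s.vectors, axis=1) == 0):
            degenerate = True
        rows.append(fisher_z(np.clip(rho, -1.0, 1.0)))
    if degenerate:
        warnings.warn("rank-degenerate neural RDM bins contribute z = 0",
                      stacklevel=2)
    return RSATimecourse(model=model.name, values=np.vstack(rows),
                         times_ms=stacks[0].times_ms, kind="z")


def noise_ceiling(stacks: list[NeuralRDMStack]) -> NoiseCeiling:
    """Leave-one-out noise ceiling on the neural RDM time course.

    Per bin: lower bound = mean over subjects of Spearman(subject RDM, mean
    RDM of the others); upper bound = the same against the mean of all
    subjects. Per-subject correlations are averaged on the Fisher-z scale and
    transformed back to r.
    """
    if len(stacks) < 3:
        raise ValueError("noise ceiling needs >= 3 subjects")
    _check_alignment(stacks)
    all_v = np.stack([s.vectors for s in stacks])  # S x bins x pairs
    S, n_bins, _ = all_v.shape
    total = all_v.sum(axis=0)
    z_low = np.zeros((S, n_bins))
    z_up = np.zeros((S, n_bins))
    rank_all = _rank_rows(total / S)
    for s in range(S):
        rs = _rank_rows(all_v[s])
        others = _rank_rows((total - all_v[s]) / (S - 1))
        z_low[s] = fisher_z(np.clip((rs * others).sum(-1), -1.0, 1.0))
        z_up[s] = fisher_z(np.clip((rs * rank_all).sum(-1), -1.0, 1.0))
    return NoiseCeiling(lower=np.tanh(z_low.mean(axis=0)),
                        upper=np.tanh(z_up.mean(axis=0)),
                        times_ms=stacks[0].times_ms)


def regression_rsa(stacks: list[NeuralRDMStack],
                   models: ModelSet) -> dict[str, RSATimecourse]:
    """OLS of neural RDM vectors on [1, model vectors], per subject and bin.

    Models must be normalized; a rank-deficient design raises
    :class:`CollinearityError` (reduce the set by VIF first).
    """
    _check_alignment(stacks)
    for m in models.members:
        if not m.normalized:
            raise ValueError(f"model '{m.name}' is not normalized")
    X = np.column_stack([np.ones(len(models.members[0].vector)),
                         models.matrix()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            "design matrix is rank deficient; reduce the model set by VIF")
    pinv = np.linalg.pinv(X)
    betas = np.stack([(pinv @ s.vectors.T) for s in stacks])  # S x (k+1) x bins
    out = {}
    for j, m in enumerate(models.members):
        out[m.name] = RSATimecourse(model=m.name, values=betas[:, j + 1, :],
                                    times_ms=stacks[0].times_ms, kind="beta")
    return out


def first_cluster_onset(values: np.ndarray, times_ms: np.ndarray,
                        window_ms: tuple = (0.0, 800.0),
                        alpha_cluster: float = 0.05,
                        alpha_form: float = 0.05, n_perm: int = 1000,
                        seed: int = 0,
                        groups: np.ndarray | None = None) -> float | None:
    """Onset (ms) of the first significant positive cluster inside a window.

    Returns None when no cluster reaches significance.
    """
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("test window does not intersect the time axis")
    clusters = cluster_test_1d(values[:, sel], alpha_form=alpha_form,
                               n_perm=n_perm, tail=1, seed=seed,
                               times_ms=times_ms[sel], groups=groups)
    sig = [c for c in clusters if c.significant(alpha_cluster)]
    if not sig:
        return None
    return min(c.onset_ms for c in sig)


def bootstrap_onset_ci(tc: RSATimecourse, n_boot: int = 1000, seed: int = 0,
                       window_ms: tuple = (0.0, 800.0),
                       alpha_cluster: float = 0.05, alpha_form: float = 0.05,
                       n_perm: int = 1000) -> OnsetCI:
    """Bootstrap the subject sample to get a 95% CI for a model's onset.

    Each replicate resamples subjects with replacement and reruns the full
    group cluster inference. Within a replicate the sign-flip null assigns
    one sign per *unique* resampled subject, so duplicated subjects are
    flipped as a block rather than counted as independent evidence.
    Replicates with no significant cluster are recorded as missing and
    excluded from the percentiles (their fraction is reported). If every
    replicate is null the onset fields are NaN rather than an exception.
    """
    S = tc.values.shape[0]
    if S < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(seed)
    obs = first_cluster_onset(tc.values, tc.times_ms, window_ms=window_ms,
                              alpha_cluster=alpha_cluster,
                              alpha_form=alpha_form, n_perm=n_perm,
                              seed=int(rng.integers(2**31)))
    onsets = []
    n_missing = 0
    for _ in range(n_boot):
        idx = rng.integers(0, S, size=S)
        groups = np.unique(idx, return_inverse=True)[1]
        onset = first_cluster_onset(tc.values[idx], tc.times_ms,
                                    window_ms=window_ms,
                                    alpha_cluster=alpha_cluster,
                                    alpha_form=alpha_form, n_perm=n_perm,
                                    seed=int(rng.integers(2**31)),
                                    groups=groups)
        if onset is None:
            n_missing += 1
        else:
            onsets.append(onset)
    if onsets:
        onsets = np.asarray(onsets)
        lo, hi = np.percentile(onsets, [2.5, 97.5])
        mean = float(onsets.mean())
    else:
        lo = hi = mean = float("nan")
    return OnsetCI(model=tc.model,
                   onset_ms=float("nan") if obs is None else float(obs),
                   mean_ms=mean, ci_low_ms=float(lo), ci_high_ms=float(hi),
                   n_boot=n_boot, missing_fraction=n_missing / n_boot)
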