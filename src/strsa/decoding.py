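"""Time-resolved neural RDMs from epoched EEG via cross-validated pairwise
classification.

For every pair of conditions and every time bin, a linear maximum-margin
classifier (hinge-loss SVM, cost C = 1, trained by dual coordinate descent)
is trained on all channels in a leave-one-chunk-out scheme over balanced
partitions; mean held-out accuracy over folds fills one cell of the neural
RDM at that bin. Channels are z-scored per fold using training-set statistics
only. The classifier is implemented in numba because the recovery analyses
need millions of tiny fits; a libsvm-based reference is used as an
independent check in the test suite.

Binning follows the convention of averaging ``width`` consecutive samples and
assigning the result to the center sample of the window (the 3rd of 5). The
default stride of 1 gives sliding windows at the native sample spacing; a
stride equal to the width gives disjoint bins.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .containers import EpochSet, NeuralRDMStack

__all__ = ["bin_samples", "pairwise_accuracy", "neural_rdm_timecourse"]


class PartitioningError(ValueError):
    """A condition is missing from a cross-validation chunk."""


def bin_samples(epochs: EpochSet, width: int = 5, stride: int = 1) -> EpochSet:
    """Average samples in windows of ``width``, assigned to the center sample.

    stride=1 (default) slides the window one sample at a time; stride=width
    yields disjoint consecutive bins with any trailing remainder dropped.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = epochs.n_samples
    if width > n:
        raise ValueError(f"bin width {width} exceeds {n} samples")
    starts = np.arange(0, n - width + 1, stride)
    center = (width - 1) // 2
    # cumulative-sum window means over the time axis
    cs = np.concatenate([np.zeros(epochs.data.shape[:2] + (1,)),
                         np.cumsum(epochs.data, axis=2)], axis=2)
    binned = (cs[:, :, starts + width] - cs[:, :, starts]) / width
    return EpochSet(
        data=binned,
        conditions=epochs.conditions,
        chunks=epochs.chunks,
        sfreq=epochs.sfreq / stride,
        times_ms=epochs.times_ms[starts + center],
    )


@njit(cache=True)
def _dcd_linear_svm(X, y, C, max_passes, tol):
    """Dual coordinate descent for the hinge-loss linear SVM.

    X carries the bias as an appended constant feature (so the intercept is
    regularized, as in liblinear's default formulation). Coordinates are
    visited in a fixed cyclic order so results are deterministic.
    """
    n, d = X.shape
    alpha = np.zeros(n)
    w = np.zeros(d)
    Qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        Qii[i] = s
    for _ in range(max_passes):
        max_delta = 0.0
        for i in range(n):
            if Qii[i] <= 0.0:
                continue
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            G = y[i] * g - 1.0
            if alpha[i] == 0.0 and G >= 0.0:
                continue
            if alpha[i] == C and G <= 0.0:
                continue
            a_old = alpha[i]
            a_new = a_old - G / Qii[i]
            if a_new < 0.0:
                a_new = 0.0
            elif a_new > C:
                a_new = C
            delta = a_new - a_old
            if delta != 0.0:
                alpha[i] = a_new
                for j in range(d):
                    w[j] += delta * y[i] * X[i, j]
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            break
    return w


@njit(cache=True)
def _decode_pair_kernel(data, y, chunks, n_chunks, C, max_passes, tol):
    """Fold accuracies for one condition pair, all bins.

    data : trials x channels x bins (both conditions stacked)
    y : +1/-1 per trial;  chunks : fold id per trial
    returns bins x folds accuracy matrix (nan where a fold has no test trial)
    """
    n_trials, n_ch, n_bins = data.shape
    acc = np.full((n_bins, n_chunks), np.nan)
    Xtr = np.empty((n_trials, n_ch + 1))
    Xte = np.empty((n_trials, n_ch + 1))
    for f in range(n_chunks):
        n_tr = 0
        n_te = 0
        for t in range(n_trials):
            if chunks[t] == f:
                n_te += 1
            else:
                n_tr += 1
        if n_te == 0 or n_tr == 0:
            continue
        ytr = np.empty(n_tr)
        yte = np.empty(n_te)
        tr_idx = np.empty(n_tr, dtype=np.int64)
        te_idx = np.empty(n_te, dtype=np.int64)
        a = 0
        b = 0
        for t in range(n_trials):
            if chunks[t] == f:
                te_idx[b] = t
                yte[b] = y[t]
                b += 1
            else:
                tr_idx[a] = t
                ytr[a] = y[t]
                a += 1
        for bin_ in range(n_bins):
            # per-fold z-scoring from training trials
            for j in range(n_ch):
                m = 0.0
                for a in range(n_tr):
                    m += data[tr_idx[a], j, bin_]
                m /= n_tr
                v = 0.0
                for a in range(n_tr):
                    dlt = data[tr_idx[a], j, bin_] - m
                    v += dlt * dlt
                sd = np.sqrt(v / n_tr)
                if sd <= 0.0:
                    sd = 1.0
                for a in range(n_tr):
                    Xtr[a, j] = (data[tr_idx[a], j, bin_] - m) / sd
                for a in range(n_te):
                    Xte[a, j] = (data[te_idx[a], j, bin_] - m) / sd
            for a in range(n_tr):
                Xtr[a, n_ch] = 1.0
            for a in range(n_te):
                Xte[a, n_ch] = 1.0
            w = _dcd_linear_svm(Xtr[:n_tr], ytr, C, max_passes, tol)
            correct = 0
            for a in range(n_te):
                s = 0.0
                for j in range(n_ch + 1):
                    s += w[j] * Xte[a, j]
                pred = 1.0 if s >= 0.0 else -1.0
                if pred == yte[a]:
                    correct += 1
            acc[bin_, f] = correct / n_te
    return acc


def _balanced_subset(conditions, chunks, pair, n_chunks, rng):
    """Trial indices for a pair, balanced per class within every chunk."""
    a, b = pair
    keep = []
    for f in range(n_chunks):
        ia = np.flatnonzero((conditions == a) & (chunks == f))
        ib = np.flatnonzero((conditions == b) & (chunks == f))
        if len(ia) == 0 or len(ib) == 0:
            raise PartitioningError(
                f"condition pair {pair} not present in every chunk (chunk {f})")
        k = min(len(ia), len(ib))
        if len(ia) > k:
            ia = rng.choice(ia, size=k, replace=False)
        if len(ib) > k:
            ib = rng.choice(ib, size=k, replace=False)
        keep.extend(ia)
        keep.extend(ib)
    return np.sort(np.asarray(keep))


def pairwise_accuracy(binned: EpochSet, pair, n_chunks: int = 6, C: float = 1.0,
                      seed: int = 0, max_passes: int = 100,
                      tol: float = 1e-6) -> np.ndarray:
    """Leave-one-chunk-out decoding accuracy time course for one pair.

    Returns the mean over folds of held-out accuracy at every bin. Majority
    classes are subsampled per chunk (seeded) so every fold is balanced.
    """
    if n_chunks < 2:
        raise ValueError("need at least 2 chunks")
    rng = np.random.default_rng((seed, int(pair[0]), int(pair[1])))
    idx = _balanced_subset(binned.conditions, binned.chunks, pair, n_chunks, rng)
    y = np.where(binned.conditions[idx] == pair[0], 1.0, -1.0)
    acc = _decode_pair_kernel(
        np.ascontiguousarray(binned.data[idx]), y,
        binned.chunks[idx].astype(np.int64), n_chunks, C, max_passes, tol)
    return np.nanmean(acc, axis=1)


def neural_rdm_timecourse(binned: EpochSet, n_chunks: int = 6, C: float = 1.0,
                          seed: int = 0, subject: int = 0,
                          max_passes: int = 100,
                          tol: float = 1e-6) -> NeuralRDMStack:
    """Decode all condition pairs at every bin into a neural RDM stack.

    Pairs are decoded independently (fixed per-pair seeds), in the canonical
    lower-triangle order over the sorted condition labels, so results do not
    depend on execution order.
    """
    labels = binned.condition_labels
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 conditions")
    n_bins = binned.data.shape[2]
    vectors = np.empty((n_bins, n * (n - 1) // 2))
    k = 0
    for i in range(n):
        for j in range(i):
            vectors[:, k] = pairwise_accuracy(
                binned, (labels[i], labels[j]), n_chunks=n_chunks, C=C,
                seed=seed, max_passes=max_passes, tol=tol)
            k += 1
    return NeuralRDMStack(vectors=vectors, labels=labels,
                          times_ms=binned.times_ms, subject=subject)
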