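"""Model RDM construction: image-feature RDMs via a pluggable extractor
(with an in-repo GIST-style global scene descriptor), binary attribute RDMs,
and collinearity-driven reduction of a candidate model set.

The GIST-style descriptor summarizes an image by the local energy of a bank
of oriented log-Gabor filters (default 4 scales x 8 orientations), averaged
over a coarse spatial grid (default 4 x 4), giving a 512-dimensional global
descriptor of scene layout. Filters are one-sided in the frequency domain, so
the magnitude response is the analytic-signal envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .rdm import (CollinearityError, ModelRDM, ModelSet, normalize_model,
                  vif_scores)

__all__ = ["ImageSet", "gist_filter_bank", "gist_descriptor", "feature_rdm",
           "binary_attribute_rdm", "reduce_by_vif"]


@dataclass
class ImageSet:
    """Grayscale images grouped by condition (each with >= 1 exemplar).

    images maps condition label -> list of 2-D luminance arrays; all arrays
    must share one shape (resize before constructing the set).
    """

    images: dict = field(repr=False)

    def __post_init__(self):
        if not self.images:
            raise ValueError("empty image set")
        shapes = set()
        for label, exemplars in self.images.items():
            if len(exemplars) < 1:
                raise ValueError(f"condition {label!r} has no exemplars")
            for img in exemplars:
                if np.ndim(img) != 2:
                    raise ValueError("images must be 2-D grayscale arrays")
                shapes.add(np.shape(img))
        if len(shapes) != 1:
            raise ValueError(f"inconsistent image shapes: {shapes}")

    @property
    def labels(self) -> list:
        return list(self.images.keys())


def gist_filter_bank(size: int, n_scales: int = 4, n_orientations: int = 8,
                     sigma_octaves: float = 0.55,
                     sigma_theta: float | None = None) -> np.ndarray:
    """Frequency-domain transfer functions, shape (scales*orients, size, size).

    Log-Gabor radial profile (center frequency 0.25/2^s cycles/pixel) times a
    one-sided angular Gaussian around each orientation. DC is zero.
    """
    if sigma_theta is None:
        sigma_theta = 0.6 * np.pi / n_orientations
    fx = np.fft.fftfreq(size)
    fy = np.fft.fftfreq(size)
    FX, FY = np.meshgrid(fx, fy, indexing="xy")
    f = np.hypot(FX, FY)
    theta = np.arctan2(FY, FX)
    filters = np.empty((n_scales * n_orientations, size, size))
    with np.errstate(divide="ignore"):
        logf = np.log2(np.where(f > 0, f, 1.0))
    k = 0
    for s in range(n_scales):
        f0 = 0.25 / (2 ** s)
        radial = np.exp(-((logf - np.log2(f0)) ** 2) / (2 * sigma_octaves ** 2))
        radial[f == 0] = 0.0
        for o in range(n_orientations):
            t0 = o * np.pi / n_orientations
            dt = np.angle(np.exp(1j * (theta - t0)))  # wrapped to (-pi, pi]
            angular = np.exp(-(dt ** 2) / (2 * sigma_theta ** 2))
            filters[k] = radial * angular
            k += 1
    return filters


def gist_descriptor(image: np.ndarray, n_scales: int = 4,
                    n_orientations: int = 8, grid: int = 4,
                    size: int = 128) -> np.ndarray:
    """GIST-style global descriptor: oriented filter energy on a spatial grid.

    The image is resized to ``size x size``, filtered by the log-Gabor bank,
    and each filter's magnitude response is averaged within a ``grid x grid``
    partition, giving a deterministic length
    ``n_scales * n_orientations * grid**2`` vector (512 by default). An
    all-constant image has zero energy in every channel (warned).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.shape != (size, size):
        from skimage.transform import resize
        img = resize(img, (size, size), anti_aliasing=True, mode="reflect")
    if np.ptp(img) == 0:
        warnings.warn("constant image yields a zero-energy descriptor",
                      stacklevel=2)
    bank = _cached_bank(size, n_scales, n_orientations)
    F = np.fft.fft2(img - img.mean())
    block = size // grid
    if block * grid != size:
        raise ValueError("working size must be divisible by the pooling grid")
    desc = np.empty(len(bank) * grid * grid)
    for i, G in enumerate(bank):
        energy = np.abs(np.fft.ifft2(F * G))
        pooled = energy.reshape(grid, block, grid, block).mean(axis=(1, 3))
        desc[i * grid * grid:(i + 1) * grid * grid] = pooled.ravel()
    return desc


_BANK_CACHE: dict = {}


def _cached_bank(size, n_scales, n_orientations):
    key = (size, n_scales, n_orientations)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = gist_filter_bank(size, n_scales, n_orientations)
    return _BANK_CACHE[key]


def _pearson_dissim(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("constant feature vector; 1 - r is undefined")
    return 1.0 - float(a @ b) / (na * nb)


def feature_rdm(images: ImageSet, extractor=gist_descriptor,
                metric: str = "pearson", exemplar_average: str = "pairs",
                name: str = "feature") -> ModelRDM:
    """Model RDM from per-image feature vectors, averaged over exemplars.

    exemplar_average='pairs' (default): dissimilarity is computed for every
    cross-exemplar pair of the two conditions and averaged.
    exemplar_average='features': condition features are averaged first and a
    single dissimilarity computed. metric is '1 - Pearson' by default, or
    Euclidean distance. The output is normalized (mean 0, sd 1); identical
    features everywhere raise a degenerate-model error.
    """
    if metric not in ("pearson", "euclidean"):
        raise ValueError("metric must be 'pearson' or 'euclidean'")
    if exemplar_average not in ("pairs", "features"):
        raise ValueError("exemplar_average must be 'pairs' or 'features'")
    feats = {lab: [np.asarray(extractor(img), dtype=float)
                   for img in imgs]
             for lab, imgs in images.images.items()}
    labels = images.labels
    if exemplar_average == "features":
        feats = {lab: [np.mean(v, axis=0)] for lab, v in feats.items()}

    def dissim(a, b):
        if metric == "pearson":
            return _pearson_dissim(a, b)
        return float(np.linalg.norm(a - b))

    vec = []
    for i in range(len(labels)):
        for j in range(i):
            pairs = [dissim(fa, fb)
                     for fa in feats[labels[i]] for fb in feats[labels[j]]]
            vec.append(float(np.mean(pairs)))
    return normalize_model(ModelRDM(name=name, vector=np.asarray(vec)))


def binary_attribute_rdm(labels, name: str = "binary",
                         normalize: bool = True) -> ModelRDM:
    """RDM from a per-condition binary attribute: 0 if same label, 1 if not.

    Exactly two distinct label values are required across conditions (an
    all-same attribute is degenerate).
    """
    labels = np.asarray(labels)
    distinct = np.unique(labels)
    if len(distinct) > 2:
        raise ValueError(f"attribute is not binary: {len(distinct)} values")
    n = len(labels)
    vec = np.array([0.0 if labels[i] == labels[j] else 1.0
                    for i in range(n) for j in range(i)])
    m = ModelRDM(name=name, vector=vec)
    return normalize_model(m) if normalize else m


def reduce_by_vif(candidates: ModelSet, threshold: float = 2.0,
                  keep: tuple = ()) -> tuple[ModelSet, list]:
    """Greedily drop the highest-VIF model until all VIFs fall below threshold.

    Perfectly collinear members (singular correlation matrix, e.g. a
    duplicated model) count as infinite VIF and are removed first. Ties break
    toward the member appearing later in the input order. Members named in
    ``keep`` are never removed (a warning is emitted if that blocks the
    threshold). Returns the reduced set and a removal log of
    ``(name, vif_at_removal)`` entries.
    """
    if threshold <= 1:
        raise ValueError("VIF threshold must exceed 1")
    members = list(candidates.members)
    removed: list = []
    while len(members) > 1:
        R = np.corrcoef(np.column_stack([m.vector for m in members]),
                        rowvar=False)
        try:
            vifs = vif_scores(R)
        except CollinearityError:
            vifs = None
        if vifs is not None and np.all(vifs < threshold):
            break
        removable = [i for i in range(len(members))
                     if members[i].name not in keep]
        if not removable:
            warnings.warn("keep-list prevents reaching the VIF threshold",
                          stacklevel=2)
            break
        if vifs is None:
            # implicate members loading on the near-null eigenvector
            w, V = np.linalg.eigh(R)
            loading = np.abs(V[:, 0])
            implicated = [i for i in removable if loading[i] > 1e-8]
            pool = implicated if implicated else removable
            idx = max(pool)
            vif_at_removal = float("inf")
        else:
            vmax = max(vifs[i] for i in removable)
            idx = max(i for i in removable if vifs[i] >= vmax - 1e-12)
            vif_at_removal = float(vifs[idx])
        removed.append((members[idx].name, vif_at_removal))
        del members[idx]
    return ModelSet(members=tuple(members)), removed
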