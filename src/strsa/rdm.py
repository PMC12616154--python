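"""Core representational-dissimilarity-matrix (RDM) containers and scalar math.

Every stage of the pipeline exchanges RDMs in a single canonical vector form:
the lower triangle read row-major over ``i > j``, i.e. the order produced by
``numpy.tril_indices(n, -1)``::

    (1,0), (2,0), (2,1), (3,0), (3,1), (3,2), ...

A vector of length ``n(n-1)/2`` therefore always corresponds to an ``n x n``
symmetric, zero-diagonal matrix, and ``vectorize``/``unvectorize`` are exact
inverses of each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "RDM",
    "ModelRDM",
    "ModelSet",
    "vectorize",
    "unvectorize",
    "n_conditions_from_vector",
    "normalize_model",
    "rank_correlation",
    "fisher_z",
    "vif_scores",
    "read_rdm_csv",
    "write_rdm_csv",
]

_SYMMETRY_TOL = 1e-8
#: |r| is clamped to this before atanh so group averages stay finite.
FISHER_CLAMP = 1.0 - 1e-12


class DegenerateModelError(ValueError):
    """A model RDM carries no variance (constant dissimilarities)."""


class CollinearityError(ValueError):
    """A model set is perfectly (or numerically) collinear."""


def _check_square_symmetric(values: np.ndarray, tol: float = _SYMMETRY_TOL) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {values.shape}")
    if not np.allclose(values, values.T, atol=tol, rtol=0):
        raise ValueError("RDM matrix is not symmetric within tolerance")
    if not np.allclose(np.diag(values), 0.0, atol=tol, rtol=0):
        raise ValueError("RDM diagonal is not zero within tolerance")
    return values


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Lower-triangle vector (row-major over ``i > j``) of a symmetric RDM.

    Raises ``ValueError`` if the input is asymmetric or has a nonzero
    diagonal beyond a small numeric tolerance.
    """
    matrix = _check_square_symmetric(matrix)
    i, j = np.tril_indices(matrix.shape[0], -1)
    return matrix[i, j].copy()


def n_conditions_from_vector(vector: np.ndarray) -> int:
    """Recover n from a length-n(n-1)/2 pair vector."""
    m = len(vector)
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a valid pair count n(n-1)/2")
    return n


def unvectorize(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the symmetric zero-diagonal matrix."""
    vector = np.asarray(vector, dtype=float)
    n = n_conditions_from_vector(vector)
    out = np.zeros((n, n))
    i, j = np.tril_indices(n, -1)
    out[i, j] = vector
    out[j, i] = vector
    return out


@dataclass
class RDM:
    """A labeled symmetric dissimilarity structure.

    Parameters
    ----------
    labels
        Ordered condition identifiers, ``n >= 2``.
    values
        ``n x n`` symmetric matrix with zero diagonal. Units are whatever the
        producing stage used (e.g. pairwise decoding accuracy, 1 - r).
    """

    labels: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if len(self.labels) < 2:
            raise ValueError("an RDM needs at least 2 conditions")
        self.values = _check_square_symmetric(self.values)
        if self.values.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def vector(self) -> np.ndarray:
        return vectorize(self.values)

    @classmethod
    def from_vector(cls, labels, vector) -> "RDM":
        return cls(labels=tuple(labels), values=unvectorize(vector))


@dataclass
class ModelRDM:
    """A named model RDM held in vector form (optionally normalized)."""

    name: str
    vector: np.ndarray = field(repr=False)
    normalized: bool = False

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.ndim != 1:
            raise ValueError("model RDM vector must be 1-D")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"model '{self.name}' contains non-finite entries")
        n_conditions_from_vector(self.vector)  # validates length
        if self.normalized:
            if abs(self.vector.mean()) > 1e-10 or abs(self.vector.std() - 1.0) > 1e-10:
                raise ValueError(f"model '{self.name}' flagged normalized but is not")


def normalize_model(model: ModelRDM) -> ModelRDM:
    """Mean-center and standardize a model RDM vector (population sd).

    Idempotent: an already-normalized vector is returned unchanged up to
    floating point. A constant vector raises :class:`DegenerateModelError`.
    """
    sd = model.vector.std()  # population sd (ddof=0), the documented convention
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateModelError(f"model '{model.name}' has zero variance")
    v = (model.vector - model.vector.mean()) / sd
    return replace(model, vector=v, normalized=True)


def rank_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average-rank tie handling."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(a) < 3:
        raise ValueError("rank correlation needs length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for zero-variance input")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def fisher_z(r) -> np.ndarray | float:
    """Fisher z-transform, ``z = atanh(r)``.

    Correlations with ``|r| >= 1`` (exact model-to-data matches do occur on
    noiseless synthetic input) are clamped to ``+/-(1 - 1e-12)`` with a
    warning so downstream group averages stay finite.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > FISHER_CLAMP):
        warnings.warn("|r| >= 1 clamped before Fisher z-transform", stacklevel=2)
        r = np.clip(r, -FISHER_CLAMP, FISHER_CLAMP)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def vif_scores(corr_matrix: np.ndarray) -> np.ndarray:
    """Variance inflation factors from a predictor correlation matrix.

    VIF_j is the j-th diagonal element of the inverse correlation matrix,
    equivalent to ``1 / (1 - R²_j)`` from regressing predictor j on the rest.
    The matrix must be a valid correlation matrix (symmetric, unit diagonal,
    positive definite); perfect collinearity raises
    :class:`CollinearityError`.
    """
    R = np.asarray(corr_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise CollinearityError("correlation matrix is not positive definite "
                                "(perfectly collinear models?)") from None
    return np.diag(np.linalg.inv(R)).copy()


@dataclass
class ModelSet:
    """An ordered collection of normalized model RDMs with collinearity metadata."""

    members: tuple

    def __post_init__(self):
        self.members = tuple(self.members)
        if len(self.members) < 1:
            raise ValueError("empty model set")
        lengths = {len(m.vector) for m in self.members}
        if len(lengths) != 1:
            raise ValueError("model RDM vectors differ in length")
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate model names")

    @property
    def names(self) -> list:
        return [m.name for m in self.members]

    def matrix(self) -> np.ndarray:
        """Stack member vectors as columns (pairs x models)."""
        return np.column_stack([m.vector for m in self.members])

    @property
    def corr_matrix(self) -> np.ndarray:
        X = self.matrix()
        if X.shape[1] == 1:
            return np.ones((1, 1))
        return np.corrcoef(X, rowvar=False)

    @property
    def vifs(self) -> np.ndarray:
        if len(self.members) == 1:
            return np.ones(1)
        return vif_scores(self.corr_matrix)


def write_rdm_csv(rdm: RDM, path, sep: str = ",") -> None:
    """Write an RDM as a square labeled matrix (header row + label column)."""
    import pandas as pd

    df = pd.DataFrame(rdm.values, index=list(rdm.labels), columns=list(rdm.labels))
    df.to_csv(path, sep=sep)


def read_rdm_csv(path, sep: str = ",") -> RDM:
    """Read an RDM written by :func:`write_rdm_csv` (or any labeled square CSV)."""
    import pandas as pd

    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels disagree")
    return RDM(labels=tuple(df.index), values=df.to_numpy(dtype=float))
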