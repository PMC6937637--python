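"""Truncated-SVD embedding of flattened DCT feature vectors.

The m x f^2 matrix M of feature vectors is factored M = U W V^t. Because V
has orthonormal columns, U W = M V, so the r-dimensional coordinates used
for lookup can be computed for training rows and query vectors through the
identical path: right-multiplication by the truncated V. Two scalability
variants are provided: fitting the SVD on a random row subsample and
projecting everything through its V, and the Gram-matrix route that
eigen-decomposes M^t M and takes square roots of its eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

#: Below this row count a dense SVD is used; above it, a Lanczos-type
#: iterative solver (cheaper when r << min(m, f^2)).
DENSE_SVD_MAX_ROWS = 2000

_ARCHIVE_VERSION = 1


@dataclass
class EmbeddingModel:
    """Truncated right-singular matrix V (f^2 x r, orthonormal columns),
    the r leading singular values (non-increasing), and the rank r."""

    V: np.ndarray
    singular_values: np.ndarray
    r: int

    @property
    def f_squared(self) -> int:
        return self.V.shape[0]

    def save(self, path: str | Path) -> None:
        """Persist the model to a single .npz archive (versioned)."""
        np.savez(
            path,
            version=np.array([_ARCHIVE_VERSION]),
            V=self.V,
            singular_values=self.singular_values,
            r=np.array([self.r]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with np.load(path) as data:
            version = int(data["version"][0])
            if version != _ARCHIVE_VERSION:
                raise ValueError(f"unsupported model archive version {version}")
            return cls(
                V=data["V"],
                singular_values=data["singular_values"],
                r=int(data["r"][0]),
            )


@dataclass
class EmbeddedCorpus:
    """Embedded training vectors (m x r) with per-row ids and label maps."""

    vectors: np.ndarray
    ids: list[str]
    labels: list[dict[str, str]]

    def __post_init__(self) -> None:
        if not (len(self.vectors) == len(self.ids) == len(self.labels)):
            raise ValueError("vectors, ids and labels must have equal length")

    def __len__(self) -> int:
        return len(self.ids)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    SVD column signs are arbitrary; fixing them makes outputs reproducible
    and makes the gram/subsampled variants directly comparable."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _validate_rank(M: np.ndarray, r: int) -> None:
    if r <= 0:
        raise ValueError("rank r must be positive")
    if r > min(M.shape):
        raise ValueError(f"rank r={r} exceeds min(M.shape)={min(M.shape)}")


def fit_svd(M: np.ndarray, r: int) -> tuple[EmbeddingModel, np.ndarray]:
    """Fit a rank-r truncated SVD of M and return (model, embedded rows).

    Embedded rows are computed as M V — identical to U W at full rank and,
    under truncation, identical to what :func:`project` produces for the
    same rows, so the training and query paths coincide exactly.
    """
    M = np.asarray(M, dtype=float)
    _validate_rank(M, r)
    if M.shape[0] <= DENSE_SVD_MAX_ROWS:
        _, s, Vt = scipy.linalg.svd(M, full_matrices=False)
        s, Vt = s[:r], Vt[:r]
    else:
        _, s, Vt = scipy.sparse.linalg.svds(M, k=r)
        order = np.argsort(s)[::-1]
        s, Vt = s[order], Vt[order]
    V = _fix_signs(Vt.T)
    model = EmbeddingModel(V=V, singular_values=s, r=r)
    return model, M @ V


def project(model: EmbeddingModel, v: np.ndarray) -> np.ndarray:
    """Project feature vector(s) into the r-dimensional lookup space (v V).

    Accepts a single length-f^2 vector or a stack of them. Each vector is
    expected to be centred by its own mean already (the spectral stage does
    this); no re-centring with a training mean is applied.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != model.f_squared:
        raise ValueError(
            f"feature length {v.shape[-1]} != model input dimension {model.f_squared}"
        )
    return v @ model.V


def fit_svd_subsampled(
    M: np.ndarray, r: int, fraction: float, seed: int
) -> tuple[EmbeddingModel, np.ndarray]:
    """Fit the SVD on a seeded uniform row subsample, then project all rows.

    Rows omitted from the subsample are handled exactly like query vectors:
    right-multiplied by the subsample's V. With fraction=1 this reduces to
    :func:`fit_svd`.
    """
    M = np.asarray(M, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = M.shape[0]
    n_sub = int(np.ceil(fraction * m))
    if n_sub < r:
        raise ValueError(f"subsample of {n_sub} rows is smaller than rank r={r}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=n_sub, replace=False))
    model, _ = fit_svd(M[idx], r)
    return model, M @ model.V


def fit_svd_gram(M: np.ndarray, r: int) -> EmbeddingModel:
    """Gram-matrix SVD variant: eigen-decompose M^t M and take square roots.

    Produces the same V (up to column signs, which the sign convention
    normalises away) and the same singular values as the direct SVD;
    negative eigenvalues arising from round-off are clamped to zero.
    """
    M = np.asarray(M, dtype=float)
    _validate_rank(M, r)
    gram = M.T @ M
    eigvals, eigvecs = scipy.linalg.eigh(gram)
    eigvals = np.clip(eigvals[::-1], 0.0, None)[:r]
    V = _fix_signs(eigvecs[:, ::-1][:, :r])
    return EmbeddingModel(V=V, singular_values=np.sqrt(eigvals), r=r)
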