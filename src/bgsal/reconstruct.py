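"""Dense (PCA) and sparse (L1) reconstruction errors against the dictionary.

A superpixel resembling the background dictionary is reconstructed with a
small residual; a salient superpixel is not.  The dense route projects
each feature vector onto the leading eigenvectors of the dictionary's
covariance; the sparse route encodes it as an L1-regularized combination
of dictionary atoms.  Both squared residuals are min-max normalized and
used as complementary saliency measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LassoLars

from bgsal.errors import SolverError

__all__ = [
    "DenseModel",
    "ErrorVector",
    "SparseConfig",
    "fit_dense_model",
    "dense_errors",
    "sparse_errors",
    "normalize_errors",
]


@dataclass(frozen=True)
class DenseModel:
    """PCA basis of the dictionary atoms plus the global mean feature.

    ``V`` has orthonormal columns (eigenvectors of the atom covariance,
    largest eigenvalues first); reconstruction of a feature ``f`` is
    ``V V^T (f - f_bar) + f_bar`` where ``f_bar`` is the mean feature of
    *all* superpixels, not of the dictionary.
    """

    V: np.ndarray  # (D, D') orthonormal columns
    f_bar: np.ndarray  # (D,)
    eigenvalues: np.ndarray  # all D eigenvalues, non-increasing
    explained_fraction: float
    degenerate: bool = False  # covariance had no positive eigenvalue

    @property
    def n_components(self) -> int:
        return self.V.shape[1]


@dataclass(frozen=True)
class ErrorVector:
    """Per-superpixel non-negative reconstruction errors."""

    values: np.ndarray
    kind: str  # "dense" | "sparse"
    normalized: bool = False


@dataclass(frozen=True)
class SparseConfig:
    """L1 solver settings.  ``lam = 0`` (ordinary least squares on the
    atoms) is permitted for testing only."""

    lam: float = 0.01
    tol: float = 1e-8  # kept for interface compatibility; LARS is exact
    max_iter: int = 2000


def fit_dense_model(
    atoms: np.ndarray,
    f_bar: np.ndarray,
    explained_fraction: float = 0.95,
) -> DenseModel:
    """Eigendecompose the covariance of the dictionary atoms.

    The covariance is centered on the atoms' own mean; reconstruction
    nevertheless uses ``f_bar`` (mean of all superpixels) — the asymmetry
    is deliberate.  ``D'`` is the smallest number of leading eigenvectors
    whose cumulative eigenvalue share reaches ``explained_fraction``.
    """
    atoms = np.asarray(atoms, dtype=float)
    if atoms.ndim != 2 or atoms.shape[0] < 2:
        raise ValueError("need at least 2 dictionary atoms")
    if not 0.0 < explained_fraction <= 1.0:
        raise ValueError("explained_fraction must lie in (0, 1]")
    centered = atoms - atoms.mean(axis=0)
    cov = centered.T @ centered / atoms.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total <= 0:
        # all atoms identical: keep a single (arbitrary) direction
        return DenseModel(
            V=eigvecs[:, :1],
            f_bar=np.asarray(f_bar, dtype=float),
            eigenvalues=eigvals,
            explained_fraction=explained_fraction,
            degenerate=True,
        )
    share = np.cumsum(eigvals) / total
    n_comp = int(np.searchsorted(share, explained_fraction - 1e-12) + 1)
    n_comp = min(n_comp, eigvals.shape[0])
    return DenseModel(
        V=eigvecs[:, :n_comp],
        f_bar=np.asarray(f_bar, dtype=float),
        eigenvalues=eigvals,
        explained_fraction=explained_fraction,
    )


def dense_errors(model: DenseModel, F: np.ndarray, normalize: bool = True) -> ErrorVector:
    """Squared residual after projection onto the dense basis.

    ``err_i = || f_i - (V V^T (f_i - f_bar) + f_bar) ||^2``.
    """
    F = np.asarray(F, dtype=float)
    centered = F - model.f_bar
    coeffs = centered @ model.V  # gamma_i, one row per superpixel
    residual = centered - coeffs @ model.V.T
    values = np.einsum("ij,ij->i", residual, residual)
    ev = ErrorVector(values=values, kind="dense")
    return normalize_errors(ev) if normalize else ev


def sparse_errors(
    atoms: np.ndarray,
    F: np.ndarray,
    config: SparseConfig | None = None,
    normalize: bool = True,
) -> ErrorVector:
    """Squared residual of the L1-regularized encoding over the atoms.

    Solves ``min_a ||f_i - B a||^2 + lam * ||a||_1`` for each feature row
    (atoms as columns of ``B``) and reports ``||f_i - B a||^2``.
    """
    config = config or SparseConfig()
    B = np.asarray(atoms, dtype=float).T  # (D, n_atoms): atoms as columns
    F = np.asarray(F, dtype=float)
    n_dim = B.shape[0]
    values = np.empty(F.shape[0])
    if config.lam == 0.0:
        coef, *_ = np.linalg.lstsq(B, F.T, rcond=None)
        resid = F.T - B @ coef
        values = np.einsum("ij,ij->j", resid, resid)
    else:
        # sklearn minimizes (1/2n)||y - Xw||^2 + alpha ||w||_1; LARS gives
        # the exact solution and is robust at small lam on overcomplete B
        alpha = config.lam / (2.0 * n_dim)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign degenerate-atom warnings
            for i, f in enumerate(F):
                solver = LassoLars(
                    alpha=alpha, fit_intercept=False, max_iter=config.max_iter
                )
                solver.fit(B, f)
                resid = f - B @ solver.coef_
                if not np.isfinite(resid).all():
                    raise SolverError(
                        f"L1 solver diverged for superpixel {i}",
                        n_iter=int(np.atleast_1d(solver.n_iter_)[0]),
                    )
                values[i] = float(resid @ resid)
    ev = ErrorVector(values=values, kind="sparse")
    return normalize_errors(ev) if normalize else ev


def normalize_errors(errors: ErrorVector | np.ndarray) -> ErrorVector:
    """Min-max normalize to [0, 1]; a constant vector maps to all zeros."""
    if isinstance(errors, ErrorVector):
        values, kind = errors.values, errors.kind
    else:
        values, kind = np.asarray(errors, dtype=float), "dense"
    if np.any(values < 0):
        raise ValueError("errors must be non-negative")
    span = values.max() - values.min()
    if span <= 0:
        out = np.zeros_like(values, dtype=float)
    else:
        out = (values - values.min()) / span
    return ErrorVector(values=out, kind=kind, normalized=True)
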