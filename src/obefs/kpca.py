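"""Kernel principal component analysis with out-of-sample projection.

Classical KPCA: eigendecompose the double-centered Gram matrix
``K' = K - 1K - K1 + 1K1`` (``1`` = n^-1 all-ones), keep the leading
eigenpairs, and scale eigenvectors by ``1/sqrt(lambda)`` so projections are the
kernel-space principal component scores.  New rows are projected through the
cross-kernel, centered with the stored training statistics.

With the linear kernel this reproduces classical PCA scores up to component
sign; with the RBF kernel the default bandwidth is gamma = 1/(D * var(X)).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from sklearn.metrics.pairwise import pairwise_kernels

_KERNELS = ("linear", "rbf", "poly")
# relative eigenvalue floor: components whose eigenvalue falls below
# EIG_RTOL * max(lambda, 1) are treated as numerically zero and dropped
EIG_RTOL = 1e-10


@dataclasses.dataclass
class KpcaModel:
    kernel: str
    kernel_params: dict
    n_components: int  # M actually retained
    training_rows: np.ndarray  # (n_train, D)
    alphas: np.ndarray  # (n_train, M), columns scaled by 1/sqrt(lambda)
    lambdas: np.ndarray  # (M,), descending, all > 0
    k_col_means: np.ndarray  # (n_train,) column means of the raw training K
    k_grand_mean: float
    rank_deficient: bool = False  # fewer positive eigenvalues than requested

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "kernel": self.kernel,
            "kernel_params": self.kernel_params,
            "n_components": self.n_components,
            "k_grand_mean": self.k_grand_mean,
            "rank_deficient": self.rank_deficient,
        }
        np.savez(
            path,
            training_rows=self.training_rows,
            alphas=self.alphas,
            lambdas=self.lambdas,
            k_col_means=self.k_col_means,
            meta=json.dumps(meta),
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "KpcaModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                kernel=meta["kernel"],
                kernel_params=meta["kernel_params"],
                n_components=meta["n_components"],
                training_rows=z["training_rows"],
                alphas=z["alphas"],
                lambdas=z["lambdas"],
                k_col_means=z["k_col_means"],
                k_grand_mean=meta["k_grand_mean"],
                rank_deficient=meta["rank_deficient"],
            )


def _kernel_matrix(X: np.ndarray, Y: np.ndarray, kernel: str, params: dict) -> np.ndarray:
    allowed = {
        "linear": (),
        "rbf": ("gamma",),
        "poly": ("gamma", "degree", "coef0"),
    }[kernel]
    kw = {k: v for k, v in params.items() if k in allowed}
    return pairwise_kernels(X, Y, metric=kernel, **kw)


def fit_kpca(
    X: np.ndarray,
    kernel: str = "rbf",
    kernel_params: dict | None = None,
    n_components: int | None = None,
    variance_retained: float = 0.95,
) -> KpcaModel:
    """Fit KPCA on training rows.

    ``n_components=None`` retains the smallest M whose eigenvalues hold
    ``variance_retained`` of the positive kernel spectrum mass.  If the
    centered kernel has fewer positive eigenvalues than requested, the model
    is returned with fewer components and ``rank_deficient=True``.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if kernel not in _KERNELS:
        raise ValueError(f"kernel must be one of {_KERNELS}")
    params = dict(kernel_params or {})
    if kernel in ("rbf", "poly") and "gamma" not in params:
        var = float(X.var())
        params["gamma"] = 1.0 / (d * var) if var > 0 else 1.0
    if kernel == "rbf" and params["gamma"] <= 0:
        raise ValueError("gamma must be > 0 for the rbf kernel")
    if n_components is not None and n_components >= min(n, d + 1):
        # kernel PCA can yield at most n-1 informative directions, and the
        # reduced space must be smaller than the input dimension
        raise ValueError("n_components must be < min(n_rows, n_cols + 1)")

    K = _kernel_matrix(X, X, kernel, params)
    col_means = K.mean(axis=0)
    grand = float(K.mean())
    Kc = K - col_means[None, :] - col_means[:, None] + grand

    lam, vec = eigh(Kc)  # ascending
    lam, vec = lam[::-1], vec[:, ::-1]
    tol = EIG_RTOL * max(float(lam[0]) if len(lam) else 0.0, 1.0)
    lam = np.where(np.abs(lam) < tol, 0.0, lam)
    pos = lam > 0
    lam_pos, vec_pos = lam[pos], vec[:, pos]

    if n_components is None:
        if len(lam_pos) == 0:
            m = 0
        else:
            frac = np.cumsum(lam_pos) / lam_pos.sum()
            m = int(np.searchsorted(frac, variance_retained) + 1)
        m = min(m, max(d - 1, 1))
        requested = m
    else:
        requested = int(n_components)
        m = min(requested, len(lam_pos))
    rank_deficient = m < requested or len(lam_pos) == 0

    lam_m = lam_pos[:m]
    alphas = vec_pos[:, :m] / np.sqrt(lam_m)[None, :] if m else np.zeros((n, 0))
    return KpcaModel(
        kernel=kernel,
        kernel_params=params,
        n_components=m,
        training_rows=X.copy(),
        alphas=alphas,
        lambdas=lam_m,
        k_col_means=col_means,
        k_grand_mean=grand,
        rank_deficient=rank_deficient,
    )


def transform(model: KpcaModel, X_new: np.ndarray) -> np.ndarray:
    """Project new rows into the fitted component space (n_new x M)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.training_rows.shape[1]:
        raise ValueError(
            f"expected {model.training_rows.shape[1]} columns, got {X_new.shape}"
        )
    Kx = _kernel_matrix(X_new, model.training_rows, model.kernel, model.kernel_params)
    Kc = (
        Kx
        - Kx.mean(axis=1, keepdims=True)
        - model.k_col_means[None, :]
        + model.k_grand_mean
    )
    return Kc @ model.alphas


def fitted_scores(model: KpcaModel) -> np.ndarray:
    """Component scores of the training rows."""
    return transform(model, model.training_rows)
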