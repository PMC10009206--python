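"""Ordination and discriminant analysis with independent fossil projection.

Three related tools:

* correlation-matrix PCA — variables are z-scored by the extant sample's
  means and standard deviations before eigendecomposition, so variables on
  different scales contribute equally;
* FDA — flexible discriminant analysis in its canonical (non-penalized)
  form, fitted by optimal scoring with a linear-regression backend, which
  is equivalent to classical canonical discriminant analysis / LDA;
* pFDA — FDA after phylogenetic GLS whitening of the predictors by
  C(λ)^(-1/2), where C(λ) scales the off-diagonal phylogenetic covariance
  by Pagel's λ. λ can be fixed or profiled over a grid by summed
  per-variable GLS likelihood.

Fossil rows are never used in fitting: every model projects held-out rows
with parameters estimated from extant taxa only, so adding or removing
fossils cannot change the ordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from paleotroph.comparative_stats import _sqrt_inv
from paleotroph.phylo import BMCovariance

logger = logging.getLogger(__name__)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"v{j}" for j in range(X.shape[1])])


# ====================================================================== PCA

@dataclass
class PCAModel:
    """Correlation-matrix PCA fitted on extant rows only."""

    variables: list
    means: np.ndarray = field(repr=False)
    sds: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)   # variables x components
    explained: np.ndarray = field(repr=False)  # proportion of variance
    scores: pd.DataFrame = field(repr=False)   # extant training scores

    def project(self, X_new) -> pd.DataFrame:
        """Project new rows using the extant-fitted standardization and
        rotation; the fit itself is never updated."""
        X_new = _as_frame(X_new)
        missing = [v for v in self.variables if v not in X_new.columns]
        if missing:
            raise ValueError(f"missing variables: {missing}")
        Z = (X_new[self.variables].to_numpy() - self.means) / self.sds
        return pd.DataFrame(Z @ self.loadings, index=X_new.index,
                            columns=self.scores.columns)


def pca_correlation(X) -> PCAModel:
    """PCA of the correlation matrix of extant data.

    Data are z-scored column-wise (ddof=1) and the correlation matrix
    eigendecomposed; loadings are orthonormal eigenvectors, ordered by
    decreasing eigenvalue, and scores are standardized data times loadings.
    """
    X = _as_frame(X)
    if len(X) < 2:
        raise ValueError("need at least 2 rows")
    means = X.to_numpy().mean(axis=0)
    sds = X.to_numpy().std(axis=0, ddof=1)
    constant = [v for v, s in zip(X.columns, sds) if s == 0]
    if constant:
        raise ValueError(f"constant columns cannot be standardized: {constant}")
    Z = (X.to_numpy() - means) / sds
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]
    # deterministic sign: largest-magnitude loading of each axis positive
    signs = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])])
    vecs = vecs * np.where(signs == 0, 1.0, signs)
    cols = [f"PC{i + 1}" for i in range(len(vals))]
    scores = pd.DataFrame(Z @ vecs, index=X.index, columns=cols)
    return PCAModel(list(X.columns), means, sds, vecs,
                    vals / vals.sum(), scores)


# ====================================================================== FDA

@dataclass
class DiscriminantModel:
    """Fitted FDA/pFDA state: discriminant axis weights, class centroids in
    discriminant space, and class priors. pFDA additionally stores λ and
    the extant-fitted whitening transform."""

    method: str                       # "fda" | "pfda"
    variables: list
    classes: list
    weights: np.ndarray = field(repr=False)    # variables x axes
    intercepts: np.ndarray = field(repr=False)
    centroids: np.ndarray = field(repr=False)  # classes x axes
    priors: np.ndarray = field(repr=False)
    discrimination: np.ndarray = field(repr=False)  # squared canonical corr
    scores: pd.DataFrame = field(repr=False)   # extant training coordinates
    lam: float | None = None
    whitener: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_axes(self) -> int:
        return self.weights.shape[1]

    def project(self, X_new) -> pd.DataFrame:
        """Discriminant coordinates of new rows (extant-fitted axes only).

        For pFDA, held-out (fossil) rows are projected on their raw values:
        they carry no covariance with the training tips, so the whitener is
        the identity for them (self-variance not modeled).
        """
        X_new = _as_frame(X_new)
        missing = [v for v in self.variables if v not in X_new.columns]
        if missing:
            raise ValueError(f"missing variables: {missing}")
        D = X_new[self.variables].to_numpy() @ self.weights + self.intercepts
        return pd.DataFrame(D, index=X_new.index, columns=self.scores.columns)


def fda_fit(X, labels, priors=None) -> DiscriminantModel:
    """Fit FDA by optimal scoring with a linear-regression backend.

    Class indicators are regressed on the predictors; the eigenvectors of
    the resulting scoring problem give canonical discriminant axes, which
    are then rescaled so the pooled within-class covariance of the training
    coordinates is the identity. Axes are ordered by decreasing
    discrimination (squared canonical correlation); at most classes − 1
    axes are returned.

    ``priors``: None for training class proportions, "equal", or a mapping
    class → prior.
    """
    X = _as_frame(X)
    labels = pd.Series(labels).astype(str)
    if len(labels) != len(X):
        raise ValueError("labels do not match rows")
    classes = sorted(labels.unique())
    counts = labels.value_counts()
    small = [c for c in classes if counts[c] < 2]
    if len(classes) < 2 or small:
        raise ValueError(f"every class needs >= 2 members; offending: {small}")

    n, p = X.shape
    Xc = X.to_numpy()
    x_mean = Xc.mean(axis=0)
    Xc = Xc - x_mean
    Z = np.column_stack([(labels == c).astype(float) for c in classes])

    # optimal scoring: regress indicators on predictors, eigendecompose
    B, *_ = np.linalg.lstsq(Xc, Z - Z.mean(axis=0), rcond=None)
    Zhat = Xc @ B
    M = Z.T @ Zhat / n
    Dpi = np.diag(Z.mean(axis=0))
    Dh = np.diag(1.0 / np.sqrt(np.diag(Dpi)))
    W = Dh @ (M + M.T) / 2 @ Dh
    vals, vecs = np.linalg.eigh(W)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_axes = min(len(classes) - 1, p, int(np.sum(vals > 1e-10)))
    theta = Dh @ vecs[:, :n_axes]           # class scorings
    A = B @ theta                           # raw axis directions

    # sphere the axes: identity pooled within-class covariance
    D = Xc @ A
    Sw = np.zeros((n_axes, n_axes))
    for c in classes:
        Dc = D[(labels == c).to_numpy()]
        Sw += (Dc - Dc.mean(axis=0)).T @ (Dc - Dc.mean(axis=0))
    Sw /= n - len(classes)
    T = np.linalg.inv(np.linalg.cholesky(Sw)).T
    A = A @ T
    D = Xc @ A
    # deterministic sign convention
    signs = np.sign(A[np.abs(A).argmax(axis=0), np.arange(n_axes)])
    signs = np.where(signs == 0, 1.0, signs)
    A, D = A * signs, D * signs

    centroids = np.vstack([D[(labels == c).to_numpy()].mean(axis=0)
                           for c in classes])
    pri = _resolve_priors(priors, classes, counts, n)
    cols = [f"DA{i + 1}" for i in range(n_axes)]
    scores = pd.DataFrame(D, index=X.index, columns=cols)
    return DiscriminantModel(
        "fda", list(X.columns), classes, A, -x_mean @ A, centroids,
        pri, vals[:n_axes], scores)


def _resolve_priors(priors, classes, counts, n) -> np.ndarray:
    if priors is None:
        pri = np.array([counts[c] / n for c in classes], dtype=float)
    elif isinstance(priors, str) and priors == "equal":
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        pri = np.array([float(priors[c]) for c in classes])
    if np.any(pri <= 0):
        raise ValueError("priors must be positive")
    return pri / pri.sum()


def discriminant_predict(model: DiscriminantModel, X_new) -> pd.DataFrame:
    """Class posterior probabilities for new rows.

    Classes are Gaussian with identity covariance in the (within-class
    sphered) discriminant space, so the posterior is
    π_k·exp(-‖d(x) − μ_k‖²/2) normalized across classes. Ties in the argmax
    break toward the first class in sorted label order. The predicted class
    is appended as a ``predicted`` column.
    """
    D = model.project(X_new).to_numpy()
    d2 = ((D[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    log_post = np.log(model.priors)[None, :] - 0.5 * d2
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    out = pd.DataFrame(post, index=_as_frame(X_new).index,
                       columns=model.classes)
    out["predicted"] = [model.classes[i] for i in post.argmax(axis=1)]
    return out


# ===================================================================== pFDA

def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel-λ transform: off-diagonal entries scaled by λ."""
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def _standardized_whitener(C: np.ndarray, lam: float) -> np.ndarray:
    """C(λ)^(-1/2) after scaling C(λ) to unit mean diagonal.

    The standardization is a global rescaling of the whitened space (FDA is
    invariant to it on training data) chosen so that λ = 0 on an
    ultrametric tree gives exactly the identity whitener, making
    pFDA(λ=0) ≡ FDA, and so that raw-projected fossils live on the same
    scale as whitened extant rows.
    """
    Cl = _lambda_cov(C, lam)
    Cl = Cl / np.diag(Cl).mean()
    return _sqrt_inv(Cl)


def pfda_fit(X, labels, C: BMCovariance, lam="optimize",
             grid=None) -> DiscriminantModel:
    """Phylogenetic FDA: whiten extant predictors by C(λ)^(-1/2), then FDA.

    ``lam`` is a value in [0, 1] or ``"optimize"`` to profile it on a grid
    (default 0 to 1 in steps of 0.01) by summed per-variable GLS likelihood.
    Rows of X must be extant taxa present in C; fossils are projected later
    via :meth:`DiscriminantModel.project` on raw values.
    """
    X = _as_frame(X)
    missing = [t for t in X.index if t not in C.taxon_order]
    if missing:
        raise ValueError(
            f"rows not in the phylogenetic covariance (fossils must be "
            f"projected, not fitted): {missing}")
    C = C.reorder(list(X.index))
    if lam == "optimize":
        lam = optimal_lambda(X, C, grid)
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    P = _standardized_whitener(C.matrix, lam)
    Xw = pd.DataFrame(P @ X.to_numpy(), index=X.index, columns=X.columns)
    model = fda_fit(Xw, labels)
    model.method = "pfda"
    model.lam = lam
    model.whitener = P
    return model


def optimal_lambda(X, C: BMCovariance, grid=None) -> float:
    """Profile Pagel's λ on a grid by summed per-variable GLS likelihood.

    For each grid value, each variable's BM rate σ² is profiled out of the
    Gaussian likelihood with covariance σ²·C(λ); log-likelihoods are summed
    over variables (traits treated as independent) and the maximizing grid
    value returned (ties toward the smaller λ).
    """
    X = _as_frame(X)
    if set(X.index) <= set(C.taxon_order) and list(X.index) != C.taxon_order:
        C = C.reorder(list(X.index))
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    Y = X.to_numpy()
    n = len(Y)
    best_lam, best_ll = None, -np.inf
    for lam in grid:
        Cl = _lambda_cov(C.matrix, lam)
        sign, logdet = np.linalg.slogdet(Cl)
        if sign <= 0:
            continue
        Cinv = np.linalg.inv(Cl)
        ones = np.ones(n)
        w = Cinv @ ones / (ones @ Cinv @ ones)
        R = Y - w @ Y
        ss = np.einsum("ij,ik,kj->j", R, Cinv, R)
        sigma2 = np.clip(ss / n, 1e-300, None)
        ll = float(np.sum(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
                          - 0.5 * logdet))
        if ll > best_ll + 1e-12:
            best_ll, best_lam = ll, float(lam)
    if best_lam is None:
        raise np.linalg.LinAlgError("no grid value gave a valid likelihood")
    return best_lam
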