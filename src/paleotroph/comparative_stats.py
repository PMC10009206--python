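"""Phylogenetic signal and pairwise group-mean comparison.

Blomberg's K measures phylogenetic signal in one trait relative to
Brownian-motion (BM) expectation on a given tree; K_mult is its
multivariate extension, obtained by summing GLS-centered sums of squares
across traits so that K_mult reduces exactly to K for one trait. Both are
tested by permuting trait rows across tips.

"Phylogenetic HSD" is a residual-randomization pairwise comparison of group
means on data whitened by C^(-1/2) — the phylogenetic analogue of Tukey's
honestly-significant-difference test, with p-values from permutation rather
than the studentized range. Classical Tukey's HSD is provided for
non-phylogenetic comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from paleotroph.phylo import BMCovariance

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 1000


@dataclass
class SignalResult:
    """Result of a phylogenetic-signal test (K or K_mult)."""

    statistic: float
    p_value: float | None
    n_permutations: int
    permuted_statistics: np.ndarray | None = field(default=None, repr=False)


@dataclass
class PairwiseResult:
    """Pairwise distances between group means with permutation (or
    studentized-range) p-values. Matrices are symmetric; the distance
    diagonal is 0 and the p-value diagonal 1."""

    groups: list
    distances: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    method: str


def _permutation_p(observed: float, permuted: np.ndarray) -> float:
    """(1 + #{perm >= obs}) / (1 + n): observed counted, never zero."""
    return (1.0 + np.sum(permuted >= observed - 1e-12)) / (1.0 + len(permuted))


def _gls_quantities(C: np.ndarray):
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(C))
    w = Cinv @ ones / (ones @ Cinv @ ones)  # GLS-mean weights
    n = len(C)
    expected = (np.trace(C) - n / Cinv.sum()) / (n - 1)
    return Cinv, w, expected


def _k_statistic(Y: np.ndarray, Cinv: np.ndarray, w: np.ndarray,
                 expected: float) -> float:
    a_hat = w @ Y                      # (p,) phylogenetic GLS mean per trait
    R = Y - a_hat
    num = float(np.sum(R * R))
    den = float(np.sum(R * (Cinv @ R)))
    if den <= 0 or num <= 0:
        raise ValueError("trait matrix is constant; K is undefined")
    return (num / den) / expected


def blomberg_k(y, C: BMCovariance) -> SignalResult:
    """Blomberg's K for a single trait.

    K = [(y-a)'(y-a) / (y-a)'C^{-1}(y-a)] / [(tr C - N/Σ C^{-1}) / (N-1)]
    with a the phylogenetic GLS mean. K = 1 under BM expectation (exactly 1
    when C is proportional to the identity); significance is obtained via
    :func:`k_mult` on the single column.
    """
    y = _align(y, C)
    if y.shape[1] != 1:
        raise ValueError("blomberg_k takes a single trait; use k_mult")
    Cinv, w, expected = _gls_quantities(C.matrix)
    return SignalResult(_k_statistic(y, Cinv, w, expected), None, 0)


def k_mult(Y, C: BMCovariance, n_perm: int = DEFAULT_N_PERMUTATIONS,
           seed: int | None = None) -> SignalResult:
    """Multivariate phylogenetic signal (K_mult) with a permutation test.

    Sums the GLS-centered cross-products across traits; equals Blomberg's K
    for one-dimensional data. The null distribution shuffles trait rows
    across tips.
    """
    Y = _align(Y, C)
    Cinv, w, expected = _gls_quantities(C.matrix)
    observed = _k_statistic(Y, Cinv, w, expected)
    rng = np.random.default_rng(seed)
    n = len(Y)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        Yp = Y[rng.permutation(n)]
        permuted[b] = _k_statistic(Yp, Cinv, w, expected)
    return SignalResult(observed, _permutation_p(observed, permuted),
                        n_perm, permuted)


def _align(Y, C: BMCovariance) -> np.ndarray:
    """Coerce trait data to an (n_taxa, p) array in C's taxon order."""
    if isinstance(Y, pd.DataFrame):
        missing = [t for t in C.taxon_order if t not in Y.index]
        if missing:
            raise ValueError(f"taxa missing from trait table: {missing}")
        Y = Y.loc[C.taxon_order].to_numpy(dtype=float)
    elif isinstance(Y, pd.Series):
        Y = Y.loc[C.taxon_order].to_numpy(dtype=float)[:, None]
    else:
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
    if len(Y) != len(C.taxon_order):
        raise ValueError("trait rows do not match covariance taxa")
    return Y


def _sqrt_inv(C: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition (permutation-
    order invariant, unlike Cholesky)."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("covariance is singular")
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def phylogenetic_hsd(Y, groups, C: BMCovariance,
                     n_perm: int = DEFAULT_N_PERMUTATIONS,
                     seed: int | None = None) -> PairwiseResult:
    """Residual-randomization pairwise comparison of group means under a
    phylogenetic GLS transform.

    Data and the one-hot group design are premultiplied by C^(-1/2); the
    test statistic per pair is the Euclidean distance between group
    least-squares means; the null permutes residuals of the intercept-only
    reduced model. Singleton groups are dropped with a warning.
    """
    Y = _align(Y, C)
    groups = np.asarray(pd.Series(groups).astype(str))
    if len(groups) != len(Y):
        raise ValueError("group labels do not match trait rows")
    counts = pd.Series(groups).value_counts()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"dropping singleton groups: {sorted(singletons)}")
        keep = ~np.isin(groups, singletons)
        Y, groups = Y[keep], groups[keep]
        C = BMCovariance([t for t, k in zip(C.taxon_order, keep) if k],
                         C.matrix[np.ix_(keep, keep)])
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")

    P = _sqrt_inv(C.matrix)
    Yt = P @ Y
    X = np.column_stack([(groups == g).astype(float) for g in levels])
    Xt = P @ X
    ones_t = P @ np.ones((len(Y), 1))

    H_full = np.linalg.pinv(Xt)                   # LS means = H_full @ Yt
    H_red = np.linalg.pinv(ones_t)
    fitted_red = ones_t @ (H_red @ Yt)
    resid_red = Yt - fitted_red

    def pair_distances(Ymat: np.ndarray) -> np.ndarray:
        means = H_full @ Ymat                     # (k, p)
        diff = means[:, None, :] - means[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    observed = pair_distances(Yt)
    rng = np.random.default_rng(seed)
    k = len(levels)
    exceed = np.zeros((k, k))
    for _ in range(n_perm):
        Yb = fitted_red + resid_red[rng.permutation(len(Y))]
        exceed += pair_distances(Yb) >= observed - 1e-12
    pmat = (1.0 + exceed) / (1.0 + n_perm)
    np.fill_diagonal(pmat, 1.0)
    np.fill_diagonal(observed, 0.0)
    return PairwiseResult(
        levels,
        pd.DataFrame(observed, index=levels, columns=levels),
        pd.DataFrame(pmat, index=levels, columns=levels),
        n_perm, "phylo_hsd")


def tukey_hsd(y, groups) -> PairwiseResult:
    """Classical Tukey HSD on a one-way layout (studentized-range
    p-values); distances are absolute differences of group means."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(pd.Series(groups).astype(str))
    levels = sorted(set(groups))
    samples = [y[groups == g] for g in levels]
    if len(levels) < 2 or any(len(s) < 1 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    if sum(len(s) for s in samples) - len(levels) < 2:
        raise ValueError("insufficient residual degrees of freedom")
    res = stats.tukey_hsd(*samples)
    means = np.array([s.mean() for s in samples])
    dist = np.abs(means[:, None] - means[None, :])
    pmat = np.array(res.pvalue, dtype=float)
    np.fill_diagonal(pmat, 1.0)
    pmat = np.clip(pmat, np.finfo(float).tiny, 1.0)
    return PairwiseResult(
        levels,
        pd.DataFrame(dist, index=levels, columns=levels),
        pd.DataFrame(pmat, index=levels, columns=levels),
        0, "tukey")
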