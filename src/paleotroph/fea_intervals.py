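"""Postprocessing of finite-element strain fields: the intervals method.

Each solved FE model is reduced to (a) its mesh-weighted arithmetic mean
(MWAM) strain — the area-weighted mean of element max in-plane principal
strains, a scalar proxy for jaw strength — and (b) an interval
composition: the percentage of model area falling in each of N
equally-wide strain intervals spanning the pooled strain range of all
models. Compositions are compositional data (rows sum to 100%), so before
Euclidean statistics zeros are replaced multiplicatively and a centered
(clr) or isometric (ilr) log-ratio transform is applied. The number of
intervals is chosen by convergence testing: N is increased until the
downstream ordination's pairwise-distance structure stabilizes.

Absolute strain values are comparative only — they are meaningful among
models built under the same assumptions, not as predictions of strain in
real bone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default multiplicative-replacement fraction: zeros become
#: ``DELTA_FRACTION x`` the row's smallest positive part.
DELTA_FRACTION = 0.65

CONVERGENCE_THRESHOLD = 0.99


@dataclass
class StrainField:
    """One FE model's solved state: per-element area (> 0, consistent
    units) and max in-plane principal strain (με, >= 0)."""

    label: str
    areas: np.ndarray = field(repr=False)
    strains: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        self.strains = np.atleast_1d(np.asarray(self.strains, dtype=float))
        if self.areas.size == 0:
            raise ValueError(f"model {self.label!r}: empty mesh")
        if self.areas.shape != self.strains.shape:
            raise ValueError(f"model {self.label!r}: area/strain mismatch")
        if np.any(self.areas <= 0):
            raise ValueError(f"model {self.label!r}: element areas must be > 0")
        if np.any(self.strains < 0):
            raise ValueError(f"model {self.label!r}: negative strain")


@dataclass(frozen=True)
class IntervalSpec:
    """Equal-width strain binning: N intervals over [lower, upper), the
    last optionally open above to absorb strains >= upper."""

    lower: float
    upper: float
    n_intervals: int
    open_upper_tail: bool = True

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.n_intervals < 2:
            raise ValueError("need at least 2 intervals")

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_intervals + 1)


def mwam(field: StrainField) -> float:
    """Mesh-weighted arithmetic mean strain: Σ(strain·area)/Σarea (με)."""
    return float(np.average(field.strains, weights=field.areas))


def pooled_spec(fields, n_intervals: int,
                open_upper_tail: bool = True) -> IntervalSpec:
    """IntervalSpec spanning the pooled [min, max] strain of all models
    (shared bins are required for comparability across models)."""
    lo = min(float(f.strains.min()) for f in fields)
    hi = max(float(f.strains.max()) for f in fields)
    if hi <= lo:
        hi = lo + 1.0  # all strains identical: any width works
    return IntervalSpec(lo, hi, n_intervals, open_upper_tail)


def interval_composition(fields, spec: IntervalSpec) -> pd.DataFrame:
    """Percent of model area per strain interval; one row per model,
    summing to 100. With an open upper tail, strains >= upper fall in the
    final bin; the lowest edge is closed."""
    edges = spec.edges
    rows = {}
    for f in fields:
        if np.any(f.strains < spec.lower - 1e-12):
            raise ValueError(f"model {f.label!r}: strain below interval range")
        idx = np.searchsorted(edges, f.strains, side="right") - 1
        over = idx >= spec.n_intervals
        if np.any(over) and not spec.open_upper_tail:
            if np.any(f.strains > spec.upper):
                raise ValueError(
                    f"model {f.label!r}: strain above interval range "
                    f"(open_upper_tail disabled)")
        idx = np.clip(idx, 0, spec.n_intervals - 1)
        area = np.bincount(idx, weights=f.areas, minlength=spec.n_intervals)
        rows[f.label] = 100.0 * area / f.areas.sum()
    cols = [f"interval_{i + 1}" for i in range(spec.n_intervals)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


# ---------------------------------------------------------- compositional

def impute_zeros(comp: pd.DataFrame,
                 delta_fraction: float = DELTA_FRACTION) -> pd.DataFrame:
    """Multiplicative zero replacement.

    Zeros in a row become δ = ``delta_fraction`` × the row's smallest
    positive value; the non-zero parts are multiplicatively shrunk so the
    row again sums to 100, preserving their ratios. All-zero rows are an
    error.
    """
    X = comp.to_numpy(dtype=float).copy()
    if np.any(X < 0):
        raise ValueError("compositions must be non-negative")
    for i in range(len(X)):
        row = X[i]
        pos = row > 0
        if not pos.any():
            raise ValueError(f"row {comp.index[i]!r} is all zero")
        nz = (~pos).sum()
        if nz == 0:
            continue
        delta = delta_fraction * row[pos].min()
        total = row.sum()
        if nz * delta > 0.5 * total:
            # concentrated rows: cap the replaced mass at half the total so
            # the multiplicative rescale of the non-zero parts stays positive
            delta = 0.5 * total / nz
            logger.debug("row %r: delta capped at %g", comp.index[i], delta)
        row[~pos] = delta
        row[pos] *= (total - nz * delta) / total
    return pd.DataFrame(X, index=comp.index, columns=comp.columns)


def _positive(comp) -> np.ndarray:
    X = np.asarray(comp, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if np.any(X <= 0):
        raise ValueError("log-ratio transforms need strictly positive parts "
                         "(impute zeros first)")
    return X


def clr(comp) -> np.ndarray:
    """Centered log-ratio: log(x / geometric mean(x)); rows sum to 0 and
    the transform is invariant to row rescaling."""
    X = _positive(comp)
    L = np.log(X)
    return L - L.mean(axis=1, keepdims=True)


def helmert_basis(d: int) -> np.ndarray:
    """Fixed orthonormal ilr contrast basis ((d−1) × d), Helmert-type with
    parts in bin order: row k contrasts the geometric mean of the first
    k parts against part k+1. Fixing the basis makes ilr coordinates
    bit-reproducible."""
    V = np.zeros((d - 1, d))
    for k in range(1, d):
        V[k - 1, :k] = 1.0 / k
        V[k - 1, k] = -1.0
        V[k - 1] *= np.sqrt(k / (k + 1.0))
    return V


def ilr(comp) -> np.ndarray:
    """Isometric log-ratio coordinates (D parts → D−1), an isometry from
    the Aitchison geometry onto Euclidean space."""
    X = _positive(comp)
    return clr(X) @ helmert_basis(X.shape[1]).T


def ilr_inverse(coords, total: float = 100.0) -> np.ndarray:
    """Back-transform ilr coordinates to compositions closed to ``total``."""
    Z = np.asarray(coords, dtype=float)
    if Z.ndim == 1:
        Z = Z[None, :]
    Y = np.exp(Z @ helmert_basis(Z.shape[1] + 1))
    return total * Y / Y.sum(axis=1, keepdims=True)


# ------------------------------------------------------------- convergence

def _distance_matrix(comp: pd.DataFrame, downstream: str, labels=None):
    from paleotroph import ordination

    coords = ilr(impute_zeros(comp))
    frame = pd.DataFrame(coords, index=comp.index)
    frame.columns = [f"z{j}" for j in range(frame.shape[1])]
    if downstream == "pca":
        keep = frame.columns[frame.std(ddof=1) > 0]
        if len(keep) == 0:
            return np.zeros((len(frame), len(frame)))
        scores = ordination.pca_correlation(frame[keep]).scores.to_numpy()
    elif downstream == "fda_distances":
        model = ordination.fda_fit(frame, labels)
        scores = model.scores.to_numpy()
    else:
        raise ValueError(f"unknown downstream ordination: {downstream!r}")
    diff = scores[:, None, :] - scores[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def converge_intervals(fields, start_n: int = 10, step: int = 5,
                       criterion_threshold: float = CONVERGENCE_THRESHOLD,
                       downstream: str = "pca", labels=None,
                       max_n: int = 200) -> int:
    """Smallest interval count N (from ``start_n`` in steps of ``step``)
    at which the downstream ordination has stabilized.

    At each N the interval compositions are imputed, ilr-transformed and
    ordinated (PCA, or FDA with ``labels``); convergence is declared when
    the Pearson correlation between consecutive Ns' pairwise-distance
    matrices reaches ``criterion_threshold``. Degenerate (zero-variance)
    distance matrices count as converged. Non-convergence by ``max_n``
    raises rather than returning silently.
    """
    fields = list(fields)
    if len(fields) < 3:
        raise ValueError("need at least 3 models for convergence testing")

    def dists(n):
        comp = interval_composition(fields, pooled_spec(fields, n))
        return _distance_matrix(comp, downstream, labels)

    iu = np.triu_indices(len(fields), k=1)
    prev = dists(start_n)
    n = start_n
    while n + step <= max_n:
        cur = dists(n + step)
        a, b = prev[iu], cur[iu]
        if a.std() == 0 or b.std() == 0:
            r = 1.0  # zero-variance distances: nothing left to stabilize
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        if r >= criterion_threshold:
            return n
        prev, n = cur, n + step
    raise RuntimeError(
        f"interval count did not converge by N={max_n} "
        f"(threshold {criterion_threshold})")
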