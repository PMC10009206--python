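"""Seeded synthetic-data generators for every pipeline stage.

Real inputs to the pipeline are museum measurement tables, EltonTraits
diet percentages, solved FE meshes and time-scaled supertrees. The
generators here produce data with the statistical structure each stage
assumes — Brownian-motion traits on random time-scaled trees with tunable
Pagel's λ, diet-stratified log-normal body masses, class-structured
Gaussian morphometric variables, log-normal element areas with exact
target MWAM strains, and exactly invertible claw arcs — so the whole
pipeline is testable end-to-end with no downloads. Every generator is
deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from paleotroph.claw_morphometrics import ClawArc
from paleotroph.fea_intervals import StrainField
from paleotroph.phylo import BMCovariance, Phylogeny, bm_covariance


def random_coalescent_tree(n_tips: int, seed=None, depth: float = 100.0,
                           prefix: str = "t") -> Phylogeny:
    """Random ultrametric tree: pairs of lineages merge at uniform-random
    ordered times, then node depths are rescaled so the root-to-tip depth
    is ``depth`` Ma."""
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.0, 1.0, n_tips - 1))
    # node records: (children, age); tips have age 0
    nodes = [([], 0.0) for _ in range(n_tips)]
    active = list(range(n_tips))
    for k in range(n_tips - 1):
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        nodes.append(([a, b], float(times[k])))
        active.append(len(nodes) - 1)
    root = active[0]
    scale = depth / nodes[root][1]
    parent = np.full(len(nodes), -1, dtype=int)
    length = np.zeros(len(nodes))
    for idx, (children, age) in enumerate(nodes):
        for c in children:
            parent[c] = idx
            length[c] = (age - nodes[c][1]) * scale
    labels = [f"{prefix}{i + 1}" if i < n_tips else None
              for i in range(len(nodes))]
    # reindex so the root is node 0 (preorder), as Phylogeny expects
    order = [root]
    pos = 0
    while pos < len(order):
        order.extend(np.flatnonzero(parent == order[pos]).tolist())
        pos += 1
    remap = {old: new for new, old in enumerate(order)}
    new_parent = np.array([remap[parent[o]] if parent[o] >= 0 else -1
                           for o in order])
    new_length = np.array([length[o] for o in order])
    new_labels = [labels[o] for o in order]
    return Phylogeny(new_parent, new_length, new_labels)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def simulate_bm_traits(tree: Phylogeny, p: int = 1, sigma2: float = 1.0,
                       lambda_true: float = 1.0, seed=None) -> pd.DataFrame:
    """Tip values of ``p`` independent traits evolving by Brownian motion:
    each trait is a multivariate-normal draw with covariance
    σ²·C(λ_true), where C is the tree's BM covariance and λ_true scales
    the off-diagonal (shared-history) entries."""
    C = bm_covariance(tree)
    cov = sigma2 * _lambda_cov(C.matrix, lambda_true)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    Y = (L @ rng.standard_normal((len(cov), p)))
    return pd.DataFrame(Y, index=C.taxon_order,
                        columns=[f"trait_{j + 1}" for j in range(p)])


def simulate_class_data(classes, n_per_class, means, shared_covariance,
                        seed=None, prefix: str = "s") -> pd.DataFrame:
    """Labeled Gaussian samples with one mean vector per class and a
    shared covariance — the generating model under which LDA/FDA is
    Bayes-optimal. Returns a trait table with a ``label`` column."""
    rng = np.random.default_rng(seed)
    means = {c: np.asarray(means[c], dtype=float) for c in classes}
    cov = np.asarray(shared_covariance, dtype=float)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("shared covariance must be positive definite") from exc
    rows, labels, index = [], [], []
    counts = ({c: int(n_per_class) for c in classes}
              if np.isscalar(n_per_class) else dict(n_per_class))
    i = 0
    for c in classes:
        for _ in range(counts[c]):
            rows.append(means[c] + L @ rng.standard_normal(len(cov)))
            labels.append(c)
            index.append(f"{prefix}{i + 1}")
            i += 1
    out = pd.DataFrame(rows, index=index,
                       columns=[f"v{j + 1}" for j in range(cov.shape[0])])
    out["label"] = labels
    return out


def simulate_masses(diet_params: dict, seed=None) -> pd.DataFrame:
    """Diet-stratified body masses on the log10-gram scale.

    ``diet_params`` maps diet → (n, mean_log10g, sd_log10g); masses are
    log-normal, i.e. normal on the log10 scale the analyses use.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for diet, (n, mu, sd) in diet_params.items():
        logm = rng.normal(mu, sd, int(n))
        for i, v in enumerate(logm):
            rows.append({"taxon": f"{diet.lower()}_{i + 1}", "diet": diet,
                         "log10_mass_g": float(v)})
    return pd.DataFrame(rows).set_index("taxon")


def simulate_strain_fields(model_targets: dict, n_elements: int = 200,
                           dispersion: float = 0.5, seed=None) -> list:
    """Strain fields with exact target MWAM strains.

    Element areas are log-normal; raw strains are log-normal with
    log-scale sd ``dispersion`` (per-model values accepted as a dict),
    then rescaled so the realized area-weighted mean equals the target
    exactly — giving sharp oracles for MWAM and interval tests.
    """
    rng = np.random.default_rng(seed)
    disp = (dispersion if isinstance(dispersion, dict)
            else {m: dispersion for m in model_targets})
    fields = []
    for label, target in model_targets.items():
        if target <= 0:
            raise ValueError(f"model {label!r}: target MWAM must be > 0")
        areas = rng.lognormal(0.0, 0.3, n_elements)
        raw = rng.lognormal(0.0, disp[label], n_elements)
        realized = np.average(raw, weights=areas)
        fields.append(StrainField(label, areas, raw * (target / realized)))
    return fields


def claw_from_parameters(curvature_deg: float, radius: float) -> ClawArc:
    """Arc landmarks on a circle of the given radius spanning the given
    central angle, mid landmark at the arc midpoint — the exact inverse of
    the claw-geometry operations, for round-trip testing."""
    if not 0.0 < curvature_deg < 360.0:
        raise ValueError("curvature must be in (0, 360) degrees")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    theta = np.deg2rad(curvature_deg)
    angles = (0.0, theta / 2, theta)
    pts = [(radius * np.cos(a), radius * np.sin(a)) for a in angles]
    return ClawArc(pts[0], pts[1], pts[2])


def simulate_elton_rows(n: int, seed=None) -> pd.DataFrame:
    """EltonTraits-style percentage rows in multiples of 10 summing to
    100: each row distributes 10 decads over the nine diet columns with a
    random concentration, producing a mix of specialists and
    generalists."""
    from paleotroph.diet_synthesis import ELTON_COLUMNS
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        alpha = rng.choice([0.15, 0.5, 2.0])
        w = rng.dirichlet(np.full(len(ELTON_COLUMNS), alpha))
        decads = np.floor(w * 10).astype(int)
        short = 10 - decads.sum()
        frac = w * 10 - np.floor(w * 10)
        for j in np.argsort(frac)[::-1][:short]:
            decads[j] += 1
        rows.append(decads * 10.0)
    return pd.DataFrame(rows, columns=list(ELTON_COLUMNS),
                        index=[f"sp{i + 1}" for i in range(n)])


def pathological_presets(seed=0) -> dict:
    """Inputs that exercise downstream error paths: an all-zero
    composition row, a singleton ecological group, and a claw record with
    a missing digit."""
    comp = pd.DataFrame(
        [[50.0, 50.0, 0.0], [0.0, 0.0, 0.0]],
        index=["ok", "all_zero"],
        columns=["interval_1", "interval_2", "interval_3"])
    groups = pd.Series(["A", "A", "B", "B", "C"],
                       index=[f"t{i + 1}" for i in range(5)])
    arcs = {d: claw_from_parameters(90.0, 1.0) for d in ("II", "III", "IV")}
    return {"composition_with_all_zero_row": comp,
            "singleton_group_labels": groups,
            "claw_arcs_missing_digit_I": arcs}
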