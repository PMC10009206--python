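"""Diet-category assignment, rater agreement, and multi-proxy synthesis.

Extant diets are assigned from EltonTraits-style percentage columns by
fixed cut-offs (e.g. Granivore at 70+% Diet-Seed, Piscivore at 50+%
Diet-Fish, Generalist when no category exceeds 40%), with tetrapod hunting
scored on Diet-Ect + Diet-End combined. Agreement between predicted and
true diets is scored with Fleiss' kappa. Finally, per-proxy posterior
tables for a fossil are combined into "likely", "unlikely" and "agreed"
diet sets by thresholding each proxy's posteriors and intersecting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

ELTON_COLUMNS = (
    "Diet-PlantO", "Diet-Fruit", "Diet-Seed", "Diet-Nect", "Diet-Inv",
    "Diet-Fish", "Diet-Scav", "Diet-Ect", "Diet-End",
)

#: diet -> (source column, minimum percentage). Diet-Tetr is the sum of
#: Diet-Ect and Diet-End (ectothermic + endothermic tetrapods combined).
DIET_CUTOFFS = {
    "Folivore": ("Diet-PlantO", 60.0),
    "Frugivore": ("Diet-Fruit", 60.0),
    "Granivore": ("Diet-Seed", 70.0),
    "Invertivore": ("Diet-Inv", 60.0),
    "Nectarivore": ("Diet-Nect", 60.0),
    "Piscivore": ("Diet-Fish", 50.0),
    "Scavenger": ("Diet-Scav", 50.0),
    "Tetrapod Hunter": ("Diet-Tetr", 60.0),
}

GENERALIST_MAX = 40.0


def _category_values(row) -> dict:
    row = dict(row)
    missing = [c for c in ELTON_COLUMNS if c not in row]
    if missing:
        raise ValueError(f"missing diet columns: {missing}")
    vals = {c: float(row[c]) for c in ELTON_COLUMNS}
    if any(v < 0 for v in vals.values()):
        raise ValueError("diet percentages must be non-negative")
    total = sum(vals.values())
    if abs(total - 100.0) > 1e-6:
        raise ValueError(f"diet percentages sum to {total}, expected 100")
    vals["Diet-Tetr"] = vals["Diet-Ect"] + vals["Diet-End"]
    return vals


def assign_diet(row) -> str:
    """Diet category for one EltonTraits-style row.

    When two cut-offs fire at once (possible only at 50/50
    piscivore/scavenger-type boundaries) the higher percentage wins; an
    exact tie is "unclassified", as are rows meeting no rule at all.
    """
    vals = _category_values(row)
    fired = [(diet, vals[col]) for diet, (col, cut) in DIET_CUTOFFS.items()
             if vals[col] >= cut]
    if not fired:
        if all(vals[c] <= GENERALIST_MAX
               for c in (*ELTON_COLUMNS, "Diet-Tetr")):
            return "Generalist"
        return "unclassified"
    if len(fired) == 1:
        return fired[0][0]
    fired.sort(key=lambda t: (-t[1], t[0]))
    if fired[0][1] == fired[1][1]:
        return "unclassified"
    return fired[0][0]


@dataclass
class AgreementResult:
    """Fleiss' kappa over a subjects × raters categorical table."""

    kappa: float
    n_subjects: int
    n_raters: int
    categories: list
    degenerate: bool = False  # single category everywhere: kappa undefined


def fleiss_kappa(ratings) -> AgreementResult:
    """Fleiss' kappa κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) for a subjects × raters table
    of categorical labels (e.g. columns "true" and "predicted" diets).

    A table where every rating is the same single category has no chance
    disagreement; the result is flagged degenerate with κ = 1 under
    perfect agreement by convention.
    """
    R = pd.DataFrame(ratings)
    if R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    flat = R.astype(str).to_numpy()
    categories = sorted(np.unique(flat))
    table, _ = aggregate_raters(flat)
    if len(categories) < 2:
        return AgreementResult(1.0, R.shape[0], R.shape[1], categories,
                               degenerate=True)
    kappa = float(_sm_fleiss_kappa(table, method="fleiss"))
    return AgreementResult(kappa, R.shape[0], R.shape[1], categories)


def evidence_summary(posteriors: dict, likely_threshold: float = 0.10) -> dict:
    """Combine per-proxy posterior rows for one fossil.

    ``posteriors`` maps proxy name → mapping/Series of diet → posterior.
    Per proxy, diets at or above ``likely_threshold`` are "likely".
    "agreed" diets are likely in every proxy whose category set covers
    them (category-aware intersection); "unlikely" diets fall below the
    threshold in every proxy that covers them.
    """
    if not posteriors:
        raise ValueError("need at least one proxy posterior table")
    likely_by_proxy = {}
    covered: dict = {}
    for proxy, post in posteriors.items():
        post = pd.Series(post, dtype=float).drop(labels=["predicted"],
                                                 errors="ignore")
        if post.empty:
            raise ValueError(f"proxy {proxy!r} has an empty posterior table")
        likely_by_proxy[proxy] = {d for d, p in post.items()
                                  if p >= likely_threshold}
        for d in post.index:
            covered.setdefault(d, set()).add(proxy)
    all_diets = set(covered)
    agreed = {d for d in all_diets
              if all(d in likely_by_proxy[p] for p in covered[d])}
    likely = set().union(*likely_by_proxy.values())
    unlikely = {d for d in all_diets
                if all(d not in likely_by_proxy[p] for p in covered[d])}
    return {"likely": likely, "unlikely": unlikely, "agreed": agreed,
            "likely_by_proxy": likely_by_proxy}
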