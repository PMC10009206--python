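"""Jaw mechanical advantage and size-free functional indices.

Mechanical advantage (MA) treats the jaw as a lever about its articulation
(the quadrate in birds): MA = in-lever / out-lever. Anterior and posterior
closing MA (AMA, PMA) use the out-lever to the anterior and posterior bite
points; opening MA (OMA) uses the opening in-lever. The shape indices are
relative (length-normalized) heights and offsets: AO (articular offset /
lower-jaw length), ACH (average cranium height), MMH and AMH (maximum and
average mandible height). All quantities are dimensionless ratios, so the
absolute scale of the measurements never matters.

Inputs are measured lever/height/length values; the quadrate-position
sensitivity analysis instead takes 2D point coordinates and recomputes all
levers from alternative articulation positions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from math import isnan

import numpy as np

#: index name -> (numerator field, denominator field)
_RATIOS = {
    "upper_AMA": ("upper_closing_inlever", "upper_anterior_outlever"),
    "upper_PMA": ("upper_closing_inlever", "upper_posterior_outlever"),
    "upper_OMA": ("upper_opening_inlever", "upper_anterior_outlever"),
    "lower_AMA": ("lower_closing_inlever", "lower_anterior_outlever"),
    "lower_PMA": ("lower_closing_inlever", "lower_posterior_outlever"),
    "lower_OMA": ("lower_opening_inlever", "lower_anterior_outlever"),
    "AO": ("articular_offset", "lower_jaw_length"),
    "ACH": ("cranium_avg_height", "cranium_length"),
    "MMH": ("mandible_max_height", "lower_jaw_length"),
    "AMH": ("mandible_avg_height", "lower_jaw_length"),
}


@dataclass
class JawMeasurements:
    """Linear measurements (any consistent unit) for one taxon's jaws.
    Missing values may be NaN; the corresponding index is then NaN while
    the others are still computed."""

    upper_closing_inlever: float = np.nan
    upper_opening_inlever: float = np.nan
    upper_anterior_outlever: float = np.nan
    upper_posterior_outlever: float = np.nan
    lower_closing_inlever: float = np.nan
    lower_opening_inlever: float = np.nan
    lower_anterior_outlever: float = np.nan
    lower_posterior_outlever: float = np.nan
    lower_jaw_length: float = np.nan
    articular_offset: float = np.nan
    cranium_avg_height: float = np.nan
    cranium_length: float = np.nan
    mandible_max_height: float = np.nan
    mandible_avg_height: float = np.nan

    def scaled(self, k: float) -> "JawMeasurements":
        return JawMeasurements(**{f.name: getattr(self, f.name) * k
                                  for f in fields(self)})


def mechanical_advantage(in_lever: float, out_lever: float) -> float:
    """MA = in-lever / out-lever of the jaw about its articulation."""
    if out_lever == 0:
        raise ValueError("out-lever must be non-zero")
    return in_lever / out_lever


def jaw_indices(m: JawMeasurements) -> dict:
    """All MA and functional indices computable from the measurements;
    indices whose fields are missing (NaN) come back NaN."""
    out = {}
    for name, (num, den) in _RATIOS.items():
        a, b = getattr(m, num), getattr(m, den)
        if isnan(a) or isnan(b):
            out[name] = np.nan
        else:
            out[name] = mechanical_advantage(a, b)
    return out


def quadrate_sensitivity(articulation, closing_insertion, opening_insertion,
                         anterior_bite, posterior_bite,
                         alternative_positions) -> list:
    """Recompute lever-based MA for alternative articulation positions.

    All arguments are 2D points; levers are Euclidean distances from the
    articulation to the muscle insertions (in-levers) and bite points
    (out-levers). Returns one dict per scenario — the baseline first, then
    one per alternative position (typically the extreme anterior and
    posterior ends of the articular surface).
    """
    def indices_at(art):
        art = np.asarray(art, dtype=float)
        pts = {"closing": closing_insertion, "opening": opening_insertion,
               "anterior": anterior_bite, "posterior": posterior_bite}
        lev = {}
        for k, p in pts.items():
            d = float(np.linalg.norm(np.asarray(p, dtype=float) - art))
            if d == 0:
                raise ValueError(
                    f"articulation coincides with the {k} lever endpoint")
            lev[k] = d
        return {
            "articulation": tuple(art),
            "AMA": lev["closing"] / lev["anterior"],
            "PMA": lev["closing"] / lev["posterior"],
            "OMA": lev["opening"] / lev["anterior"],
        }

    return [indices_at(articulation)] + [indices_at(p)
                                         for p in alternative_positions]
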