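"""Body-mass estimation and diet-group mass cut-points.

Fossil masses come from a published enantiornithine-specific multiple
regression on six log10 forelimb/hindlimb measurements. Extant species
masses, log10-transformed, are compared between lumped diet groups
(invertivores vs vertivores; folivores+frugivores vs
granivores+nectarivores) and an optimal threshold between each pair is
chosen by maximizing the Youden index J = sensitivity + specificity − 1,
the standard cut-point criterion from diagnostic medicine. A fossil's mass
interval is then read against the thresholds: above, below, or straddling
(inconclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isfinite

import numpy as np

#: Regression coefficients for log10 body mass (g) of enantiornithine
#: birds from six log10 skeletal measurements (mm): humerus length,
#: bicipital crest length, distal humerus width, ulna length, distal ulna
#: width, tibiotarsus length.
ENAN_INTERCEPT = -2.626
ENAN_COEFFICIENTS = {
    "HL": 1.528,
    "bcL": 0.340,
    "dHW": 0.828,
    "UL": -1.451,
    "dUW": 0.811,
    "TL": 0.378,
}

#: Diet-lumping maps for the two mass contrasts. Carnivores split into
#: invertivores vs "vertivores" (vertebrate eaters); herbivores into
#: folivores+frugivores vs granivores+nectarivores.
CARNIVORE_CONTRAST = {
    "low": ("Invertivore",),
    "high": ("Piscivore", "Scavenger", "Tetrapod Hunter"),
}
HERBIVORE_CONTRAST = {
    "high": ("Folivore", "Frugivore"),
    "low": ("Granivore", "Nectarivore"),
}


@dataclass(frozen=True)
class MassMeasurements:
    """log10 skeletal measurements (mm) feeding the mass regression."""

    HL: float
    bcL: float
    dHW: float
    UL: float
    dUW: float
    TL: float

    def __post_init__(self):
        for name in ENAN_COEFFICIENTS:
            v = getattr(self, name)
            if v is None or not isfinite(float(v)):
                raise ValueError(f"measurement {name} missing or non-finite")


def estimate_log_mass(m: MassMeasurements) -> float:
    """log10 body mass (g) from the enantiornithine regression:
    −2.626 + 1.528·HL + 0.34·bcL + 0.828·dHW − 1.451·UL + 0.811·dUW
    + 0.378·TL."""
    return ENAN_INTERCEPT + sum(
        coef * float(getattr(m, name))
        for name, coef in ENAN_COEFFICIENTS.items())


@dataclass
class CutpointResult:
    """Optimal two-group threshold by the Youden index."""

    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    direction: str  # which group lies on the "positive" (high) side

    def __post_init__(self):
        assert abs(self.youden_j - (self.sensitivity + self.specificity - 1)) < 1e-9


def youden_cutpoint(group_a, group_b) -> CutpointResult:
    """Threshold between two samples maximizing J = sens + spec − 1.

    Candidate thresholds are midpoints of adjacent distinct pooled values
    (plus sentinels below/above the data); the group with the larger mean
    is treated as "positive" (above threshold). Ties in J break toward the
    smaller threshold.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    # positive = high-mean group
    if a.mean() >= b.mean():
        high, low, direction = a, b, "a"
    else:
        high, low, direction = b, a, "b"
    pooled = np.unique(np.concatenate([a, b]))
    mids = (pooled[:-1] + pooled[1:]) / 2 if pooled.size > 1 else np.array([])
    candidates = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    sens = (high[None, :] > candidates[:, None]).mean(axis=1)
    spec = (low[None, :] <= candidates[:, None]).mean(axis=1)
    J = sens + spec - 1
    best = int(np.argmax(J))  # argmax takes the first (smallest) threshold
    return CutpointResult(float(candidates[best]), float(J[best]),
                          float(sens[best]), float(spec[best]), direction)


def classify_by_mass(log_mass_interval, cutpoints: dict) -> dict:
    """Read a fossil's [low, high] log-mass interval against per-contrast
    thresholds.

    ``cutpoints`` maps a contrast name to ``(threshold, low_side_label,
    high_side_label)``. An interval entirely on one side supports that
    side's group set; an interval containing the threshold is
    "inconclusive" for that contrast.
    """
    low, high = (float(v) for v in log_mass_interval)
    if low > high:
        raise ValueError("interval low must be <= high")
    out = {}
    for contrast, (thr, low_label, high_label) in cutpoints.items():
        if high < thr:
            out[contrast] = low_label
        elif low > thr:
            out[contrast] = high_label
        else:
            out[contrast] = "inconclusive"
    return out
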