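"""Ungual (claw) outer-arc morphometrics.

Each digit's claw is summarized by the curvature of its outer (dorsal) arc
in degrees and by its outer arc length. The arc is operationalized as the
unique circle through three planar landmarks — base, midpoint, and tip of
the outer arc — with curvature the central angle subtended by the
base-to-tip arc that passes through the midpoint. Arc lengths of digits I,
II and IV are expressed as ratios to digit III, giving a 7-variable,
size-free record per taxon (4 curvatures + 3 ratios).

Both raw landmarks and precomputed curvature/length values are accepted;
the geometry here is a minimal faithful stand-in for the published
landmark protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import atan2, degrees, hypot, pi

import numpy as np

logger = logging.getLogger(__name__)

#: Circumradius-to-chord ratio beyond which an arc is treated as a
#: straight line (collinear landmarks).
COLLINEAR_RADIUS_FACTOR = 1e6

DIGITS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ClawArc:
    """Three planar landmarks on a claw's outer arc."""

    base: tuple
    mid: tuple
    tip: tuple

    def __post_init__(self):
        pts = [np.asarray(p, dtype=float) for p in (self.base, self.mid, self.tip)]
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(pts[i], pts[j]):
                    raise ValueError("claw landmarks must be pairwise distinct")


def _circumcircle(arc: ClawArc):
    """Center and radius of the circle through the three landmarks, or
    ``None`` when they are (numerically) collinear."""
    # center on the landmark centroid first: keeps the computation
    # well-conditioned for shallow arcs far from the coordinate origin
    pts = np.array([arc.base, arc.mid, arc.tip], dtype=float)
    cen = pts.mean(axis=0)
    (ax, ay), (bx, by), (cx, cy) = pts - cen
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    chord = hypot(cx - ax, cy - ay)
    if d == 0.0:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    r = hypot(ax - ux, ay - uy)
    if r > COLLINEAR_RADIUS_FACTOR * chord:
        logger.debug("near-collinear arc treated as straight (r/chord=%g)",
                     r / chord)
        return None
    return (ux + cen[0], uy + cen[1]), r


def arc_curvature(arc: ClawArc) -> float:
    """Outer-arc curvature in degrees: the angle at the circumcircle center
    swept from base to tip through the midpoint landmark. Collinear
    landmarks give 0°."""
    circ = _circumcircle(arc)
    if circ is None:
        return 0.0
    (ux, uy), _ = circ
    ang = {}
    for name, (px, py) in (("base", arc.base), ("mid", arc.mid),
                           ("tip", arc.tip)):
        ang[name] = atan2(py - uy, px - ux)

    def ccw_span(frm, to):
        return (to - frm) % (2 * pi)

    # choose the base->tip direction whose arc contains the midpoint
    span_ccw = ccw_span(ang["base"], ang["tip"])
    mid_ccw = ccw_span(ang["base"], ang["mid"])
    theta = span_ccw if mid_ccw <= span_ccw else 2 * pi - span_ccw
    return degrees(theta)


def arc_length(arc: ClawArc) -> float:
    """Outer arc length r·θ along the fitted circle; the base-tip chord
    length when the landmarks are collinear."""
    circ = _circumcircle(arc)
    if circ is None:
        (ax, ay), (cx, cy) = arc.base, arc.tip
        return hypot(cx - ax, cy - ay)
    _, r = circ
    return r * arc_curvature(arc) * pi / 180.0


@dataclass
class TMRecord:
    """Traditional-morphometric record: per-digit curvature (deg) and arc
    length relative to digit III. ``complete`` is False when any digit is
    missing; incomplete records are excluded from ordination."""

    curvature: dict       # digit -> degrees (np.nan if missing)
    ratio: dict           # digit (I, II, IV) -> length / length_III
    complete: bool

    def to_vector(self) -> dict:
        out = {f"curvature_{d}": self.curvature.get(d, np.nan) for d in DIGITS}
        out.update({f"ratio_{d}": self.ratio.get(d, np.nan)
                    for d in ("I", "II", "IV")})
        return out


def tm_record(arcs: dict) -> TMRecord:
    """Assemble the 7-variable record from per-digit arcs (keys from
    ``DIGITS``; missing digits flag the record incomplete)."""
    unknown = sorted(set(arcs) - set(DIGITS))
    if unknown:
        raise ValueError(f"unknown digits: {unknown}")
    curv = {d: arc_curvature(a) for d, a in arcs.items()}
    lengths = {d: arc_length(a) for d, a in arcs.items()}
    complete = all(d in arcs for d in DIGITS)
    ratio = {}
    if "III" in arcs:
        l3 = lengths["III"]
        if l3 == 0:
            raise ValueError("digit III arc length is zero")
        ratio = {d: lengths[d] / l3 for d in ("I", "II", "IV") if d in arcs}
    return TMRecord(curv, ratio, complete)
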