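"""Membrane-undulation morphometrics on traced EM-section polylines.

The plasma membrane at the T cell:APC interface is traced as a 2D polyline
(µm coordinates) in a single electron-microscopy section. Undulation is
quantified as the ratio of membrane arc length to the straight-line chord
("diameter") of the same interface region. The interface diameter is divided
into four equal sections; the central two sections are the cSMAC, the outer
two the left/right pSMAC. Ratios near 1 indicate a flat membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MembraneTrace",
    "UndulationReport",
    "arc_length",
    "partition_interface",
    "undulation_ratio",
    "undulation_report",
]

#: section index -> region name under the quartering convention
_REGION_OF_SECTION = {0: "pSMAC_left", 1: "cSMAC", 2: "cSMAC", 3: "pSMAC_right"}


@dataclass
class MembraneTrace:
    """An ordered 2D membrane trace with its interface-diameter endpoints.

    Parameters
    ----------
    points : (N, 2) array
        Ordered (x, y) vertices of the traced membrane, in µm.
    endpoints : (2, 2) array
        The two points defining the interface diameter (the chord), in µm.
        They must lie within 0.1 µm of the first and last polyline vertices.
    """

    points: np.ndarray
    endpoints: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.endpoints = np.asarray(self.endpoints, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("trace needs at least two (x, y) points")
        if self.endpoints.shape != (2, 2):
            raise ValueError("endpoints must be two (x, y) points")
        d0 = np.linalg.norm(self.points[0] - self.endpoints[0])
        d1 = np.linalg.norm(self.points[-1] - self.endpoints[1])
        if d0 > 0.1 or d1 > 0.1:
            raise ValueError(
                "interface endpoints must lie within 0.1 µm of the polyline ends "
                f"(got {d0:.3f} and {d1:.3f} µm)"
            )


@dataclass
class UndulationReport:
    """Per-region arc length, chord ('diameter') and undulation ratio."""

    cell_id: str
    regions: dict[str, dict[str, float]] = field(default_factory=dict)
    overhang_flagged: bool = False

    def ratio(self, region: str) -> float:
        return self.regions[region]["ratio"]


def arc_length(points: np.ndarray) -> float:
    """Sum of consecutive Euclidean segment lengths of a polyline (µm).

    Duplicate consecutive points are allowed and contribute zero length.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("need at least two points")
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _chord_parameter(points: np.ndarray, endpoints: np.ndarray):
    """Project polyline vertices onto the chord; return (t, chord length, flag).

    ``t`` is the scalar coordinate of each vertex's orthogonal projection
    along the chord, measured from the first endpoint. Projections falling
    outside [0, L] (membrane overhang past the diameter) are clamped and
    flagged.
    """
    e0, e1 = np.asarray(endpoints, dtype=float)
    chord_vec = e1 - e0
    length = float(np.linalg.norm(chord_vec))
    if length <= 0:
        raise ValueError("interface endpoints must be distinct")
    u = chord_vec / length
    t = (points - e0) @ u
    overhang = bool(np.any(t < -1e-9) or np.any(t > length + 1e-9))
    if overhang:
        warnings.warn(
            "membrane trace overhangs the interface diameter; projections clamped",
            stacklevel=3,
        )
    return np.clip(t, 0.0, length), length, overhang


def partition_interface(trace: MembraneTrace):
    """Cut the trace into the four quarter-chord sections.

    The chord is cut at 1/4, 1/2 and 3/4 of its length. Every polyline
    segment is split (by linear interpolation) where its projection crosses
    a quarter boundary, then each sub-segment is assigned to the section
    containing its projected midpoint. Section arc lengths therefore add up
    exactly to the whole-trace arc length.

    Returns
    -------
    sections : list of dict
        Four dicts with keys ``points`` (the sub-polyline, possibly empty),
        ``arc_length``, ``chord`` (= L/4) and ``region``.
    overhang : bool
    """
    pts = trace.points
    t, length, overhang = _chord_parameter(pts, trace.endpoints)
    bounds = np.array([0.25, 0.5, 0.75]) * length

    # split every segment at interior boundary crossings
    split_pts = [pts[0]]
    split_t = [t[0]]
    for i in range(len(pts) - 1):
        t0, t1 = t[i], t[i + 1]
        crossings = []
        for b in bounds:
            lo, hi = min(t0, t1), max(t0, t1)
            if lo < b < hi:
                crossings.append((b - t0) / (t1 - t0))
        for frac in sorted(crossings):
            split_pts.append(pts[i] + frac * (pts[i + 1] - pts[i]))
            split_t.append(t0 + frac * (t1 - t0))
        split_pts.append(pts[i + 1])
        split_t.append(t1)
    split_pts = np.asarray(split_pts)
    split_t = np.asarray(split_t)

    quarter = length / 4.0
    seg_mid = 0.5 * (split_t[:-1] + split_t[1:])
    seg_section = np.clip((seg_mid / quarter).astype(int), 0, 3)
    seg_len = np.linalg.norm(np.diff(split_pts, axis=0), axis=1)

    sections = []
    for s in range(4):
        sel = seg_section == s
        idx = np.flatnonzero(sel)
        if idx.size:
            sec_pts = np.vstack([split_pts[idx[0]], split_pts[idx + 1]])
        else:
            sec_pts = np.empty((0, 2))
        sections.append(
            {
                "points": sec_pts,
                "arc_length": float(seg_len[sel].sum()),
                "chord": quarter,
                "region": _REGION_OF_SECTION[s],
            }
        )
    return sections, overhang


def undulation_ratio(points: np.ndarray, chord: float) -> float:
    """Arc length of a section divided by its chord length."""
    if chord <= 0:
        raise ValueError("chord must be positive")
    return arc_length(points) / chord


def undulation_report(trace: MembraneTrace, whole_interface: bool = False) -> UndulationReport:
    """Undulation ratios per interface region.

    With ``whole_interface=True`` (the convention for control couples without
    a cSMAC) a single ratio over the full chord is reported under region
    ``whole``; otherwise cSMAC (central half of the diameter) and the two
    pSMAC quarters are reported separately.
    """
    if whole_interface:
        _, length, overhang = _chord_parameter(trace.points, trace.endpoints)
        rep = UndulationReport(trace.cell_id, overhang_flagged=overhang)
        al = arc_length(trace.points)
        rep.regions["whole"] = {"length": al, "diameter": length, "ratio": al / length}
        return rep

    sections, overhang = partition_interface(trace)
    rep = UndulationReport(trace.cell_id, overhang_flagged=overhang)
    # cSMAC = central two quarter-sections; its diameter is half the chord
    csmac_len = sections[1]["arc_length"] + sections[2]["arc_length"]
    csmac_chord = sections[1]["chord"] + sections[2]["chord"]
    rep.regions["cSMAC"] = {
        "length": csmac_len,
        "diameter": csmac_chord,
        "ratio": csmac_len / csmac_chord,
    }
    for sec in (sections[0], sections[3]):
        rep.regions[sec["region"]] = {
            "length": sec["arc_length"],
            "diameter": sec["chord"],
            "ratio": sec["arc_length"] / sec["chord"],
        }
    return rep
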