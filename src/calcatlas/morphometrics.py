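"""Landmark-based calcaneal morphometrics and left/right group comparison.

Seven classical measures derived from the six anatomical landmarks (G is
the midpoint of C and D):

* LCA  — length of the calcaneal axis, |G - E| (mm)
* HPF  — height of the posterior facet: perpendicular distance from A to
         the infinite calcaneal-axis line through G and E (mm)
* LPF  — length of the posterior facet, |A - B| (mm)
* LAP  — length of the anterior process, |B - C| (mm)
* HAP  — height of the anterior process, |C - D| (mm)
* GA   — critical angle of Gissane, the angle ABC at vertex B (degrees)
* BA   — tuber angle of Boehler, 180 deg minus the angle CAF at vertex A
         (degrees)

All are invariant under rigid motion; lengths scale linearly and angles are
unchanged under uniform scaling.  Angles are computed in radians internally
and reported in degrees.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pose import LandmarkSet

__all__ = ["MEASURE_NAMES", "measure", "compare_groups"]

MEASURE_NAMES = ("LCA", "HPF", "LPF", "LAP", "HAP", "BA", "GA")


def _angle_deg(vertex: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Angle at ``vertex`` between rays to p and q, degrees; NaN if undefined."""
    u, v = p - vertex, q - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return math.nan
    c = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _point_line_distance(point: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Distance from ``point`` to the infinite line through a and b."""
    d = b - a
    nd = np.linalg.norm(d)
    if nd == 0.0:
        return math.nan
    return float(np.linalg.norm(np.cross(point - a, d)) / nd)


def measure(landmarks: LandmarkSet) -> dict[str, float]:
    """All seven morphometric measures of one bone.

    Degenerate configurations (coincident points) yield NaN for the affected
    measure instead of raising.
    """
    A, B, C, D, E, F = (getattr(landmarks, n) for n in "ABCDEF")
    G = landmarks.G
    return {
        "LCA": float(np.linalg.norm(G - E)),
        "HPF": _point_line_distance(A, G, E),
        "LPF": float(np.linalg.norm(A - B)),
        "LAP": float(np.linalg.norm(B - C)),
        "HAP": float(np.linalg.norm(C - D)),
        "BA": 180.0 - _angle_deg(A, C, F),
        "GA": _angle_deg(B, A, C),
    }


def _welch_p(left: np.ndarray, right: np.ndarray) -> float:
    if left.size == right.size and np.array_equal(np.sort(left), np.sort(right)):
        return 1.0  # identical samples: no evidence of difference by construction
    if left.std(ddof=1) == 0.0 and right.std(ddof=1) == 0.0:
        return 1.0 if left.mean() == right.mean() else 0.0
    return float(stats.ttest_ind(left, right, equal_var=False).pvalue)


def compare_groups(
    left_reports: Sequence[Mapping[str, float]],
    right_reports: Sequence[Mapping[str, float]],
) -> pd.DataFrame:
    """Per-measure group statistics and Welch t-test p-values.

    Rows are the seven measures; columns give mean and SD for the pooled,
    left and right groups plus the left-vs-right Welch two-sample p-value.
    """
    if len(left_reports) < 2 or len(right_reports) < 2:
        raise ValueError("group comparison needs at least 2 bones per side")
    rows = []
    for name in MEASURE_NAMES:
        lv = np.array([r[name] for r in left_reports], dtype=float)
        rv = np.array([r[name] for r in right_reports], dtype=float)
        both = np.concatenate([lv, rv])
        rows.append(
            {
                "measure": name,
                "both_mean": both.mean(),
                "both_sd": both.std(ddof=1),
                "left_mean": lv.mean(),
                "left_sd": lv.std(ddof=1),
                "right_mean": rv.mean(),
                "right_sd": rv.std(ddof=1),
                "p_value": _welch_p(lv, rv),
            }
        )
    return pd.DataFrame(rows).set_index("measure")
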