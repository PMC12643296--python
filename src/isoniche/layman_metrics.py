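"""The six Layman community-wide metrics in (δ¹³C, δ¹⁵N) space.

For a point cloud of consumers the metrics are: the δ¹³C range and δ¹⁵N
range (trophic-diversity extent on each axis), TA — the convex-hull
area (total niche width, ‰²), CD — mean Euclidean distance to the
centroid, MNND — mean nearest-neighbour distance (packing density) and
SDNND — the sample standard deviation of nearest-neighbour distances
(evenness of packing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import cdist


@dataclass
class PointSet2D:
    """Labelled point cloud in isotope space (x = δ¹³C, y = δ¹⁵N, ‰)."""

    points: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if pts.shape[0] < 1:
            raise ValueError("point set must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class LaymanMetrics:
    """The six community metrics; all non-negative, ranges/CD/MNND/SDNND
    in ‰ and TA in ‰²."""

    dC_range: float
    dN_range: float
    TA: float
    CD: float
    MNND: float
    SDNND: float

    def as_dict(self) -> dict[str, float]:
        return {
            "dC_range": self.dC_range,
            "dN_range": self.dN_range,
            "TA": self.TA,
            "CD": self.CD,
            "MNND": self.MNND,
            "SDNND": self.SDNND,
        }


METRIC_NAMES = ("dC_range", "dN_range", "TA", "CD", "MNND", "SDNND")


def convex_hull_area(ps: PointSet2D | np.ndarray) -> float:
    """Area of the planar convex hull (TA), 0 for < 3 points or a
    collinear cloud."""
    pts = ps.points if isinstance(ps, PointSet2D) else np.asarray(ps, dtype=float)
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0  # degenerate (collinear / coincident) cloud


def layman_all(ps: PointSet2D) -> LaymanMetrics:
    """Compute all six Layman metrics for one community.

    A single point yields all-zero metrics with a warning.  Nearest
    neighbour distances may be 0 when coordinates are duplicated; SDNND
    uses the sample standard deviation (n−1 denominator).
    """
    pts = ps.points
    n = len(ps)
    if n == 1:
        warnings.warn("single-point community: all Layman metrics set to 0")
        return LaymanMetrics(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    dC_range = float(pts[:, 0].max() - pts[:, 0].min())
    dN_range = float(pts[:, 1].max() - pts[:, 1].min())
    centroid = pts.mean(axis=0)
    cd = float(np.linalg.norm(pts - centroid, axis=1).mean())

    dist = cdist(pts, pts)
    np.fill_diagonal(dist, np.inf)
    nnd = dist.min(axis=1)
    mnnd = float(nnd.mean())
    sdnnd = float(nnd.std(ddof=1)) if n > 1 else 0.0

    return LaymanMetrics(dC_range, dN_range, convex_hull_area(pts), cd, mnnd, sdnnd)


def layman_table(communities: Sequence[PointSet2D]) -> pd.DataFrame:
    """Long-format (community, metric, value) table for several clouds."""
    rows = []
    for ps in communities:
        m = layman_all(ps).as_dict()
        rows.extend(
            {"community": ps.label, "metric": k, "value": v} for k, v in m.items()
        )
    return pd.DataFrame(rows)
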