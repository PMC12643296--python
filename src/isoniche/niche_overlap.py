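"""Maximum-likelihood niche ellipses and pairwise overlap areas.

An ellipse at coverage p for a bivariate normal fit is
{x : (x−c)ᵀ Σ⁻¹ (x−c) ≤ q(p)} with q(p) = −2 ln(1−p), the χ²(2)
quantile; its area is π √det Σ · q(p).  Overlap between two such
ellipses is computed by adaptive 1-D quadrature of the intersection
cross-section after mapping the first ellipse to the unit disk, which
keeps eccentric ellipses well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from isoniche.layman_metrics import PointSet2D


def coverage_to_quantile(p: float) -> float:
    """q(p) = −2 ln(1−p), the χ² quantile with 2 degrees of freedom."""
    if not 0.0 < p < 1.0:
        raise ValueError("coverage proportion must lie in (0, 1)")
    return -2.0 * np.log1p(-p)


@dataclass(frozen=True)
class EllipseSpec:
    """Niche ellipse: center (‰), SPD covariance (‰²) and coverage p."""

    center: tuple[float, float]
    sigma: tuple[tuple[float, float], tuple[float, float]]
    p: float = 0.95

    def __post_init__(self) -> None:
        s = self.sigma_matrix
        if not np.allclose(s, s.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.det(s) <= 0 or s[0, 0] <= 0:
            raise ValueError("covariance must be positive definite")
        coverage_to_quantile(self.p)

    @property
    def sigma_matrix(self) -> np.ndarray:
        return np.asarray(self.sigma, dtype=float)

    @property
    def center_vec(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def area(self) -> float:
        return float(
            np.pi * np.sqrt(np.linalg.det(self.sigma_matrix)) * coverage_to_quantile(self.p)
        )

    def scaled_shape(self) -> np.ndarray:
        """Σ · q(p): the matrix whose unit ball is this ellipse."""
        return self.sigma_matrix * coverage_to_quantile(self.p)


def ml_ellipse(ps: PointSet2D, p: float = 0.95) -> EllipseSpec:
    """Maximum-likelihood ellipse of a point cloud at coverage p.

    Center = sample mean; shape = ML covariance (denominator n, the
    true maximum-likelihood estimate — distinct from the n−1 sample
    covariance used for SEAc).
    """
    if len(ps) < 3:
        raise ValueError("at least 3 points are required")
    cov = np.cov(ps.points.T, ddof=0)
    if np.linalg.det(cov) <= 0:
        raise ValueError(f"group {ps.label!r}: singular ML covariance")
    c = ps.points.mean(axis=0)
    return EllipseSpec(center=(float(c[0]), float(c[1])),
                       sigma=tuple(map(tuple, cov)), p=p)


def _halfwidth(a: np.ndarray, c: np.ndarray, x: np.ndarray):
    """For the ellipse uᵀ A⁻¹ u ≤ 1 centered at c, the y-interval at
    abscissa x (empty where the ellipse does not reach)."""
    ai = np.linalg.inv(a)
    dx = x - c[0]
    # ai[1,1] y'^2 + 2 ai[0,1] dx y' + ai[0,0] dx^2 - 1 <= 0, y' = y - c[1]
    aa = ai[1, 1]
    bb = 2.0 * ai[0, 1] * dx
    cc = ai[0, 0] * dx * dx - 1.0
    disc = bb * bb - 4.0 * aa * cc
    ok = disc > 0
    root = np.sqrt(np.where(ok, disc, 0.0))
    lo = c[1] + (-bb - root) / (2.0 * aa)
    hi = c[1] + (-bb + root) / (2.0 * aa)
    return np.where(ok, lo, np.nan), np.where(ok, hi, np.nan)


def ellipse_overlap(
    e1: EllipseSpec, e2: EllipseSpec, rtol: float = 1e-4
) -> dict[str, float]:
    """Overlap area of two ellipses and normalized proportions.

    The intersection is convex, so at each abscissa its cross-section is
    the intersection of two intervals; the area is the adaptive
    quadrature of that length over the overlapping x-extent, evaluated
    in the frame where the first ellipse is the unit disk (then scaled
    back by the Jacobian).

    Returns overlap area together with three normalizations: the
    union-normalized (Jaccard) ``proportion`` plus ``frac_1`` and
    ``frac_2`` (overlap over each ellipse's own area), since a single
    printed overlap percentage can be defined either way.
    """
    a1 = e1.scaled_shape()
    a2 = e2.scaled_shape()
    # Map x -> L^{-1}(x - c1): ellipse 1 becomes the unit disk.
    L = np.linalg.cholesky(a1)
    Linv = np.linalg.inv(L)
    c2 = Linv @ (e2.center_vec - e1.center_vec)
    b2 = Linv @ a2 @ Linv.T  # ellipse 2 shape in the disk frame
    jac = float(np.sqrt(np.linalg.det(a1)))  # area scale back to data frame

    disk = np.eye(2)
    c1 = np.zeros(2)
    # x-extent of each region in the disk frame
    ext2 = float(np.sqrt(b2[0, 0]))
    xlo = max(-1.0, c2[0] - ext2)
    xhi = min(1.0, c2[0] + ext2)
    if xlo >= xhi:
        area = 0.0
    else:
        def cross_section(x: float) -> float:
            xv = np.asarray([x])
            lo1, hi1 = _halfwidth(disk, c1, xv)
            lo2, hi2 = _halfwidth(b2, c2, xv)
            if np.isnan(lo1[0]) or np.isnan(lo2[0]):
                return 0.0
            lo = max(lo1[0], lo2[0])
            hi = min(hi1[0], hi2[0])
            return max(hi - lo, 0.0)

        area, abserr = integrate.quad(
            cross_section, xlo, xhi, epsabs=1e-12, epsrel=rtol, limit=200
        )
        if area > 0 and abserr > 10 * rtol * area + 1e-9:
            raise RuntimeError(
                f"overlap quadrature reached abs error {abserr:.2e} "
                f"on area {area:.6g}; requested rtol {rtol}"
            )
        area *= jac

    area1, area2 = e1.area, e2.area
    area = min(area, area1, area2)  # clip quadrature round-off
    union = area1 + area2 - area
    return {
        "area_1": area1,
        "area_2": area2,
        "overlap_area": float(area),
        "proportion": float(area / union),
        "frac_1": float(area / area1),
        "frac_2": float(area / area2),
    }
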