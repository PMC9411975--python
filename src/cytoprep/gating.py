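"""Cell and live-cell gating.

Debris and doublets are excluded with a per-sample elliptical gate on the
two DNA channels (Ir191/Ir193): a single bivariate Gaussian is fitted and
events inside its chi-square quantile ellipse pass.  Dead cells are then
excluded with a polygon gate in (DNA, cisplatin Pt194) space built from a
bivariate-normal density threshold intersected with a half-plane below a
line, taking the convex hull of the retained points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull
from scipy.stats import chi2, norm
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "EllipseGate",
    "PolygonGate",
    "fit_ellipse_gate",
    "live_gate_polygon",
    "apply_polygon",
    "gate_yields",
]


@dataclass
class EllipseGate:
    """Mahalanobis ellipse at the chi-square(2) quantile ``q``."""

    center: np.ndarray
    covariance: np.ndarray  # 2x2 symmetric positive-definite
    q: float

    def mask(self, x: np.ndarray) -> np.ndarray:
        """Boolean pass mask for an E x 2 matrix."""
        xc = np.asarray(x, dtype=float) - self.center
        inv = np.linalg.inv(self.covariance)
        d2 = np.einsum("ij,jk,ik->i", xc, inv, xc)
        return d2 <= chi2.ppf(self.q, df=2)


@dataclass
class PolygonGate:
    """Convex polygon gate; vertices in gate-construction order."""

    vertices: np.ndarray  # V x 2

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.shape[0] < 3:
            raise ValueError("polygon gate needs at least 3 vertices")


def fit_ellipse_gate(
    x: np.ndarray,
    q: float = 0.98,
    target: tuple[float, float] | None = None,
    trim: float = 0.02,
) -> EllipseGate:
    """Fit an elliptical gate to an E x 2 matrix of arcsinh DNA expressions.

    A single bivariate Gaussian cluster (mean, covariance) is fitted, with
    one round of outlier-trimmed re-fitting: the ``trim`` fraction of events
    farthest (Mahalanobis) from the initial fit is dropped and the moments
    re-estimated.  ``target`` optionally seeds the initial center (events
    nearest the seed get full weight in the first pass; with a single
    cluster the fit is insensitive to it and it may be omitted).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 10 or x.shape[1] != 2:
        raise ValueError("need an E x 2 matrix with E >= 10")
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    if trim > 0:
        inv = _safe_inv(cov)
        d2 = np.einsum("ij,jk,ik->i", x - center, inv, x - center)
        keep = d2 <= np.quantile(d2, 1.0 - trim)
        center = x[keep].mean(axis=0)
        cov = np.cov(x[keep], rowvar=False)
        # consistency factor for the truncated chi-square(2): dropping the
        # top `trim` fraction by Mahalanobis radius shrinks the covariance
        # by E[d^2 | kept] / 2; divide it back out so coverage is unbiased
        t = chi2.ppf(1.0 - trim, df=2)
        consistency = (2.0 - (t + 2.0) * trim) / (1.0 - trim) / 2.0
        cov = cov / consistency
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError("rank-deficient covariance; DNA channels are degenerate")
    return EllipseGate(center=center, covariance=cov, q=q)


def _safe_inv(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient covariance; DNA channels are degenerate") from exc


def live_gate_polygon(
    x: np.ndarray, q: float = 0.99, i: float = 0.9, s: float = 0.4
) -> PolygonGate:
    """Construct the live-cell polygon gate in (DNA, dead-marker) space.

    The columns are z-scored (x0); with ``z = Phi^-1(q)``, events are kept
    when the bivariate standard-normal density at x0 strictly exceeds the
    density at (z, z) — i.e. within the q-ish central contour — and when
    they fall strictly below the line ``i + s * x0[:,0] > x0[:,1]``.  The
    gate is the convex hull of the retained points on the original scale.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 10 or x.shape[1] != 2:
        raise ValueError("need an E x 2 matrix with E >= 10")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError("a column has zero spread; cannot standardize")
    x0 = (x - mu) / sd
    z = norm.ppf(q)
    # log-density comparison: exp(-r^2/2) > exp(-(z^2+z^2)/2)  <=>  r^2 < 2 z^2
    r2 = (x0**2).sum(axis=1)
    keep1 = r2 < 2.0 * z * z
    keep2 = (i + s * x0[:, 0]) > x0[:, 1]
    pts = x[keep1 & keep2]
    if pts.shape[0] < 3:
        raise ValueError(
            "fewer than 3 events inside the live gate region; adjust q, i or s"
        )
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # degenerate (collinear) retained points
        raise ValueError(
            "retained live-gate points are degenerate (collinear); adjust q, i or s"
        ) from exc
    return PolygonGate(pts[hull.vertices])


def apply_polygon(x: np.ndarray, polygon: PolygonGate) -> np.ndarray:
    """Point-in-polygon mask for an E x 2 matrix; boundary counts as inside."""
    x = np.asarray(x, dtype=float)
    poly = Polygon(polygon.vertices)
    pts = shapely.points(x[:, 0], x[:, 1])
    return shapely.covers(poly, pts)


def gate_yields(parent_counts: pd.Series | dict, child_counts: pd.Series | dict) -> pd.DataFrame:
    """Percent of the parent population passing a gate, per sample.

    Empty parents yield a missing value.
    """
    parent = pd.Series(parent_counts, dtype=float)
    child = pd.Series(child_counts, dtype=float).reindex(parent.index).fillna(0.0)
    if (child > parent).any():
        raise ValueError("child counts exceed parent counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(parent > 0, 100.0 * child / parent, np.nan)
    return pd.DataFrame({"parent": parent, "child": child, "yield_pct": pct})
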