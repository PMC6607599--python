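"""Ellipse fitting for the extracted pore boundary.

Two routes are provided: :func:`fit_ellipse`, a numerically stable direct
least-squares conic fit constrained to an ellipse (Halir-Flegl), and
:func:`ellipse_from_moments`, a second-order-moments fallback that always
yields an answer for any non-degenerate region. The pipeline prefers the
conic fit and falls back to moments when it degenerates.

Conventions: points and centres are (row, col); ``theta`` is the
major-axis angle measured from the column (x) axis in the image frame
(row increasing downward), normalised to [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

from .errors import FitFailedError, InvalidArgumentError, TooSmallRegionError

__all__ = ["EllipseParams", "fit_ellipse", "ellipse_from_moments"]

MIN_REGION_PX = 9


@dataclass(frozen=True)
class EllipseParams:
    """Canonical ellipse: centre (row, col), semi-axes a >= b > 0, theta in [0, pi)."""

    center: tuple[float, float]
    a: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        a, b, theta = self.a, self.b, self.theta
        if b <= 0 or a <= 0 or not np.isfinite([a, b, theta]).all():
            raise InvalidArgumentError(f"invalid ellipse axes a={a}, b={b}")
        if a < b:
            a, b = b, a
            theta = theta + np.pi / 2.0
        theta = float(np.mod(theta, np.pi))
        object.__setattr__(self, "a", float(a))
        object.__setattr__(self, "b", float(b))
        object.__setattr__(self, "theta", theta)
        object.__setattr__(
            self, "center", (float(self.center[0]), float(self.center[1]))
        )

    def boundary_points(self, n: int = 100) -> np.ndarray:
        """Sample n points on the ellipse, returned as (row, col)."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        ct, st = np.cos(self.theta), np.sin(self.theta)
        x = self.a * np.cos(t) * ct - self.b * np.sin(t) * st
        y = self.a * np.cos(t) * st + self.b * np.sin(t) * ct
        return np.column_stack([self.center[0] + y, self.center[1] + x])


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Direct least-squares ellipse fit to boundary points (row, col).

    Raises :class:`FitFailedError` for fewer than 5 points, collinear
    configurations, or fits that do not yield a proper ellipse; callers
    fall back to :func:`ellipse_from_moments`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidArgumentError("points must be an (N, 2) array of (row, col)")
    if pts.shape[0] < 5:
        raise FitFailedError(f"need >= 5 points, got {pts.shape[0]}")
    xy = pts[:, ::-1]  # EllipseModel works in (x, y) = (col, row)
    with np.errstate(invalid="ignore", divide="ignore"):  # exact circles: a == c
        model = EllipseModel.from_estimate(xy)
    if not model:
        raise FitFailedError(f"conic fit failed: {model}")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        raise FitFailedError("degenerate conic (not an ellipse)")
    return EllipseParams(center=(yc, xc), a=a, b=b, theta=theta)


def ellipse_from_moments(region: np.ndarray) -> EllipseParams:
    """Moment-equivalent ellipse of a binary region, area-matched.

    The principal axes come from the second-order central moments; the
    result is rescaled so that pi*a*b equals the region's pixel area.
    """
    mask = np.asarray(region, dtype=bool)
    n = int(mask.sum())
    if n < MIN_REGION_PX:
        raise TooSmallRegionError(f"region has {n} px; need >= {MIN_REGION_PX}")
    rr, cc = np.nonzero(mask)
    y = rr.astype(float)
    x = cc.astype(float)
    xbar, ybar = x.mean(), y.mean()
    dx, dy = x - xbar, y - ybar
    mxx = float((dx * dx).mean())
    myy = float((dy * dy).mean())
    mxy = float((dx * dy).mean())
    common = np.hypot(mxx - myy, 2.0 * mxy)
    lam1 = (mxx + myy + common) / 2.0
    lam2 = (mxx + myy - common) / 2.0
    if lam2 <= 1e-12:
        raise FitFailedError("region is (nearly) one-dimensional; no moment ellipse")
    a0 = 2.0 * np.sqrt(lam1)
    b0 = 2.0 * np.sqrt(lam2)
    theta = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)
    s = np.sqrt(n / (np.pi * a0 * b0))
    return EllipseParams(center=(ybar, xbar), a=a0 * s, b=b0 * s, theta=theta)
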