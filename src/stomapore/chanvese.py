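"""Two-phase Chan-Vese level-set segmentation of a single-stoma ROI.

The pore is segmented by evolving a level-set field ``phi`` to minimise the
piecewise-constant Chan-Vese energy

    E(C, c1, c2) = mu * Length(C) + nu * Area(inside(C))
                   + lambda1 * sum_{outside(C)} |I - c1|^p
                   + lambda2 * sum_{inside(C)}  |I - c2|^p

where ``c1`` is the mean intensity outside the contour, ``c2`` the mean
inside, and ``p`` defaults to 2 (the classical squared-difference form).
The contour C is the zero crossing of ``phi``; by convention ``phi > 0``
is the inside (pore) phase, seeded as a circle at the ROI centre — the
method's one assumption is that the pore lies near the centre of the ROI.

Numerics: smoothed Heaviside/Dirac with width ``epsilon``, explicit
gradient-descent update with time step ``dt``, curvature by central finite
differences under replicated-edge (Neumann) boundaries, and ``phi`` clamped
to a fixed band instead of periodic reinitialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateLevelSetError,
    EmptySegmentationError,
    InvalidArgumentError,
)

__all__ = [
    "CVParams",
    "RegionStats",
    "SegmentationResult",
    "validate_image",
    "initialize_phi",
    "region_means",
    "cv_energy",
    "evolve_step",
    "segment",
]

#: phi is clamped to [-PHI_CLIP, PHI_CLIP]; stands in for reinitialisation.
PHI_CLIP = 50.0

MIN_IMAGE_SIDE = 16


@dataclass
class CVParams:
    """Weights and numerical settings of the Chan-Vese evolution.

    Parameters
    ----------
    mu : float or None
        Contour-length penalty. ``None`` (default) resolves per image to
        ``0.1 * (intensity range)**2``, which keeps the smoothing term on
        the same scale as the squared fitting terms.
    nu : float
        Inside-area penalty; 0 by default so segmentation is invariant to
        constant intensity shifts.
    lambda1, lambda2 : float
        Weights of the outside / inside fitting terms.
    max_iters : int
        Iteration budget (default 300).
    dt : float
        Explicit time step.
    epsilon : float
        Width (px) of the smoothed Heaviside and Dirac.
    tol : float
        Stop when the fraction of pixels whose sign changed in one
        iteration falls below this.
    init_radius : float or None
        Seed-circle radius; ``None`` resolves to ``min(h, w) / 8``.
    fit_exponent : float
        Exponent ``p`` of the fitting terms; 2 = classical Chan-Vese.
    """

    mu: float | None = None
    nu: float = 0.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    max_iters: int = 300
    dt: float = 0.5
    epsilon: float = 1.0
    tol: float = 1e-4
    init_radius: float | None = None
    fit_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise InvalidArgumentError("lambda1 and lambda2 must be > 0")
        if self.mu is not None and self.mu < 0:
            raise InvalidArgumentError("mu must be >= 0")
        if self.max_iters < 1:
            raise InvalidArgumentError("max_iters must be >= 1")
        if self.dt < 0:
            raise InvalidArgumentError("dt must be >= 0")
        if self.epsilon <= 0:
            raise InvalidArgumentError("epsilon must be > 0")

    def resolve_mu(self, image: np.ndarray) -> float:
        if self.mu is not None:
            return float(self.mu)
        rng = float(image.max() - image.min())
        return 0.1 * rng * rng


@dataclass(frozen=True)
class RegionStats:
    """Phase means: ``c1`` outside the contour, ``c2`` inside."""

    c1: float
    c2: float


@dataclass
class SegmentationResult:
    """Mask plus per-iteration diagnostics from :func:`segment`.

    ``trace`` rows are ``(iteration, energy, c1, c2, area_px)``; row 0 is
    the initial state, the last row the final one.
    """

    mask: np.ndarray
    phi: np.ndarray
    trace: list[tuple[int, float, float, float, int]] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    @property
    def initial_energy(self) -> float:
        return self.trace[0][1]

    @property
    def final_energy(self) -> float:
        return self.trace[-1][1]


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check a grayscale ROI and return it as float64.

    Images must be 2-D, at least 16x16, finite, and within [0, 255].
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise InvalidArgumentError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < MIN_IMAGE_SIDE or arr.shape[1] < MIN_IMAGE_SIDE:
        raise InvalidArgumentError(
            f"image {arr.shape} smaller than {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("image contains non-finite intensities")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidArgumentError("intensities must lie in [0, 255]")
    return arr


def initialize_phi(
    shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> np.ndarray:
    """Signed distance to a seed circle, positive inside.

    ``center`` defaults to the grid centre and ``radius`` to
    ``min(shape) / 8``. ``phi(p) = radius - |p - center|`` so the zero
    level is the circle itself.
    """
    h, w = int(shape[0]), int(shape[1])
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    r0, c0 = float(center[0]), float(center[1])
    if not (0 <= r0 <= h - 1 and 0 <= c0 <= w - 1):
        raise InvalidArgumentError(f"center {center} outside grid {shape}")
    if radius is None:
        radius = min(h, w) / 8.0
    radius = float(radius)
    if not (2 <= radius < min(h, w) / 2.0):
        raise InvalidArgumentError(
            f"radius {radius} outside [2, min(shape)/2) for grid {shape}"
        )
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    phi = radius - np.hypot(rr - r0, cc - c0)
    return np.clip(phi, -PHI_CLIP, PHI_CLIP)


def _check_grids(image: np.ndarray, phi: np.ndarray) -> None:
    if image.shape != phi.shape:
        raise InvalidArgumentError(
            f"image {image.shape} and phi {phi.shape} grids differ"
        )


def region_means(image: np.ndarray, phi: np.ndarray) -> RegionStats:
    """Mean intensity outside (``c1``, phi <= 0) and inside (``c2``, phi > 0)."""
    _check_grids(image, phi)
    inside = phi > 0
    n_in = int(inside.sum())
    if n_in == 0 or n_in == phi.size:
        raise DegenerateLevelSetError("level set has a single sign; no contour")
    img = np.asarray(image, dtype=float)
    c2 = float(img[inside].mean())
    c1 = float(img[~inside].mean())
    return RegionStats(c1=c1, c2=c2)


def _heaviside(phi: np.ndarray, eps: float) -> np.ndarray:
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(phi / eps))


def _dirac(phi: np.ndarray, eps: float) -> np.ndarray:
    return eps / (np.pi * (eps * eps + phi * phi))


def _central_gradients(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # replicated-edge central differences
    p = np.pad(f, 1, mode="edge")
    fy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    fx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    return fy, fx


def _curvature(phi: np.ndarray) -> np.ndarray:
    """div(grad phi / |grad phi|) by central differences."""
    p = np.pad(phi, 1, mode="edge")
    fy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    fx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    fyy = p[2:, 1:-1] - 2.0 * phi + p[:-2, 1:-1]
    fxx = p[1:-1, 2:] - 2.0 * phi + p[1:-1, :-2]
    fxy = (p[2:, 2:] - p[2:, :-2] - p[:-2, 2:] + p[:-2, :-2]) / 4.0
    grad2 = fx * fx + fy * fy
    denom = np.power(grad2, 1.5) + 1e-8
    return (fxx * fy * fy - 2.0 * fx * fy * fxy + fyy * fx * fx) / denom


def _fit_residual(image: np.ndarray, c: float, p: float) -> np.ndarray:
    d = np.abs(image - c)
    if p == 2.0:
        return d * d
    return np.power(d, p)


def cv_energy(image: np.ndarray, phi: np.ndarray, params: CVParams) -> float:
    """Chan-Vese energy of the current contour.

    Length and area use the smoothed Heaviside of phi:
    ``Length = sum |grad H_eps(phi)|``, ``Area = sum H_eps(phi)``.
    """
    _check_grids(image, phi)
    stats = region_means(image, phi)
    img = np.asarray(image, dtype=float)
    mu = params.resolve_mu(img)
    H = _heaviside(phi, params.epsilon)
    Hy, Hx = _central_gradients(H)
    length = float(np.hypot(Hy, Hx).sum())
    area = float(H.sum())
    inside = phi > 0
    p = params.fit_exponent
    fit_out = float(_fit_residual(img[~inside], stats.c1, p).sum())
    fit_in = float(_fit_residual(img[inside], stats.c2, p).sum())
    return (
        mu * length
        + params.nu * area
        + params.lambda1 * fit_out
        + params.lambda2 * fit_in
    )


def evolve_step(
    image: np.ndarray,
    phi: np.ndarray,
    params: CVParams,
    stats: RegionStats | None = None,
) -> np.ndarray:
    """One explicit gradient-descent update of phi.

    The update is ``phi += dt * delta_eps(phi) * F`` with

        F = mu * curvature - nu + lambda1 |I - c1|^p - lambda2 |I - c2|^p

    so a pixel whose intensity is closer to the inside mean ``c2`` than to
    the outside mean ``c1`` gains phi (moves into the pore phase).
    """
    _check_grids(image, phi)
    if stats is None:
        stats = region_means(image, phi)
    else:
        inside = phi > 0
        if inside.all() or not inside.any():
            raise DegenerateLevelSetError("level set has a single sign; no contour")
    if params.dt == 0:
        return phi.copy()
    img = np.asarray(image, dtype=float)
    mu = params.resolve_mu(img)
    p = params.fit_exponent
    force = _fit_residual(img, stats.c1, p) * params.lambda1
    force -= _fit_residual(img, stats.c2, p) * params.lambda2
    force -= params.nu
    if mu != 0.0:
        force += mu * _curvature(phi)
    new_phi = phi + params.dt * _dirac(phi, params.epsilon) * force
    return np.clip(new_phi, -PHI_CLIP, PHI_CLIP)


def segment(
    image: np.ndarray,
    params: CVParams | None = None,
    center: tuple[float, float] | None = None,
) -> SegmentationResult:
    """Segment the pore phase of a single-stoma ROI.

    Seeds phi as a circle at ``center`` (default: ROI centre), runs
    :func:`evolve_step` until fewer than ``tol`` of the pixels change sign
    in an iteration or ``max_iters`` is reached, and returns the positive
    phase ``{phi > 0}`` with the per-iteration energy trace.

    Raises
    ------
    EmptySegmentationError
        If the image has no intensity structure or phi collapses to a
        single sign.
    """
    img = validate_image(image)
    if params is None:
        params = CVParams()
    if img.max() == img.min():
        raise EmptySegmentationError("constant image: no two-phase structure to fit")
    phi = initialize_phi(img.shape, center=center, radius=params.init_radius)

    trace: list[tuple[int, float, float, float, int]] = []
    n = img.size
    converged = False
    it = 0
    try:
        stats = region_means(img, phi)
        trace.append((0, cv_energy(img, phi, params), stats.c1, stats.c2, int((phi > 0).sum())))
        for it in range(1, params.max_iters + 1):
            old_sign = phi > 0
            phi = evolve_step(img, phi, params, stats=stats)
            new_sign = phi > 0
            n_in = int(new_sign.sum())
            if n_in == 0 or n_in == n:
                raise DegenerateLevelSetError("phi collapsed to a single sign")
            stats = region_means(img, phi)
            trace.append((it, cv_energy(img, phi, params), stats.c1, stats.c2, n_in))
            flipped = int(np.count_nonzero(old_sign != new_sign))
            if flipped / n < params.tol:
                converged = True
                break
    except DegenerateLevelSetError as exc:
        raise EmptySegmentationError(str(exc)) from exc

    return SegmentationResult(
        mask=(phi > 0),
        phi=phi,
        trace=trace,
        iterations=it,
        converged=converged,
    )


def trace_records(trace: Sequence[tuple[int, float, float, float, int]]) -> list[dict]:
    """Energy trace as serialisable records (iteration, energy, c1, c2, area_px)."""
    return [
        {"iteration": i, "energy": e, "c1": c1, "c2": c2, "area_px": a}
        for (i, e, c1, c2, a) in trace
    ]
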