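"""Pore morphology metrics from the fitted ellipse.

With semi-axes a >= b the reported quantities are

    area                A  = pi * a * b
    eccentricity        e  = sqrt(1 - (b/a)^2)
    opening degree      Od = b / a

so that e^2 + Od^2 = 1 identically. Pixel lengths convert to micrometres
through the microscope scale (default 4.8 px/um at 1000x); a pore whose
minor axis 2b falls below ~4 px (~0.83 um at that scale) is flagged as
closed-or-too-small — apertures that narrow cannot be measured reliably
and are physiologically negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ellipse import EllipseParams
from .errors import InvalidArgumentError

__all__ = [
    "STATUS_OK",
    "STATUS_CLOSED",
    "STATUS_FAILED",
    "ScaleSpec",
    "PoreMeasurement",
    "pore_metrics",
    "pixels_to_micrometers",
]

STATUS_OK = "ok"
STATUS_CLOSED = "closed_or_too_small"
STATUS_FAILED = "failed"

DEFAULT_MIN_MINOR_AXIS_PX = 4.0


@dataclass(frozen=True)
class ScaleSpec:
    """Microscope pixel scale in pixels per micrometre."""

    pixels_per_um: float = 4.8

    def __post_init__(self) -> None:
        if not (self.pixels_per_um > 0 and np.isfinite(self.pixels_per_um)):
            raise InvalidArgumentError("pixels_per_um must be positive and finite")


@dataclass(frozen=True)
class PoreMeasurement:
    """Derived pore metrics in pixels and micrometres.

    ``major_axis_*`` / ``minor_axis_*`` are the full axes 2a and 2b; the
    semi-axes ``a_px`` and ``b_px`` are also carried to avoid any
    axis-vs-semi-axis ambiguity downstream.
    """

    a_px: float
    b_px: float
    major_axis_px: float
    minor_axis_px: float
    major_axis_um: float
    minor_axis_um: float
    area_px2: float
    area_um2: float
    eccentricity: float
    opening_degree: float
    status: str


def pixels_to_micrometers(length_px: float, scale: ScaleSpec) -> float:
    """Convert a pixel length to micrometres (length / pixels_per_um)."""
    return float(length_px) / scale.pixels_per_um


def pore_metrics(
    ellipse: EllipseParams,
    scale: ScaleSpec | None = None,
    min_minor_axis_px: float = DEFAULT_MIN_MINOR_AXIS_PX,
) -> PoreMeasurement:
    """Compute A, e and Od for a fitted pore ellipse.

    ``status`` is ``closed_or_too_small`` when the minor axis 2b is below
    ``min_minor_axis_px`` (default 4 px), else ``ok``.
    """
    if scale is None:
        scale = ScaleSpec()
    a, b = ellipse.a, ellipse.b
    if b <= 0:
        raise InvalidArgumentError("semi-minor axis must be positive")
    ratio = b / a
    area = np.pi * a * b
    ecc = float(np.sqrt(max(0.0, 1.0 - ratio * ratio)))
    status = STATUS_CLOSED if 2.0 * b < min_minor_axis_px else STATUS_OK
    ppu = scale.pixels_per_um
    return PoreMeasurement(
        a_px=a,
        b_px=b,
        major_axis_px=2.0 * a,
        minor_axis_px=2.0 * b,
        major_axis_um=2.0 * a / ppu,
        minor_axis_um=2.0 * b / ppu,
        area_px2=float(area),
        area_um2=float(area / (ppu * ppu)),
        eccentricity=ecc,
        opening_degree=float(ratio),
        status=status,
    )
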