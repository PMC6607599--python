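"""Seeded generator of single-stoma ROI images with exact ground truth.

Each rendered ROI is an elliptical pore (known semi-axes, orientation and
centre) surrounded by an elliptical guard-cell ring on a textured
background, plus seeded Gaussian noise. The texture is a sum of three
low-frequency sinusoids with seeded phases — enough spatial non-uniformity
to defeat a naive global threshold without overwhelming a region-based
level set, which is the regime the method is designed for.

Two appearance modes are emulated:

* ``dark`` — dark-field microscopy of living leaves: dark pore, bright
  guard-cell ring, mid-grey background; no specular reflections.
* ``bright`` — transmitted-light imagery with specular glints: low-contrast
  dark pore and darker background, with saturated Gaussian-profile
  reflection spots inside the pore (one seeded near a pore tip, where
  glints from the guard-cell junction typically appear). These reflections
  are what the mean-replacement preprocessing step exists to suppress.

The ground-truth mask uses centre sampling: a pixel is pore iff its centre
lies inside the true ellipse, so analytic-area oracles are well defined.
All randomness flows through the per-spec seed; rendering the same spec
twice is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ellipse import EllipseParams
from .errors import InvalidArgumentError

__all__ = [
    "SyntheticStomaSpec",
    "GroundTruth",
    "render_stoma",
    "generate_dataset",
    "OD_BIN_EDGES",
]

#: Opening-degree strata used for stratified dataset generation, matching
#: the standard error-vs-opening-degree binning (10-20, 20-30, 30-40, >40 %).
OD_BIN_EDGES = (0.1, 0.2, 0.3, 0.4)


@dataclass(frozen=True)
class SyntheticStomaSpec:
    """Full description of one synthetic stoma ROI."""

    shape: tuple[int, int] = (128, 128)
    a_true: float = 35.0
    b_true: float = 17.5
    theta_true: float = 0.0
    center_true: tuple[float, float] | None = None  # None -> grid centre
    pore_intensity: float = 40.0
    guard_intensity: float = 230.0
    background_intensity: float = 180.0
    guard_ring_width: float = 6.0
    noise_sigma: float = 10.0
    texture_amplitude: float = 10.0
    reflection_blobs: int = 0
    reflection_peak: float = 255.0
    reflection_sigma: float = 3.0
    field: str = "dark"
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.center_true is not None:
            return self.center_true
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    def validate(self) -> None:
        h, w = self.shape
        a, b = self.a_true, self.b_true
        if not (a >= b > 0):
            raise InvalidArgumentError(f"need a_true >= b_true > 0, got {a}, {b}")
        if self.field not in ("dark", "bright"):
            raise InvalidArgumentError(f"field must be 'dark' or 'bright': {self.field}")
        if self.field == "dark" and self.pore_intensity >= self.guard_intensity:
            raise InvalidArgumentError("dark field requires pore darker than guard ring")
        if self.reflection_blobs < 0:
            raise InvalidArgumentError("reflection_blobs must be >= 0")
        if self.reflection_blobs and self.reflection_peak < (
            self.background_intensity + 4.0 * self.noise_sigma
        ):
            raise InvalidArgumentError(
                "reflection_peak must be >= background + 4*noise_sigma"
            )
        for v in (self.pore_intensity, self.guard_intensity, self.background_intensity):
            if not (0 <= v <= 255):
                raise InvalidArgumentError("intensities must lie in [0, 255]")
        rc, cc = self.resolved_center()
        # pore bounding half-extents in the image frame
        ct, st = np.cos(self.theta_true), np.sin(self.theta_true)
        ex = np.hypot(a * ct, b * st)
        ey = np.hypot(a * st, b * ct)
        if not (
            rc - ey >= 4 and rc + ey <= h - 5 and cc - ex >= 4 and cc + ex <= w - 5
        ):
            raise InvalidArgumentError("pore must fit inside the grid with >= 4 px margin")


@dataclass(frozen=True)
class GroundTruth:
    """Exact pore mask and parameters for one rendered ROI."""

    mask: np.ndarray
    ellipse: EllipseParams
    opening_degree: float


#: Defaults that differ between the two appearance modes.
BRIGHT_FIELD_DEFAULTS = dict(
    pore_intensity=45.0,
    guard_intensity=105.0,
    background_intensity=75.0,
    reflection_blobs=2,
)


def bright_field_spec(**overrides) -> SyntheticStomaSpec:
    """Convenience constructor with bright-field appearance defaults."""
    kw = dict(BRIGHT_FIELD_DEFAULTS)
    kw.update(overrides)
    kw.setdefault("field", "bright")
    return SyntheticStomaSpec(**kw)


def _ellipse_quadform(
    shape: tuple[int, int],
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
) -> np.ndarray:
    """Normalised ellipse quadratic form sampled at pixel centres (<=1 inside)."""
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float), indexing="ij"
    )
    dy = rr - center[0]
    dx = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (dy * ct - dx * st) / b
    return u * u + v * v


def render_stoma(spec: SyntheticStomaSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one ROI and its exact ground truth.

    Layer order: textured background, guard ring, flat pore, reflection
    blobs (bright field), Gaussian noise, clip to [0, 255].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    center = spec.resolved_center()

    img = np.full((h, w), spec.background_intensity, dtype=float)
    if spec.texture_amplitude > 0:
        rr, cc = np.meshgrid(
            np.arange(h, dtype=float) / h, np.arange(w, dtype=float) / w, indexing="ij"
        )
        for _ in range(3):
            fr, fc = rng.uniform(0.5, 2.0, size=2)
            phase = rng.uniform(0, 2 * np.pi)
            sign_r, sign_c = rng.choice([-1.0, 1.0], size=2)
            img += (spec.texture_amplitude / 3.0) * np.sin(
                2 * np.pi * (sign_r * fr * rr + sign_c * fc * cc) + phase
            )

    q_pore = _ellipse_quadform(spec.shape, center, spec.a_true, spec.b_true, spec.theta_true)
    q_ring = _ellipse_quadform(
        spec.shape,
        center,
        spec.a_true + spec.guard_ring_width,
        spec.b_true + spec.guard_ring_width,
        spec.theta_true,
    )
    pore_mask = q_pore <= 1.0
    ring_mask = (q_ring <= 1.0) & ~pore_mask
    img[ring_mask] = spec.guard_intensity
    img[pore_mask] = spec.pore_intensity

    if spec.field == "bright" and spec.reflection_blobs > 0:
        centers = _reflection_centers(spec, rng)
        rr, cc = np.meshgrid(
            np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij"
        )
        for br, bc in centers:
            d2 = (rr - br) ** 2 + (cc - bc) ** 2
            bump = (spec.reflection_peak - img) * np.exp(
                -d2 / (2.0 * spec.reflection_sigma**2)
            )
            img += np.maximum(bump, 0.0)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=(h, w))
    img = np.clip(img, 0.0, 255.0)

    truth = GroundTruth(
        mask=pore_mask,
        ellipse=EllipseParams(
            center=center, a=spec.a_true, b=spec.b_true, theta=spec.theta_true
        ),
        opening_degree=spec.b_true / spec.a_true,
    )
    return img, truth


def _reflection_centers(
    spec: SyntheticStomaSpec, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Blob centres inside the pore; the first sits near a major-axis tip."""
    rc, cc = spec.resolved_center()
    ct, st = np.cos(spec.theta_true), np.sin(spec.theta_true)
    centers: list[tuple[float, float]] = []
    # near-tip glint: ~85% of the way out along the major axis
    tip_frac = 0.85
    side = rng.choice([-1.0, 1.0])
    centers.append((rc + side * tip_frac * spec.a_true * st, cc + side * tip_frac * spec.a_true * ct))
    # glints sit toward the pore periphery (guard-cell junctions); the
    # centre trough — where the level set is seeded — stays clear
    min_sep = 3.0 * spec.reflection_sigma
    attempts = 0
    while len(centers) < spec.reflection_blobs and attempts < 200:
        attempts += 1
        t = rng.uniform(0, 2 * np.pi)
        r = np.sqrt(rng.uniform(0.4**2, 0.85**2))
        u = r * np.cos(t) * spec.a_true
        v = r * np.sin(t) * spec.b_true
        br = rc + u * st + v * ct
        bc = cc + u * ct - v * st
        if all(np.hypot(br - pr, bc - pc) >= min_sep for pr, pc in centers):
            centers.append((br, bc))
    return centers[: spec.reflection_blobs]


def generate_dataset(
    n: int,
    seed: int,
    a_range: tuple[float, float] = (22.0, 42.0),
    od_range: tuple[float, float] = (0.1, 0.9),
    theta_range: tuple[float, float] = (0.0, np.pi),
    field: str = "dark",
    shape: tuple[int, int] = (128, 128),
    **spec_overrides,
) -> list[tuple[np.ndarray, GroundTruth, SyntheticStomaSpec]]:
    """Draw and render n stoma specs, stratified over opening-degree bins.

    When ``od_range`` spans the standard strata (10-20, 20-30, 30-40,
    >40 %), specs are assigned to the covered strata round-robin so every
    bin is populated evenly; the draw is reproducible per ``seed``.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    lo, hi = od_range
    if not (0 < lo < hi <= 1):
        raise InvalidArgumentError(f"invalid od_range {od_range}")
    if a_range[0] > a_range[1] or a_range[0] <= 0:
        raise InvalidArgumentError(f"invalid a_range {a_range}")

    edges = [lo, *[e for e in (*OD_BIN_EDGES[1:], ) if lo < e < hi], hi]
    strata = list(zip(edges[:-1], edges[1:]))

    rng = np.random.default_rng(seed)
    base = dict(shape=shape, field=field)
    if field == "bright":
        merged = dict(BRIGHT_FIELD_DEFAULTS)
        merged.update(spec_overrides)
        spec_overrides = merged
    base.update(spec_overrides)

    out = []
    for i in range(n):
        s_lo, s_hi = strata[i % len(strata)]
        od = rng.uniform(s_lo, s_hi)
        a = rng.uniform(*a_range)
        theta = rng.uniform(*theta_range)
        # jitter the pore centre slightly off the exact grid centre
        jitter = rng.uniform(-2.0, 2.0, size=2)
        center = ((shape[0] - 1) / 2.0 + jitter[0], (shape[1] - 1) / 2.0 + jitter[1])
        spec = SyntheticStomaSpec(
            a_true=a,
            b_true=od * a,
            theta_true=theta,
            center_true=center,
            seed=int(rng.integers(0, 2**31 - 1)),
            **base,
        )
        try:
            spec.validate()
        except InvalidArgumentError:
            # pore too large for the grid at this orientation: shrink a
            spec = replace(spec, a_true=a * 0.8, b_true=od * a * 0.8)
            spec.validate()
        img, truth = render_stoma(spec)
        out.append((img, truth, spec))
    return out
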