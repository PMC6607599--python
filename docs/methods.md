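# Methods

## Segmentation model

The pore is segmented by minimising the two-phase piecewise-constant
Chan–Vese energy over a level-set field φ defined on the image grid:

    E(C, c1, c2) = μ·Length(C) + ν·Area(inside(C))
                 + λ1·Σ_outside |I − c1|^p + λ2·Σ_inside |I − c2|^p

with `inside(C) = {φ > 0}`, `c1` the mean intensity over `{φ ≤ 0}` and
`c2` over `{φ > 0}`. The fitting exponent is `p = 2` by default (the
classical squared-difference form; `CVParams.fit_exponent` makes it
configurable). The model assumes only that the image is roughly
two-phase around the pore and that the pore is near the ROI centre — the
seed for the positive phase is a circle at the centre with radius
`min(h, w)/8`. Phase identity follows the seed: the "pore" is whatever
the centre-grown positive phase converges to, with no assumption that it
is the darker phase.

Length and area use a smoothed Heaviside
`H_ε(φ) = ½(1 + (2/π)·arctan(φ/ε))`:
`Length = Σ |∇H_ε(φ)|` (central differences), `Area = Σ H_ε(φ)`.

## Numerical scheme

One iteration performs the explicit gradient-descent update

    φ ← clip(φ + dt · δ_ε(φ) · [μ·κ − ν + λ1(I − c1)² − λ2(I − c2)²], ±50)

with `δ_ε(φ) = ε / (π(ε² + φ²))` and curvature
`κ = div(∇φ/|∇φ|)` from central finite differences (denominator
regularised by 1e-8). All spatial derivatives use replicated-edge
(Neumann) boundaries. φ is clamped to [−50, 50] in place of periodic
reinitialisation: the clamp bounds |φ| so δ_ε never vanishes entirely
and distant pixels can still change phase, while preventing unbounded
drift. The update is intentionally simple; with the default weights it
behaves like region competition with curvature smoothing and converges
in well under the 300-iteration budget on ROI-scale images (typically
10–100 iterations).

Stopping: the evolution ends when the fraction of pixels whose sign
changed in one iteration drops below `tol = 1e-4`, or after
`max_iters = 300` iterations, whichever comes first. A level set that
collapses to a single sign, or an input with no intensity variation at
all, raises an empty-segmentation error which the pipeline records as a
failed stoma.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| μ (length weight) | 0.1·(intensity range)² | intensity² | scales the smoothing term with the squared fitting terms, so behaviour is invariant to contrast stretch |
| ν (area weight) | 0 | intensity² | keeps segmentation invariant to constant intensity shifts |
| λ1, λ2 | 1, 1 | — | symmetric fitting weights |
| dt | 0.5 | — | explicit step |
| ε | 1.0 | px | Heaviside/Dirac smoothing width |
| tol | 1e-4 | fraction | sign-flip stopping criterion |
| max_iters | 300 | — | iteration budget |
| init radius | min(h, w)/8 | px | seed circle well inside typical pores |
| solidity threshold | 0.85 | — | independence discriminator; exactly 0.85 counts as independent |
| structuring element | disk r = 2, +1 per round, ≤ 3 rounds | px | disconnection schedule |
| scale | 4.8 | px/μm | 1000× microscope scale |
| min minor axis | 4 | px | below this (≈0.83 μm) a pore is reported closed_or_too_small |
| reflection k | 2 | std devs | specular threshold mean + k·std |

With μ = ν = 0 and a strictly two-valued image the stationary state of
the update assigns each pixel to the nearer of the two phase means, so
segmentation recovers a two-valued blob exactly. This holds in the
contrasty regime (the package's exactness fixtures keep the two grey
values ≥ 40 levels apart, comparable to pore/background contrast); when
the two values are nearly equal (ΔI ≲ 12 of 255) the forcing term is so
small that the finite-step dynamics stall before distant pixels convert,
and exact recovery is not claimed there.

## Shape analysis

Foreground components are 8-connected, background 4-connected. The
component containing the ROI centre wins; otherwise the nearest centroid
(ties: larger area, then smaller label). Solidity is
`area / convex_area` in pixel counts, computed on the hole-filled
region (a pore is conceptually solid; an interior hole would spuriously
depress solidity and trigger disconnection) with the convex hull taken
over half-pixel-extended pixel coordinates, the regionprops convention.
Note the discretization consequence: the ideal continuous solidity of a
plus-shape of five 10×10 blocks is 5/7 ≈ 0.714, while the pixel-count
value is 0.735; both are far below the 0.85 threshold. Disconnection
erodes with a growing disk, reselects the central component, dilates
with the same disk and restricts to the original footprint, recomputing
solidity after the restriction; it never adds foreground outside the
input footprint.

The outer boundary is extracted at mask iso-level 0.5 with sub-pixel
interpolation (marching squares), oriented counter-clockwise as
displayed (row down) and started at the topmost-then-leftmost point, so
ellipse fitting sees a smooth contour rather than a pixel staircase.

## Ellipse fit and metrics

The primary fit is the numerically stable direct least-squares conic fit
constrained to an ellipse (Halir–Flegl); when it degenerates (< 5
points, collinear input) the pipeline falls back to the second-moment
ellipse rescaled to match the region's area. θ is measured from the
column axis, normalised to [0, π), and `a ≥ b` is enforced by swapping
axes with a π/2 rotation. Reported metrics: `A = πab`,
`e = √(1 − (b/a)²)`, `Od = b/a` (so `e² + Od² = 1` identically), full
axes `2a`, `2b` in px and μm. On rasterized ellipses the
boundary-then-fit route recovers both semi-axes within 3% whenever
`b ≳ 4 px`; below that the half-pixel rasterization uncertainty
dominates (an aperture that thin is flagged unmeasurable by the 4-px
rule in any case).

Per-stoma total error in the evaluation harness is
`√(err_major² + err_minor²)` computed per stoma and then averaged within
each opening-degree bin; aggregating the other way (bin means first) is
not equivalent, and the per-stoma order was chosen because it weights
every stoma equally.

## Synthetic data model

`synthgen` renders: a background at a base intensity plus a sum of three
low-frequency seeded sinusoids (defeats naive global thresholding
without overwhelming a region-based model), an elliptical guard-cell
ring of fixed width, a flat elliptical pore, optional Gaussian-profile
specular glints, and i.i.d. Gaussian noise, clipped to [0, 255]. The
ground-truth mask is centre-sampled (a pixel is pore iff its centre lies
inside the true ellipse), which makes analytic area oracles well
defined. Dark-field defaults: pore 40, guard 230, background 180, noise
σ = 10, texture amplitude 10. Bright-field defaults emulate low-contrast
transmitted-light imagery: pore 45, guard 105, background 75, with
saturated glints (peak 255, σ = 3 px) placed toward the pore periphery —
one near a major-axis tip, where glints from the guard-cell junction
appear — leaving the centre trough clear, consistent with the method's
centre-seed assumption. Dataset draws stratify the opening degree over
the bins 10–20, 20–30, 30–40 and >40 % round-robin, with the pore centre
jittered ±2 px off the grid centre.

What the generator does *not* emulate: guard-cell texture and wall
detail, neighbouring stomata, trichomes and veins, depth-of-field blur,
non-elliptical pore outlines, and spatially correlated noise. Passing
the synthetic suites therefore demonstrates correctness of the
algorithmic chain (segmentation energy, shape logic, fitting, metrics)
under controlled conditions, not performance on real micrographs.

## Evaluation problem sizes

The shipped suites use: 50 two-valued blob images (96×96); 30 noise-free
and 30 noisy (σ = 10) single-pore ROIs with a ∈ [15, 50] px and
b/a ∈ [0.2, 1.0]; a stratified 400-stoma dark-field suite (128×128,
a ∈ [22, 42] px, Od ∈ [0.1, 0.9], 100 per bin) for the consistency
regression and the error-vs-opening-degree table; 100 random polyominoes
for the solidity oracle; and 20 bright-field glint fixtures for the
reflection-removal ablation. These sizes give stable statistics while
keeping a full run in the tens of seconds on one CPU.

## Known limitations

- Near-closed pores (minor axis of a few px) are over-segmented: the
  centre seed does not land cleanly inside the pore and the converged
  phase latches onto the guard-cell ring. Such stomata surface either as
  `closed_or_too_small` or as over-sized measurements; the 4-px flag
  catches them only when the thin pore itself is recovered.
- The explicit scheme takes large effective steps near the interface;
  energy is guaranteed non-increasing only in the aggregate sense
  checked by the suites (final ≤ initial), not per iteration.
- `field_mode="auto"` decides on reflection removal from the specular
  fraction within 3× the seed radius of the centre; it is a heuristic —
  images with legitimately bright centred structures can trigger it.
- One pore per ROI: multi-pore ROIs are resolved to the single central
  component; the rest are discarded.
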