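# stomapore

Automatic segmentation and measurement of living stomatal pores in
single-stoma microscope images.

Stomata — the pores formed by pairs of guard cells on the plant epidermis —
regulate gas exchange and transpiration, and quantifying their aperture from
micrographs is a routine but laborious step in plant phenotyping. Most
existing pipelines are threshold- or skeleton-based and need per-species
priors (expected pore area, perimeter, axis ranges). `stomapore` instead
segments the pore with a region-based active contour that needs no prior
information beyond one assumption: the pore lies near the centre of the
cropped region of interest (ROI).

## Method

Given a grayscale ROI `I(x, y)`, a level-set field φ is evolved to minimise
the two-phase Chan–Vese energy

```
E(C, c1, c2) = μ·Length(C) + ν·Area(inside(C))
             + λ1·∫_outside |I − c1|² dxdy + λ2·∫_inside |I − c2|² dxdy
```

where the contour `C` is the zero level of φ, `c1`/`c2` are the mean
intensities outside/inside `C`, and the evolution is seeded with a circle at
the ROI centre. Being region-based, the model is robust to blurred or broken
edges and needs no gradient information.

The segmented mask is then analysed for shape: the central connected
component is kept, holes are filled, and its *solidity*
(`Area / ConvexArea`) decides whether the pore came out as an independent
region. Regions with solidity < 0.85 are treated as fused to neighbouring
structures and are disconnected by iterated erosion / central reselection /
dilation. The sub-pixel outer boundary of the final region is fitted with a
direct least-squares ellipse (semi-axes `a ≥ b`), from which the pore
metrics follow:

- area `A = πab`
- eccentricity `e = √(1 − (b/a)²)`
- opening degree `Od = b/a`

Pixel lengths convert to micrometres via the microscope scale (default
4.8 px/μm at 1000×). Pores whose fitted minor axis is below ~4 px
(≈0.83 μm at that scale) are flagged `closed_or_too_small`; apertures that
narrow cannot be measured reliably and are physiologically negligible.
Bright-field imagery with specular glints inside the pore is preprocessed by
replacing pixels above `mean + 2·std` with the global mean intensity.

Because microscope datasets are not shipped with the package, a seeded
synthetic generator (`stomapore.synthgen`) renders single-stoma ROIs —
elliptical pore, guard-cell ring, textured background, noise, optional
specular glints — with exact ground truth, so the whole pipeline is testable
end to end.

## Worked example

```python
from stomapore import PipelineConfig, measure_stoma
from stomapore.synthgen import SyntheticStomaSpec, render_stoma

spec = SyntheticStomaSpec(a_true=35.0, b_true=17.5, theta_true=0.4, seed=11)
img, truth = render_stoma(spec)          # dark-field stoma, known truth
result = measure_stoma(img, PipelineConfig(field_mode="dark"))
m = result.measurement
```

prints, when the fields are formatted:

```
status          : ok
major axis (2a) : 70.14 px = 14.61 um
minor axis (2b) : 34.96 px = 7.28 um
area            : 1926.0 px^2 = 83.59 um^2
eccentricity    : 0.8669
opening degree  : 0.4984
solidity        : 0.9807
iterations      : 12
```

The true pore had semi-axes 35.0 and 17.5 px (opening degree 0.5): both axes
are recovered within a fraction of a percent, the region is independent
(solidity 0.98 ≥ 0.85, no disconnection needed), and the level set converged
in 12 iterations of its 300-iteration budget.

## Command line

```sh
stomapore synth --n 100 --seed 7 --out rois/          # synthetic ROIs + truth
stomapore measure rois/ --field dark --out results.csv
stomapore measure frame.png --boxes boxes.csv --config cfg.yaml
```

`measure` writes one CSV row per ROI (axes in px and μm, area, eccentricity,
opening degree, solidity, iterations, status) and logs per-ROI progress to
stderr. Bounding boxes are 0-based half-open `row0,row1,col0,col1` rows in a
CSV/JSON sidecar; `--save-masks dir` stores the segmentation masks as PNG.

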