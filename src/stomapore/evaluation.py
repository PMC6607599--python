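"""Evaluation harness: synthetic-recovery suites and error summaries.

The headline way to validate the pipeline without microscope data is
synthetic recovery: render stomata with known ellipse parameters, run the
full pipeline, and summarise (i) the regression of measured against true
minor axis (consistency), and (ii) mean axis errors binned by true
opening degree (the error-vs-aperture relationship — narrower pores are
measured less accurately because the same half-pixel boundary uncertainty
is a larger fraction of a smaller axis).

Per-stoma total error is sqrt(err_major^2 + err_minor^2), averaged within
each bin afterwards; the aggregation order (per-stoma, then mean) is a
deliberate choice documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import PipelineConfig, measure_stoma
from .synthgen import GroundTruth, SyntheticStomaSpec

__all__ = [
    "iou",
    "run_suite",
    "minor_axis_regression",
    "axis_errors_by_bin",
    "OD_BINS",
    "two_valued_blob",
    "random_polyomino",
]

#: Opening-degree bins (fractions) for error summaries: >40, 30-40, 20-30,
#: 10-20 percent.
OD_BINS = [(0.4, 1.0), (0.3, 0.4), (0.2, 0.3), (0.1, 0.2)]


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def run_suite(
    data: list[tuple[np.ndarray, GroundTruth, SyntheticStomaSpec]],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run the pipeline over a rendered dataset; one row per stoma.

    Columns: true/measured semi-axes, true opening degree, status,
    iteration count, initial/final energy, relative errors in percent.
    """
    if config is None:
        config = PipelineConfig(field_mode="dark")
    rows = []
    for img, truth, spec in data:
        r = measure_stoma(img, config)
        a_m = r.ellipse.a if r.ellipse is not None else np.nan
        b_m = r.ellipse.b if r.ellipse is not None else np.nan
        rows.append(
            {
                "a_true": truth.ellipse.a,
                "b_true": truth.ellipse.b,
                "od_true": truth.opening_degree,
                "a_meas": a_m,
                "b_meas": b_m,
                "status": r.status,
                "iterations": r.diagnostics.get("iterations", np.nan),
                "initial_energy": r.diagnostics.get("initial_energy", np.nan),
                "final_energy": r.diagnostics.get("final_energy", np.nan),
            }
        )
    df = pd.DataFrame(rows)
    df["err_major_pct"] = 100.0 * np.abs(df.a_meas - df.a_true) / df.a_true
    df["err_minor_pct"] = 100.0 * np.abs(df.b_meas - df.b_true) / df.b_true
    df["err_total_pct"] = np.hypot(df.err_major_pct, df.err_minor_pct)
    return df


def minor_axis_regression(df: pd.DataFrame) -> tuple[float, float]:
    """Slope and R^2 of measured vs true minor axis (2b), measured rows only."""
    ok = df[df.b_meas.notna()]
    res = stats.linregress(2.0 * ok.b_true, 2.0 * ok.b_meas)
    return float(res.slope), float(res.rvalue**2)


def axis_errors_by_bin(df: pd.DataFrame) -> pd.DataFrame:
    """Mean axis errors (%) per opening-degree bin, widest-open first."""
    out = []
    ok = df[df.a_meas.notna()]
    for lo, hi in OD_BINS:
        sel = ok[(ok.od_true > lo) & (ok.od_true <= hi)]
        out.append(
            {
                "od_lo": lo,
                "od_hi": hi,
                "n": len(sel),
                "mean_err_major_pct": float(sel.err_major_pct.mean()),
                "mean_err_minor_pct": float(sel.err_minor_pct.mean()),
                "mean_err_total_pct": float(sel.err_total_pct.mean()),
            }
        )
    return pd.DataFrame(out)


def two_valued_blob(
    rng: np.random.Generator,
    shape: tuple[int, int] = (96, 96),
    min_contrast: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded two-valued image: one simply connected blob over the centre.

    The blob is a union of random disks chained from the grid centre, so
    it always covers the level-set seed. The two grey values are at least
    ``min_contrast`` levels apart — comparable to real pore/background
    contrast; with near-equal values the finite-step evolution stalls,
    which is outside the regime this fixture probes.
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    blob = np.zeros(shape, bool)
    py, px = (h - 1) / 2.0, (w - 1) / 2.0
    for _ in range(int(rng.integers(2, 6))):
        r = rng.uniform(8, min(h, w) / 5.0)
        blob |= np.hypot(rr - py, cc - px) <= r
        ang = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(0, 0.8 * r)
        py = float(np.clip(py + step * np.sin(ang), h * 0.2, h * 0.8))
        px = float(np.clip(px + step * np.cos(ang), w * 0.2, w * 0.8))
    while True:
        v1, v2 = rng.choice(np.arange(20, 236), size=2, replace=False)
        if abs(int(v1) - int(v2)) >= min_contrast:
            break
    img = np.where(blob, float(v2), float(v1))
    return img, blob


def random_polyomino(
    rng: np.random.Generator,
    n_px: int,
    shape: tuple[int, int] = (64, 64),
) -> np.ndarray:
    """Random 4-connected polyomino grown from the grid centre."""
    m = np.zeros(shape, bool)
    r, c = shape[0] // 2, shape[1] // 2
    m[r, c] = True
    cells = [(r, c)]
    while m.sum() < n_px:
        r, c = cells[int(rng.integers(len(cells)))]
        dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[int(rng.integers(4))]
        nr, nc = r + dr, c + dc
        if 1 <= nr < shape[0] - 1 and 1 <= nc < shape[1] - 1 and not m[nr, nc]:
            m[nr, nc] = True
            cells.append((nr, nc))
    return m
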