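"""Curve inspection, overlay rendering, and robustness sweep harnesses.

The original workflow includes a visual-inspection step in which curves that
do not represent ventral stress fibers are disregarded by the user; here that
step is scriptable: :func:`filter_curves` applies a drop list while keeping
every curve in the output as an audit trail, and :func:`render_overlay` draws
the accepted curves over a background of choice.

The sweep harnesses re-run the full pipeline on a synthetic scene under
controlled corruptions (Poisson noise, downsampling, requantization) or under
variants of the SF-preprocessing parameters, tabulating fiber counts and
shape descriptors per condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .imaging import ImagePlane, add_poisson_noise, downsample, requantize
from .stressfibers import FittedCurve, SFPreprocessConfig

__all__ = [
    "SweepResult",
    "filter_curves",
    "render_overlay",
    "run_corruption_sweep",
    "run_preprocess_sweep",
]


@dataclass(frozen=True)
class SweepResult:
    """Summary of one sweep condition."""

    condition: str
    n_sfs: int
    sfs_per_fa_mean: float
    sfs_per_fa_sd: float
    rel_length_mean: float
    max_curv_mean: float


def filter_curves(
    curves: list[FittedCurve], drop_ids: list[tuple[int, int]]
) -> list[FittedCurve]:
    """Un-accept curves whose (fa_i, fa_j) pair appears in ``drop_ids``.

    Pairs are unordered; geometry and scores are untouched and every curve is
    retained in the output.  Unknown pair ids raise a warning, not an error.
    """
    known = {frozenset((c.params.fa_i, c.params.fa_j)) for c in curves}
    drop = set()
    for pair in drop_ids:
        key = frozenset(pair)
        if key not in known:
            warnings.warn(f"drop list names unknown FA pair {tuple(pair)}", stacklevel=2)
        drop.add(key)
    return [
        replace(c, accepted=False)
        if frozenset((c.params.fa_i, c.params.fa_j)) in drop
        else c
        for c in curves
    ]


def render_overlay(
    curves: list[FittedCurve],
    background: str,
    raw: ImagePlane | None = None,
    pre: ImagePlane | None = None,
    path: str | Path | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Draw accepted curves (2-px yellow polylines) over a chosen background.

    ``background`` is ``"white"``, ``"black"``, ``"raw"`` or
    ``"preprocessed"``; the latter two require the corresponding plane.  For
    white/black the canvas dimensions come from ``shape`` or any supplied
    plane.  Returns the RGB array and writes a PNG when ``path`` is given.
    """
    if background == "raw":
        if raw is None:
            raise ValueError("background 'raw' requires the raw plane")
        base = raw.data
    elif background == "preprocessed":
        if pre is None:
            raise ValueError("background 'preprocessed' requires the preprocessed plane")
        base = pre.data
    elif background in ("white", "black"):
        if raw is not None:
            dims = raw.data.shape
        elif pre is not None:
            dims = pre.data.shape
        elif shape is not None:
            dims = shape
        else:
            raise ValueError("white/black background needs a plane or an explicit shape")
        base = np.ones(dims) if background == "white" else np.zeros(dims)
    else:
        raise ValueError(f"unknown background {background!r}")

    canvas = np.repeat((np.clip(base, 0, 1) * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    stroke_mask = np.zeros(base.shape, dtype=bool)
    h, w = base.shape
    for c in curves:
        if not c.accepted:
            continue
        pts = np.round(c.polyline).astype(int)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = draw_line(y0, x0, y1, x1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            stroke_mask[rr[keep], cc[keep]] = True
    if stroke_mask.any():
        stroke_mask = dilation(stroke_mask, disk(1))
        canvas[stroke_mask] = (255, 220, 0)
    if path is not None:
        iio.imwrite(Path(path), canvas)
    return canvas


def _summarize(condition: str, result) -> SweepResult:
    accepted = [c for c in result.curves if c.accepted]
    return SweepResult(
        condition=condition,
        n_sfs=len(accepted),
        sfs_per_fa_mean=result.sfs_per_fa_mean,
        sfs_per_fa_sd=result.sfs_per_fa_sd,
        rel_length_mean=float(np.mean([c.rel_length for c in accepted])) if accepted else 0.0,
        max_curv_mean=float(np.mean([c.max_curvature for c in accepted])) if accepted else 0.0,
    )


def downsample_config(cfg, factor: int):
    """Rescale every pixel-unit parameter for a ``factor``-times-lower resolution.

    Lengths (filter radii, smoothing sigmas) scale by ``1/factor`` and areas
    by ``1/factor**2`` so the analysis stays identical in physical units;
    only the sampling density changes, which is the acquisition setting the
    corruption emulates.
    """
    f = float(factor)
    return replace(
        cfg,
        mask=replace(
            cfg.mask,
            dilation_radius=cfg.mask.dilation_radius / f,
            gaussian_sigma=cfg.mask.gaussian_sigma / f,
            min_area=cfg.mask.min_area / f**2,
        ),
        fa=replace(
            cfg.fa,
            median_radius=cfg.fa.median_radius / f,
            tophat_radius=cfg.fa.tophat_radius / f,
            min_area=cfg.fa.min_area / f**2,
            max_area=cfg.fa.max_area / f**2,
        ),
    )


def run_corruption_sweep(scene, corruptions, cfg=None, seed: int = 0) -> list[SweepResult]:
    """Pipeline results under image corruptions, control condition first.

    ``corruptions`` is a list of ``("poisson", lam)``, ``("downsample", f)``
    or ``("requantize", bits)`` tuples.  Poisson noise and requantization are
    applied to the SF channel only; downsampling is applied to both channels
    (a lower acquisition resolution affects the whole field of view) with
    pixel-unit parameters rescaled via :func:`downsample_config`.
    """
    from .config import PipelineConfig
    from .pipeline import analyze_planes
    from .synth import render_scene

    cfg = cfg or PipelineConfig()
    fa0, sf0 = render_scene(scene, seed=seed)
    results = [_summarize("control", analyze_planes(fa0, sf0, cfg))]
    for kind, value in corruptions:
        fa_img, sf_img, cond_cfg = fa0, sf0, cfg
        if kind == "poisson":
            sf_img = add_poisson_noise(sf0, value, seed=seed)
            label = f"poisson({value:g})"
        elif kind == "downsample":
            f = int(value)
            fa_img, sf_img = downsample(fa0, f), downsample(sf0, f)
            cond_cfg = downsample_config(cfg, f)
            label = f"downsample({f})"
        elif kind == "requantize":
            sf_img = requantize(sf0, int(value))
            label = f"requantize({int(value)}bit)"
        else:
            raise ValueError(f"unknown corruption kind {kind!r}")
        results.append(_summarize(label, analyze_planes(fa_img, sf_img, cond_cfg)))
    return results


def run_preprocess_sweep(
    scene, variants: list[SFPreprocessConfig], cfg=None, seed: int = 0
) -> list[SweepResult]:
    """Pipeline results for each SF-preprocessing variant, all else fixed."""
    from .config import PipelineConfig
    from .pipeline import analyze_planes

    from .synth import render_scene

    if not variants:
        raise ValueError("need at least one preprocessing variant")
    cfg = cfg or PipelineConfig()
    fa0, sf0 = render_scene(scene, seed=seed)
    results = []
    for variant in variants:
        label = (
            f"pct={variant.pct_low:g}/{variant.pct_high:g},"
            f"canny={variant.canny_low:g}/{variant.canny_high:g},"
            f"w={variant.w_contrast:g}:{variant.w_edge:g}"
        )
        vcfg = replace(cfg, sf_preprocess=variant)
        results.append(_summarize(label, analyze_planes(fa0, sf0, vcfg)))
    return results


def write_sweep_report(results: list[SweepResult], path: str | Path) -> None:
    """Write one CSV row per sweep condition."""
    import pandas as pd

    pd.DataFrame([vars(r) for r in results]).to_csv(path, index=False, float_format="%.10g")
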