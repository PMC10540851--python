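"""End-to-end pipeline: mask -> focal adhesions -> stress fibers -> reports."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

from .config import PipelineConfig, save_config
from .focal_adhesions import FocalAdhesion, preprocess_fa, segment_fas, write_fa_report
from .imaging import ImagePlane, read_plane, write_plane
from .mask import CellMask, build_composite, make_masks, select_cell, write_mask_report
from .stressfibers import (
    FitGrid,
    FittedCurve,
    default_grid,
    fit_all_pairs,
    preprocess_sf,
    sfs_per_fa,
    write_curves_report,
    write_sf_summary,
)

__all__ = ["PipelineResult", "analyze_planes", "run_pipeline"]

log = logging.getLogger("sftrace")


@dataclass(frozen=True)
class PipelineResult:
    """Everything a full run produces, in memory."""

    masks: list[CellMask]
    cell: CellMask | None
    fas: list[FocalAdhesion]
    sf_pre: ImagePlane | None
    curves: list[FittedCurve]
    sfs_per_fa_mean: float
    sfs_per_fa_sd: float

    @property
    def n_sfs(self) -> int:
        return sum(1 for c in self.curves if c.accepted)


def _grid_factory(cfg: PipelineConfig):
    fit = cfg.fit

    def build(d: float) -> FitGrid:
        return default_grid(
            d,
            a_halfwidth=fit.grid_a_halfwidth,
            a_n=fit.grid_a_n,
            a_ref_d=fit.grid_a_ref_d,
            theta_max=fit.grid_theta_max,
            theta_n=fit.grid_theta_n,
        )

    return build


def analyze_planes(
    fa_plane: ImagePlane, sf_plane: ImagePlane, cfg: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full analysis on in-memory planes.

    A scene in which no cell can be masked is a valid, empty result rather
    than an error (blank inputs yield empty reports).
    """
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    composite = build_composite(fa_plane, sf_plane)
    masks = make_masks(
        composite,
        dilation_radius=cfg.mask.dilation_radius,
        gaussian_sigma=cfg.mask.gaussian_sigma,
        threshold_method=cfg.mask.threshold_method,
        threshold_value=cfg.mask.threshold_value,
        min_area=cfg.mask.min_area,
        exclude_border=cfg.mask.exclude_border,
    )
    log.info("mask stage: %d candidate cell(s) in %.2fs", len(masks), time.perf_counter() - t0)
    if not masks:
        return PipelineResult(masks, None, [], None, [], 0.0, 0.0)
    kwargs = {}
    if cfg.mask.selector == "by_label":
        kwargs["label"] = cfg.mask.select_label
    elif cfg.mask.selector == "containing_point":
        kwargs["point"] = cfg.mask.select_point
    cell = select_cell(masks, cfg.mask.selector, **kwargs)

    t1 = time.perf_counter()
    fa_pre = preprocess_fa(
        fa_plane, tophat_radius=cfg.fa.tophat_radius, median_radius=cfg.fa.median_radius
    )
    fas = segment_fas(
        fa_pre,
        cell,
        threshold_method=cfg.fa.threshold_method,
        threshold_value=cfg.fa.threshold_value,
        min_area=cfg.fa.min_area,
        max_area=cfg.fa.max_area,
    )
    # FAs whose centroid rounds outside the (possibly concave) mask cannot
    # anchor same-cell curves; drop them rather than fail the invariant.
    h, w = cell.mask.shape
    fas = [
        fa
        for fa in fas
        if 0 <= int(round(fa.centroid[1])) < h
        and 0 <= int(round(fa.centroid[0])) < w
        and cell.mask[int(round(fa.centroid[1])), int(round(fa.centroid[0]))]
    ]
    log.info("FA stage: %d adhesion(s) in %.2fs", len(fas), time.perf_counter() - t1)

    t2 = time.perf_counter()
    sf_pre = preprocess_sf(sf_plane, cfg.sf_preprocess) if len(fas) >= 2 else None
    curves: list[FittedCurve] = []
    if sf_pre is not None:
        curves = _fit_with_grid(sf_pre, fas, cell, cfg)
    _, mean, sd = sfs_per_fa(curves, fas)
    log.info(
        "SF stage: %d/%d curve(s) accepted in %.2fs",
        sum(1 for c in curves if c.accepted),
        len(curves),
        time.perf_counter() - t2,
    )
    return PipelineResult(masks, cell, fas, sf_pre, curves, mean, sd)


def _fit_with_grid(sf_pre, fas, cell, cfg: PipelineConfig):
    return fit_all_pairs(
        sf_pre,
        fas,
        cell,
        accept_threshold=cfg.fit.accept_threshold,
        d_max=cfg.fit.d_max,
        grid=_grid_factory(cfg),
        pen=cfg.penalty,
        n_samples_min=cfg.fit.n_samples_min,
        objective=cfg.fit.objective,
    )


def run_pipeline(
    fa_path: str | Path,
    sf_path: str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path = "sftrace_out",
) -> PipelineResult:
    """Run the full pipeline on image files and write all result files.

    Writes ``mask.csv``, ``fa.csv``, ``curves.csv``, ``sfs_summary.csv``,
    ``mask.tif``, ``overlay.png``, the resolved config, and a run log.
    """
    from .evaluate import render_overlay
    import numpy as np

    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        fa_plane = read_plane(fa_path)
        sf_plane = read_plane(sf_path)
        result = analyze_planes(fa_plane, sf_plane, cfg)

        save_config(cfg, out / "config.yaml")
        if result.cell is not None:
            write_mask_report(result.cell, out / "mask.csv")
            write_plane(
                ImagePlane(result.cell.mask.astype(float)), out / "mask.tif"
            )
        else:
            (out / "mask.csv").write_text(
                "label,area,centroid_x,centroid_y,orientation_deg,"
                "bbox_x_min,bbox_y_min,bbox_x_max,bbox_y_max\n"
            )
        write_fa_report(result.fas, out / "fa.csv")
        write_curves_report(result.curves, out / "curves.csv")
        write_sf_summary(result.curves, result.fas, out / "sfs_summary.csv")
        render_overlay(
            result.curves,
            background="raw",
            raw=sf_plane,
            path=out / "overlay.png",
        )
        log.info(
            "run complete: %d FA(s), %d accepted SF(s)", len(result.fas), result.n_sfs
        )
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
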