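"""Ventral stress-fiber detection by penalized maximum-mean-intensity parabolas.

A ventral stress fiber begins and terminates at a focal adhesion, so every
unordered pair of FA centroids is a candidate anchor pair.  For each pair the
fitter searches a two-parameter family of parabolas constrained through both
anchors and keeps the curve whose mean intensity on the preprocessed actin
image -- divided by a multiplicative shape penalty -- is maximal.

Curve family
------------
Work in the *chord frame*: anchor ``E0`` at the origin, anchor ``E1`` at
``(d, 0)`` where ``d`` is the centroid distance.  A *parabola frame* is
rotated by the skew angle ``theta`` relative to the chord frame; in it the
anchors sit at ``(0, 0)`` and ``(d cos(theta), -d sin(theta))``.  With
``y = a x^2 + b x + c``, ``c = 0`` and

    b = -tan(theta) - a d cos(theta)

the parabola passes through both anchors for every ``(a, theta)``.  Sampling
``x`` uniformly over ``[0, d cos(theta)]`` and rotating back by ``theta``
yields a polyline from ``(0, 0)`` to ``(d, 0)``; a rigid transform then maps
it onto the actual anchor pixels.  ``a = 0`` or ``theta = 0`` with ``a = 0``
reduces to the straight chord, and because only ``d`` (not the absolute
anchor coordinates) enters the construction, the family is independent of
fiber orientation in the image.

Shape penalty
-------------
Curves that overshoot their anchors ("rewinding"), are too long relative to
the chord, or bend too sharply are biologically unreasonable for ventral
fibers, which are under tension and nearly straight.  Each violation
magnitude ``chi`` with threshold ``t`` contributes

    p = 1              for chi < t
    p = exp(A (chi - t))   for chi >= t

with a shared amplitude ``A``; the three penalties multiply and the candidate
score is ``mean intensity / (product of penalties)``.  The rewinding
threshold is fixed at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .focal_adhesions import FocalAdhesion
from .imaging import ImagePlane
from .mask import CellMask

__all__ = [
    "SFPreprocessConfig",
    "CurveParams",
    "PenaltyConfig",
    "FittedCurve",
    "FitGrid",
    "default_grid",
    "preprocess_sf",
    "curve_family",
    "place_curve",
    "relative_length",
    "max_curvature",
    "overshoot",
    "penalty",
    "sample_intensity",
    "fit_best_curve",
    "fit_all_pairs",
    "sfs_per_fa",
    "write_curves_report",
    "write_sf_summary",
]

#: skew angles beyond this make the parabola frame degenerate
THETA_MAX = math.pi / 2 - 0.05
_GEO_EPS = 1e-6  # floor for the geometric-mean logarithm


@dataclass(frozen=True)
class SFPreprocessConfig:
    """Parameters of the actin-channel preprocessing.

    ``pct_low``/``pct_high`` are the contrast-stretch percentiles (intensities
    between them are mapped to the full range, the rest clipped);
    ``canny_low``/``canny_high`` are hysteresis thresholds on the *normalized*
    gradient magnitude; ``w_contrast``/``w_edge`` weight the stretched and
    edge images against the raw image (implicit weight 1) in the preprocessed
    sum.  Defaults are the control values used throughout validation.
    """

    pct_low: float = 10.0
    pct_high: float = 50.0
    canny_low: float = 0.005
    canny_high: float = 0.3
    w_contrast: float = 3.0
    w_edge: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.pct_low < self.pct_high <= 100:
            raise ValueError("need 0 <= pct_low < pct_high <= 100")
        if not 0 <= self.canny_low < self.canny_high <= 1:
            raise ValueError("need 0 <= canny_low < canny_high <= 1")
        if self.w_contrast < 0 or self.w_edge < 0:
            raise ValueError("weights must be >= 0")


@dataclass(frozen=True)
class PenaltyConfig:
    """Thresholds and amplitude of the three exponential shape penalties.

    ``t_rewind`` is fixed at zero (any overshoot is penalized immediately);
    ``t_length`` bounds the relative length L/d; ``t_curv`` bounds the maximum
    unsigned curvature in 1/px; ``amplitude`` is the shared exponential rate.
    ``reject_rewind`` switches the rewinding term from the smooth exponential
    to outright rejection (score 0) of any overshooting curve.
    """

    t_length: float = 1.3
    t_curv: float = 0.05
    amplitude: float = 50.0
    reject_rewind: bool = False
    t_rewind: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.t_length <= 1:
            raise ValueError("t_length must be > 1")
        if self.t_curv <= 0:
            raise ValueError("t_curv must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class CurveParams:
    """The (d, theta, a) parametrization of one anchored parabola."""

    d: float
    theta: float
    a: float
    n_samples: int = 64
    fa_i: int = -1
    fa_j: int = -1

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if abs(self.theta) >= THETA_MAX:
            raise ValueError(f"|theta| must be < {THETA_MAX:.4f} rad")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")

    @property
    def b(self) -> float:
        """Linear coefficient implied by the endpoint constraint."""
        # grouping matches the batched fitter so both paths agree bitwise
        return -math.tan(self.theta) - self.a * (self.d * math.cos(self.theta))

    @property
    def c(self) -> float:
        return 0.0


@dataclass(frozen=True)
class FittedCurve:
    """One candidate/accepted ventral stress fiber between two FAs."""

    params: CurveParams
    polyline: np.ndarray  # (n, 2) image-frame (x, y)
    mean_arith: float
    mean_geom: float
    rel_length: float
    max_curvature: float
    overshoot: float
    penalty: float
    score: float
    accepted: bool = False


@dataclass(frozen=True)
class FitGrid:
    """Explicit (a, theta) search grid."""

    a_values: np.ndarray
    theta_values: np.ndarray


def default_grid(d: float, a_halfwidth: float = 0.02, a_n: int = 41,
                 a_ref_d: float = 100.0, theta_max: float = 0.6,
                 theta_n: int = 21) -> FitGrid:
    """Default search grid, with the curvature range scaled inversely with d.

    ``a`` spans ``[-a_halfwidth, a_halfwidth] * (a_ref_d / d)`` so that the
    sagitta range (which scales like ``a d^2``) stays comparable across
    short and long chords.
    """
    scale = a_ref_d / d
    return FitGrid(
        a_values=np.linspace(-a_halfwidth, a_halfwidth, a_n) * scale,
        theta_values=np.linspace(-theta_max, theta_max, theta_n),
    )


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_sf(sf_img: ImagePlane, cfg: SFPreprocessConfig | None = None) -> ImagePlane:
    """Emphasize fiber structure: raw + contrast-stretched + Canny edges.

    The stretched term maps ``[P(pct_low), P(pct_high)]`` to ``[0, 1]`` with
    clipping; the edge term is the binary Canny output with hysteresis
    thresholds taken as fractions of the maximum gradient magnitude.  The
    weighted sum is renormalized to unit maximum.
    """
    from skimage.feature import canny
    from skimage.filters import sobel

    cfg = cfg or SFPreprocessConfig()
    raw = sf_img.data
    p_low, p_high = np.percentile(raw, [cfg.pct_low, cfg.pct_high])
    if p_low == p_high:
        if raw.max() > raw.min():
            raise ValueError(
                f"degenerate contrast-stretch percentiles: P{cfg.pct_low:g} == "
                f"P{cfg.pct_high:g} == {p_low:g}"
            )
        stretched = np.zeros_like(raw)  # constant image: nothing to stretch
    else:
        stretched = np.clip((raw - p_low) / (p_high - p_low), 0.0, 1.0)
    grad_max = float(sobel(ndi.gaussian_filter(raw, 1.0)).max())
    if grad_max > 0:
        edges = canny(
            raw,
            sigma=1.0,
            low_threshold=cfg.canny_low * grad_max,
            high_threshold=cfg.canny_high * grad_max,
        ).astype(np.float64)
    else:
        edges = np.zeros_like(raw)
    total = raw + cfg.w_contrast * stretched + cfg.w_edge * edges
    peak = total.max()
    if peak > 0:
        total = total / peak
    return ImagePlane(total, sf_img.source_bit_depth)


# ---------------------------------------------------------------------------
# curve geometry

def curve_family(d: float, theta: float, a: float, n_samples: int) -> np.ndarray:
    """Chord-frame polyline of the anchored parabola (see module docstring).

    Returns an ``(n_samples, 2)`` array starting at ``(0, 0)`` and ending at
    ``(d, 0)`` (to within 1e-6 px) for every valid ``(a, theta)``.
    """
    params = CurveParams(d=d, theta=theta, a=a, n_samples=n_samples)
    ct, st = math.cos(theta), math.sin(theta)
    x1 = d * ct
    s = np.linspace(0.0, 1.0, n_samples)
    x = s * x1
    b = params.b
    xx = x * x
    y = a * xx + b * x
    # rotate parabola frame back into the chord frame
    out = np.empty((n_samples, 2))
    out[:, 0] = ct * x - st * y
    out[:, 1] = st * x + ct * y
    return out


def place_curve(polyline: np.ndarray, p_i, p_j) -> np.ndarray:
    """Rigidly map a chord-frame polyline onto anchors ``p_i`` -> ``p_j``.

    ``(0, 0)`` maps to ``p_i`` and ``(d, 0)`` to ``p_j``; the chord length
    implied by the polyline must equal ``|p_j - p_i|`` to within 1e-6.
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    dist = math.hypot(p_j[0] - p_i[0], p_j[1] - p_i[1])
    if dist <= 0:
        raise ValueError("anchor points coincide")
    d_poly = float(polyline[-1, 0])
    if abs(dist - d_poly) > 1e-6 * max(1.0, dist):
        raise ValueError(
            f"anchor distance {dist:g} does not match polyline chord {d_poly:g}"
        )
    e1x, e1y = (p_j[0] - p_i[0]) / dist, (p_j[1] - p_i[1]) / dist
    e2x, e2y = -e1y, e1x
    out = np.empty_like(polyline)
    out[:, 0] = p_i[0] + polyline[:, 0] * e1x + polyline[:, 1] * e2x
    out[:, 1] = p_i[1] + polyline[:, 0] * e1y + polyline[:, 1] * e2y
    return out


def _arc_length(a: float, b: float, x1: float) -> float:
    """Closed-form arc length of y = a x^2 + b x over [0, x1].

    The antiderivative difference scales like 1/(4a); for |2 a x1| tiny
    relative to the slope it cancels catastrophically, so a midpoint-slope
    evaluation (error O((2 a x1)^2)) is used there instead.
    """
    u0 = b
    u1 = 2.0 * a * x1 + b
    if abs(u1 - u0) < 1e-6 * (1.0 + abs(u0) + abs(u1)):
        um = a * x1 + b  # slope at mid-span
        return x1 * math.sqrt(1.0 + um * um)

    def antideriv(u: float) -> float:
        return (u * math.sqrt(1.0 + u * u) + math.asinh(u)) / (4.0 * a)

    return antideriv(u1) - antideriv(u0)


def relative_length(params: CurveParams) -> float:
    """Arc length divided by chord length, L/d >= 1 (closed form)."""
    x1 = params.d * math.cos(params.theta)
    return _arc_length(params.a, params.b, x1) / params.d


def _kappa(a: float, b: float, x) -> float:
    u = 2.0 * a * x + b
    return abs(2.0 * a) / (1.0 + u * u) ** 1.5


def max_curvature(params: CurveParams) -> float:
    """Maximum unsigned curvature of the parabola over its span.

    Curvature ``|2a| / (1 + (2ax + b)^2)^{3/2}`` peaks at the vertex
    ``x* = -b / (2a)``; if the vertex lies outside ``[0, d cos(theta)]`` the
    maximum is attained at an endpoint.  Zero for a straight chord.
    """
    a, b = params.a, params.b
    if a == 0.0:
        return 0.0
    x1 = params.d * math.cos(params.theta)
    x_vertex = -b / (2.0 * a)
    if 0.0 <= x_vertex <= x1:
        return abs(2.0 * a)
    return max(_kappa(a, b, 0.0), _kappa(a, b, x1))


def overshoot(polyline: np.ndarray, d: float) -> float:
    """Chord-axis overshoot of a chord-frame polyline, in pixels.

    Zero when every sample projects inside ``[0, d]``; otherwise the largest
    excursion beyond either anchor (the "rewinding" magnitude).
    """
    x = polyline[:, 0]
    return float(max(0.0, float((-x).max()), float((x - d).max())))


def penalty(chi: float, t: float, A: float) -> float:
    """Exponential threshold penalty: 1 below ``t``, exp(A (chi - t)) at/above.

    Continuous at ``chi = t`` (value 1); ``A`` must be positive.
    """
    if A <= 0:
        raise ValueError("penalty amplitude A must be > 0")
    if chi < t:
        return 1.0
    return math.exp(min(A * (chi - t), 700.0))


def sample_intensity(image: ImagePlane, polyline: np.ndarray) -> tuple[float, float]:
    """Arithmetic and geometric mean intensity along an image-frame polyline.

    Intensities are read by bilinear interpolation at each sample; samples
    outside the image contribute 0.  The geometric mean floors intensities at
    1e-6 before taking logs.
    """
    if len(polyline) == 0:
        raise ValueError("polyline must be non-empty")
    vals = ndi.map_coordinates(
        image.data,
        np.vstack([polyline[:, 1], polyline[:, 0]]),
        order=1,
        mode="constant",
        cval=0.0,
    )
    mean_arith = float(vals.mean())
    mean_geom = float(np.exp(np.log(np.maximum(vals, _GEO_EPS)).mean()))
    return mean_arith, mean_geom


# ---------------------------------------------------------------------------
# fitting

def _batch_curves(d: float, a_values: np.ndarray, theta_values: np.ndarray,
                  n: int) -> tuple[np.ndarray, np.ndarray]:
    """Chord-frame X, Y for every (a, theta) combination, shape (na, nt, n).

    Arithmetic mirrors :func:`curve_family` operation-for-operation so that
    the batched fit and the scalar path produce bit-identical samples.
    """
    av = a_values[:, None, None]
    ct = np.cos(theta_values)[None, :, None]
    st = np.sin(theta_values)[None, :, None]
    x1 = d * ct
    s = np.linspace(0.0, 1.0, n)[None, None, :]
    x = s * x1
    b = -np.tan(theta_values)[None, :, None] - av * x1
    xx = x * x
    y = av * xx + b * x
    return ct * x - st * y, st * x + ct * y


def _batch_descriptors(d: float, a_values: np.ndarray, theta_values: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form relative length and max curvature per (a, theta)."""
    a = a_values[:, None]
    ct = np.cos(theta_values)[None, :]
    x1 = d * ct
    b = -np.tan(theta_values)[None, :] - a * x1
    # arc length; midpoint-slope form where the antiderivative difference
    # would cancel (see _arc_length)
    with np.errstate(divide="ignore", invalid="ignore"):
        u0, u1 = b, 2.0 * a * x1 + b
        anti1 = (u1 * np.sqrt(1.0 + u1 * u1) + np.arcsinh(u1)) / (4.0 * a)
        anti0 = (u0 * np.sqrt(1.0 + u0 * u0) + np.arcsinh(u0)) / (4.0 * a)
        arc = anti1 - anti0
    um = a * x1 + b
    stable = x1 * np.sqrt(1.0 + um * um)
    tiny = np.abs(u1 - u0) < 1e-6 * (1.0 + np.abs(u0) + np.abs(u1))
    arc = np.where(tiny, stable, arc)
    rel_len = arc / d
    # curvature
    kappa_end = np.maximum(
        np.abs(2 * a) / (1.0 + u0 * u0) ** 1.5,
        np.abs(2 * a) / (1.0 + u1 * u1) ** 1.5,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        x_vertex = -b / (2.0 * a)
    vertex_in = (a != 0.0) & (x_vertex >= 0.0) & (x_vertex <= x1)
    curv = np.where(a == 0.0, 0.0, np.where(vertex_in, np.abs(2 * a), kappa_end))
    return rel_len, curv


def fit_best_curve(
    image: ImagePlane,
    p_i,
    p_j,
    grid: FitGrid | None = None,
    pen: PenaltyConfig | None = None,
    n_samples: int | None = None,
    objective: str = "arith",
    fa_i: int = -1,
    fa_j: int = -1,
) -> FittedCurve:
    """Exhaustive grid search for the best anchored parabola between two points.

    Every ``(a, theta)`` candidate is scored as mean intensity along the
    placed curve divided by the accumulated shape penalty; ties are broken by
    smaller ``|a|``, then smaller ``|theta|``, then smaller ``a``, then
    smaller ``theta`` (fully deterministic).
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    d = math.hypot(p_j[0] - p_i[0], p_j[1] - p_i[1])
    if d <= 0:
        raise ValueError("anchor points coincide")
    pen = pen or PenaltyConfig()
    if grid is None:
        grid = default_grid(d)
    if n_samples is None:
        n_samples = max(64, math.ceil(2 * d))
    if objective not in ("arith", "geom"):
        raise ValueError(f"unknown objective {objective!r}")
    a_values = np.asarray(grid.a_values, dtype=float)
    theta_values = np.asarray(grid.theta_values, dtype=float)
    if a_values.size == 0 or theta_values.size == 0:
        raise ValueError("search grid must be non-empty")
    if np.any(np.abs(theta_values) >= THETA_MAX):
        raise ValueError(f"grid thetas must satisfy |theta| < {THETA_MAX:.4f}")

    X, Y = _batch_curves(d, a_values, theta_values, n_samples)
    chi_over = np.maximum(0.0, np.maximum((-X).max(axis=-1), (X - d).max(axis=-1)))
    rel_len, curv = _batch_descriptors(d, a_values, theta_values)

    e1x, e1y = (p_j[0] - p_i[0]) / d, (p_j[1] - p_i[1]) / d
    e2x, e2y = -e1y, e1x
    img_x = p_i[0] + X * e1x + Y * e2x
    img_y = p_i[1] + X * e1y + Y * e2y
    vals = ndi.map_coordinates(
        image.data,
        np.vstack([img_y.ravel(), img_x.ravel()]),
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(img_x.shape)
    means = vals.mean(axis=-1)
    if objective == "geom":
        means_obj = np.exp(np.log(np.maximum(vals, _GEO_EPS)).mean(axis=-1))
    else:
        means_obj = means

    expo = pen.amplitude * (
        np.maximum(0.0, chi_over - pen.t_rewind)
        + np.maximum(0.0, rel_len - pen.t_length)
        + np.maximum(0.0, curv - pen.t_curv)
    )
    pen_total = np.exp(np.minimum(expo, 700.0))
    score = means_obj / pen_total
    if pen.reject_rewind:
        score = np.where(chi_over > 1e-6, 0.0, score)

    a_grid, th_grid = np.meshgrid(a_values, theta_values, indexing="ij")
    flat = np.lexsort(
        (
            th_grid.ravel(),
            a_grid.ravel(),
            np.abs(th_grid).ravel(),
            np.abs(a_grid).ravel(),
            -score.ravel(),
        )
    )[0]
    ia, it = np.unravel_index(flat, score.shape)

    params = CurveParams(
        d=d, theta=float(theta_values[it]), a=float(a_values[ia]),
        n_samples=n_samples, fa_i=fa_i, fa_j=fa_j,
    )
    poly_img = np.stack([img_x[ia, it], img_y[ia, it]], axis=1)
    win_vals = vals[ia, it]
    mean_geom = float(np.exp(np.log(np.maximum(win_vals, _GEO_EPS)).mean()))
    return FittedCurve(
        params=params,
        polyline=poly_img,
        mean_arith=float(means[ia, it]),
        mean_geom=mean_geom,
        rel_length=float(rel_len[ia, it]),
        max_curvature=float(curv[ia, it]),
        overshoot=float(chi_over[ia, it]),
        penalty=float(pen_total[ia, it]),
        score=float(score[ia, it]),
    )


def fit_all_pairs(
    image: ImagePlane,
    fas: list[FocalAdhesion],
    cell: CellMask,
    accept_threshold: float = 0.80,
    d_max: float | None = None,
    grid=None,
    pen: PenaltyConfig | None = None,
    n_samples: int | None = None,
    n_samples_min: int = 64,
    objective: str = "arith",
) -> list[FittedCurve]:
    """Fit the best curve for every same-cell FA pair and flag accepted SFs.

    Pairs with chord length above ``d_max`` (if given) are skipped.  ``grid``
    may be a fixed :class:`FitGrid`, a callable ``d -> FitGrid``, or ``None``
    for the chord-scaled default.  A curve is accepted when its penalized
    score reaches ``accept_threshold``.  All fitted curves (accepted and
    rejected) are returned, sorted by ``(fa_i, fa_j)``, so acceptance can be
    re-examined without re-fitting.
    """
    h, w = cell.mask.shape
    for fa in fas:
        col = int(round(fa.centroid[0]))
        row = int(round(fa.centroid[1]))
        if not (0 <= row < h and 0 <= col < w and cell.mask[row, col]):
            raise ValueError(f"FA {fa.id} centroid {fa.centroid} outside the cell mask")
    curves: list[FittedCurve] = []
    for i in range(len(fas)):
        for j in range(i + 1, len(fas)):
            p_i, p_j = fas[i].centroid, fas[j].centroid
            d = math.hypot(p_j[0] - p_i[0], p_j[1] - p_i[1])
            if d_max is not None and d > d_max:
                continue
            pair_grid = grid(d) if callable(grid) else grid
            pair_n = n_samples if n_samples is not None else max(n_samples_min, math.ceil(2 * d))
            fc = fit_best_curve(
                image, p_i, p_j, grid=pair_grid, pen=pen, n_samples=pair_n,
                objective=objective, fa_i=fas[i].id, fa_j=fas[j].id,
            )
            curves.append(replace(fc, accepted=fc.score >= accept_threshold))
    curves.sort(key=lambda c: (c.params.fa_i, c.params.fa_j))
    return curves


def sfs_per_fa(
    curves: list[FittedCurve], fas: list[FocalAdhesion]
) -> tuple[np.ndarray, float, float]:
    """Accepted-fiber count per FA plus the (mean, sample SD) over all FAs.

    Zero-count FAs are included in the summary, matching the per-cell
    "fibers per adhesion" statistic reported alongside the fiber count.
    """
    counts = np.zeros(len(fas), dtype=int)
    index = {fa.id: k for k, fa in enumerate(fas)}
    for c in curves:
        if not c.accepted:
            continue
        for fa_id in (c.params.fa_i, c.params.fa_j):
            if fa_id in index:
                counts[index[fa_id]] += 1
    if len(fas) == 0:
        return counts, 0.0, 0.0
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if len(fas) > 1 else 0.0
    return counts, mean, sd


# ---------------------------------------------------------------------------
# reports

def write_curves_report(curves: list[FittedCurve], path: str | Path) -> None:
    """One CSV row per fitted curve (accepted and rejected)."""
    df = pd.DataFrame(
        [
            {
                "fa_i": c.params.fa_i,
                "fa_j": c.params.fa_j,
                "d": c.params.d,
                "a": c.params.a,
                "theta": c.params.theta,
                "mean_arith": c.mean_arith,
                "mean_geom": c.mean_geom,
                "rel_length": c.rel_length,
                "max_curvature": c.max_curvature,
                "overshoot": c.overshoot,
                "penalty": c.penalty,
                "score": c.score,
                "accepted": c.accepted,
            }
            for c in curves
        ],
        columns=[
            "fa_i", "fa_j", "d", "a", "theta", "mean_arith", "mean_geom",
            "rel_length", "max_curvature", "overshoot", "penalty", "score",
            "accepted",
        ],
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_sf_summary(
    curves: list[FittedCurve], fas: list[FocalAdhesion], path: str | Path
) -> dict:
    """Summary CSV: FA count, accepted-SF count, SFs/FA mean and SD."""
    _, mean, sd = sfs_per_fa(curves, fas)
    summary = {
        "n_fas": len(fas),
        "n_sfs": sum(1 for c in curves if c.accepted),
        "sfs_per_fa_mean": mean,
        "sfs_per_fa_sd": sd,
    }
    pd.DataFrame([summary]).to_csv(path, index=False, float_format="%.10g")
    return summary
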