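"""Synthetic ground-truth scenes: FA blobs plus parabolic fiber strokes.

Scenes emulate the two channels the pipeline consumes: a vinculin-like plane
with Gaussian-profile elliptical puncta at known centers, and an actin-like
plane with fiber strokes stamped along the *same* anchored-parabola family the
fitter searches (shared code path, so the analytic descriptors of a truth
stroke are exactly those of a perfectly recovered curve).  Scenes also carry
an elliptical cell body filled with a weak, deterministic cytoplasmic texture
(uneven-illumination-like, not random) over a dark exterior: this is what
makes the composite maskable into a single cell and keeps the percentile
contrast stretch well defined, as in real micrographs.

Distractor strokes with free endpoints model actin fibers that do not start
and end at adhesions; a correct analysis must not report them.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .imaging import ImagePlane
from .stressfibers import CurveParams, FittedCurve, curve_family, place_curve, relative_length

__all__ = [
    "FABlob",
    "Stroke",
    "FreeStroke",
    "CellBody",
    "GroundTruthSpec",
    "default_scene",
    "render_scene",
    "orientation_variants",
    "write_truth",
    "read_truth",
    "score_against_truth",
    "TruthScore",
]

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.355: FWHM per unit sigma


@dataclass(frozen=True)
class FABlob:
    """Gaussian-profile elliptical punctum; major/minor are FWHMs in px."""

    center: tuple[float, float]
    major: float = 18.0
    minor: float = 8.0
    orientation_deg: float = 0.0
    peak: float = 0.8


@dataclass(frozen=True)
class Stroke:
    """Anchored fiber stroke between two blob centers; width is FWHM in px."""

    fa_i: int
    fa_j: int
    a: float = 0.0
    theta: float = 0.0
    width_px: float = 6.0
    peak: float = 0.9


@dataclass(frozen=True)
class FreeStroke:
    """Distractor stroke with free endpoints (not anchored at blobs)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    a: float = 0.0
    theta: float = 0.0
    width_px: float = 6.0
    peak: float = 0.9


@dataclass(frozen=True)
class CellBody:
    """Elliptical cytoplasm region; semi_x/semi_y are semi-axes in px."""

    center: tuple[float, float]
    semi_x: float
    semi_y: float
    orientation_deg: float = 0.0


@dataclass(frozen=True)
class GroundTruthSpec:
    """Complete description of a synthetic two-channel scene."""

    width: int
    height: int
    fa_blobs: tuple[FABlob, ...] = ()
    sf_strokes: tuple[Stroke, ...] = ()
    distractor_strokes: tuple[FreeStroke, ...] = ()
    background: float = 0.12
    cell_body: CellBody | None = None
    texture_amp: float = 0.5  # relative amplitude of the cytoplasmic texture
    # periods far above the FA top-hat scale: smooth, illumination-like
    texture_periods: tuple[float, float] = (241.0, 283.0)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("frame must be at least 1x1")
        if not 0 <= self.background < 1:
            raise ValueError("background must be in [0, 1)")
        n = len(self.fa_blobs)
        for s in self.sf_strokes:
            if not (0 <= s.fa_i < n and 0 <= s.fa_j < n) or s.fa_i == s.fa_j:
                raise ValueError(f"stroke references invalid blob indices ({s.fa_i}, {s.fa_j})")
        for b in self.fa_blobs:
            if not (0 <= b.center[0] < self.width and 0 <= b.center[1] < self.height):
                raise ValueError(f"blob center {b.center} outside the frame")
        for s in self.distractor_strokes:
            for p in (s.p0, s.p1):
                if not (0 <= p[0] < self.width and 0 <= p[1] < self.height):
                    raise ValueError(f"distractor endpoint {p} outside the frame")

    def stroke_params(self, stroke: Stroke, n_samples: int = 64) -> CurveParams:
        """The (d, theta, a) of a truth stroke, via the shared curve family."""
        p_i = self.fa_blobs[stroke.fa_i].center
        p_j = self.fa_blobs[stroke.fa_j].center
        d = math.hypot(p_j[0] - p_i[0], p_j[1] - p_i[1])
        return CurveParams(d=d, theta=stroke.theta, a=stroke.a, n_samples=n_samples)


def default_scene(size: int = 2048) -> GroundTruthSpec:
    """The bundled validation scene (8 blobs, 5 anchored strokes, 2 distractors).

    Geometry is chosen so that strokes sharing a blob meet at a wide angle and
    no low-curvature member of the search family can ride a stroke between a
    *non*-anchored pair; scale everything with ``size`` (default 2048).
    """
    s = size / 2048.0

    def pt(x, y):
        return (x * s, y * s)

    blobs = (
        FABlob(pt(430, 500), 20, 9, 10.0, 0.85),
        FABlob(pt(1010, 545), 18, 8, -5.0, 0.80),
        FABlob(pt(1125, 1165), 22, 9, 80.0, 0.90),
        FABlob(pt(410, 1190), 18, 8, -30.0, 0.75),
        FABlob(pt(815, 905), 20, 8, 45.0, 0.85),
        FABlob(pt(1595, 780), 18, 9, 60.0, 0.80),
        FABlob(pt(1490, 1430), 20, 8, 0.0, 0.85),
        FABlob(pt(835, 1585), 18, 8, 20.0, 0.80),
    )
    strokes = (
        Stroke(0, 1, a=0.0004 / s, theta=0.10, width_px=6 * s, peak=0.90),
        Stroke(1, 2, a=-0.0005 / s, theta=-0.12, width_px=6 * s, peak=0.95),
        Stroke(3, 4, a=0.0007 / s, theta=0.20, width_px=6 * s, peak=0.85),
        Stroke(5, 6, a=0.0000, theta=0.00, width_px=6 * s, peak=0.90),
        Stroke(6, 7, a=-0.0006 / s, theta=0.15, width_px=6 * s, peak=0.90),
    )
    distractors = (
        FreeStroke(pt(1320, 420), pt(1700, 560), a=0.0005 / s, theta=0.1,
                   width_px=6 * s, peak=0.85),
        FreeStroke(pt(300, 830), pt(520, 640), a=0.0, theta=0.0,
                   width_px=6 * s, peak=0.80),
    )
    return GroundTruthSpec(
        width=size,
        height=size,
        fa_blobs=blobs,
        sf_strokes=strokes,
        distractor_strokes=distractors,
        background=0.12,
        cell_body=CellBody(pt(1024, 1024), 940 * s, 800 * s, 15.0),
        texture_periods=(241.0 * s, 283.0 * s),
    )


# ---------------------------------------------------------------------------
# rendering

def _background_field(spec: GroundTruthSpec) -> np.ndarray:
    """Cytoplasmic background: textured inside the cell body, dark outside."""
    h, w = spec.height, spec.width
    if spec.cell_body is None:
        return np.full((h, w), spec.background)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cb = spec.cell_body
    phi = math.radians(cb.orientation_deg)
    dx, dy = xx - cb.center[0], yy - cb.center[1]
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    inside = (u / cb.semi_x) ** 2 + (v / cb.semi_y) ** 2 <= 1.0
    px, py = spec.texture_periods
    texture = 1.0 + spec.texture_amp * np.sin(2 * np.pi * xx / px) * np.sin(2 * np.pi * yy / py)
    return np.where(inside, spec.background * texture, 0.0)


def _stamp_gaussian_blob(canvas: np.ndarray, blob: FABlob) -> None:
    sx = blob.major / _FWHM
    sy = blob.minor / _FWHM
    pad = 4.0 * max(sx, sy)
    h, w = canvas.shape
    x0 = max(int(blob.center[0] - pad), 0)
    x1 = min(int(blob.center[0] + pad) + 2, w)
    y0 = max(int(blob.center[1] - pad), 0)
    y1 = min(int(blob.center[1] + pad) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
    phi = math.radians(blob.orientation_deg)
    dx, dy = xx - blob.center[0], yy - blob.center[1]
    u = dx * math.cos(phi) + dy * math.sin(phi)
    v = -dx * math.sin(phi) + dy * math.cos(phi)
    canvas[y0:y1, x0:x1] += blob.peak * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def _stamp_stroke(canvas: np.ndarray, polyline: np.ndarray, width_px: float,
                  peak: float) -> None:
    """Stamp a Gaussian cross-profile ridge along a dense polyline.

    The polyline is rasterized onto a sub-canvas and a Euclidean distance
    transform supplies the distance to the ridge; the half-pixel rasterization
    error is well below the profile width used in practice.
    """
    sigma = max(width_px / _FWHM, 0.5)
    pad = int(math.ceil(4.0 * sigma)) + 2
    h, w = canvas.shape
    x0 = max(int(np.floor(polyline[:, 0].min())) - pad, 0)
    x1 = min(int(np.ceil(polyline[:, 0].max())) + pad + 1, w)
    y0 = max(int(np.floor(polyline[:, 1].min())) - pad, 0)
    y1 = min(int(np.ceil(polyline[:, 1].max())) + pad + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    sub = np.ones((y1 - y0, x1 - x0), dtype=bool)
    cols = np.clip(np.round(polyline[:, 0]).astype(int) - x0, 0, x1 - x0 - 1)
    rows = np.clip(np.round(polyline[:, 1]).astype(int) - y0, 0, y1 - y0 - 1)
    sub[rows, cols] = False
    dist = ndi.distance_transform_edt(sub)
    canvas[y0:y1, x0:x1] += peak * np.exp(-0.5 * (dist / sigma) ** 2)


def _stroke_polyline(p0, p1, a: float, theta: float) -> np.ndarray:
    d = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    n = max(int(math.ceil(4.0 * d)), 2)
    chord = curve_family(d, theta, a, n)
    return place_curve(chord, p0, p1)


def render_scene(spec: GroundTruthSpec, seed: int = 0) -> tuple[ImagePlane, ImagePlane]:
    """Render the FA and SF planes of a scene; deterministic for a fixed seed.

    (The default scene has no stochastic elements; ``seed`` is accepted for
    interface stability with noisy extensions.)
    """
    del seed  # no stochastic elements in the base renderer
    bg = _background_field(spec)
    fa_plane = bg.copy()
    sf_plane = bg.copy()
    for blob in spec.fa_blobs:
        _stamp_gaussian_blob(fa_plane, blob)
    for stroke in spec.sf_strokes:
        p0 = spec.fa_blobs[stroke.fa_i].center
        p1 = spec.fa_blobs[stroke.fa_j].center
        poly = _stroke_polyline(p0, p1, stroke.a, stroke.theta)
        _stamp_stroke(sf_plane, poly, stroke.width_px, stroke.peak)
    for stroke in spec.distractor_strokes:
        poly = _stroke_polyline(stroke.p0, stroke.p1, stroke.a, stroke.theta)
        _stamp_stroke(sf_plane, poly, stroke.width_px, stroke.peak)
    return (
        ImagePlane(np.clip(fa_plane, 0.0, 1.0)),
        ImagePlane(np.clip(sf_plane, 0.0, 1.0)),
    )


# ---------------------------------------------------------------------------
# orientation variants

def _rotate_point(p, center, angle_rad: float) -> tuple[float, float]:
    ct, st = math.cos(angle_rad), math.sin(angle_rad)
    dx, dy = p[0] - center[0], p[1] - center[1]
    return (center[0] + ct * dx - st * dy, center[1] + st * dx + ct * dy)


def _fold_deg(deg: float) -> float:
    while deg > 90.0:
        deg -= 180.0
    while deg <= -90.0:
        deg += 180.0
    return deg


def orientation_variants(spec: GroundTruthSpec, k: int) -> list[GroundTruthSpec]:
    """``k`` rigid rotations of the scene by multiples of 360°/k.

    Per-stroke shape descriptors (d, a, theta) are unchanged -- only the
    placement rotates -- which is exactly the configuration used to check
    that detection is orientation independent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    center = (spec.width / 2.0, spec.height / 2.0)
    variants = []
    for i in range(k):
        angle = math.radians(360.0 * i / k)
        if i == 0:
            variants.append(spec)
            continue
        blobs = tuple(
            replace(
                b,
                center=_rotate_point(b.center, center, angle),
                orientation_deg=_fold_deg(b.orientation_deg + math.degrees(angle)),
            )
            for b in spec.fa_blobs
        )
        distractors = tuple(
            replace(
                s,
                p0=_rotate_point(s.p0, center, angle),
                p1=_rotate_point(s.p1, center, angle),
            )
            for s in spec.distractor_strokes
        )
        cell = spec.cell_body
        if cell is not None:
            cell = replace(
                cell,
                center=_rotate_point(cell.center, center, angle),
                orientation_deg=_fold_deg(cell.orientation_deg + math.degrees(angle)),
            )
        try:
            variants.append(
                replace(spec, fa_blobs=blobs, distractor_strokes=distractors, cell_body=cell)
            )
        except ValueError as exc:
            raise ValueError(
                f"rotation by {math.degrees(angle):g} deg moves geometry outside the frame"
            ) from exc
    return variants


# ---------------------------------------------------------------------------
# serialization

def write_truth(spec: GroundTruthSpec, path: str | Path) -> None:
    """Serialize a scene description to JSON (lossless round-trip)."""
    payload = asdict(spec)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> GroundTruthSpec:
    """Read a scene description back from JSON."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed scene file {path}: line {exc.lineno}: {exc.msg}") from exc
    try:
        cell = payload.get("cell_body")
        return GroundTruthSpec(
            width=payload["width"],
            height=payload["height"],
            fa_blobs=tuple(
                FABlob(**{**b, "center": tuple(b["center"])}) for b in payload["fa_blobs"]
            ),
            sf_strokes=tuple(Stroke(**s) for s in payload["sf_strokes"]),
            distractor_strokes=tuple(
                FreeStroke(**{**s, "p0": tuple(s["p0"]), "p1": tuple(s["p1"])})
                for s in payload["distractor_strokes"]
            ),
            background=payload["background"],
            cell_body=CellBody(**{**cell, "center": tuple(cell["center"])}) if cell else None,
            texture_amp=payload["texture_amp"],
            texture_periods=tuple(payload["texture_periods"]),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed scene file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# scoring

@dataclass(frozen=True)
class TruthScore:
    """Outcome of matching accepted curves against the scene's truth strokes."""

    true_positives: int
    false_positives: int
    false_negatives: int
    a_errors: tuple[float, ...]
    rel_length_errors: tuple[float, ...]


def score_against_truth(
    curves: list[FittedCurve], spec: GroundTruthSpec, tol_match: float = 5.0
) -> TruthScore:
    """Match accepted curves to truth strokes by endpoint proximity.

    A curve matches a stroke when both endpoints are within ``tol_match`` px
    of the stroke's blob centers (in either order); pairing minimizes the
    total endpoint distance and each stroke is matched at most once.  Per
    match the parameter errors ``|a_fit - a_true|`` and
    ``|L/d_fit - L/d_true|`` are reported, with the truth's sign convention
    flipped when the curve traverses the stroke in the opposite direction.
    """
    from scipy.optimize import linear_sum_assignment

    accepted = [c for c in curves if c.accepted]
    strokes = list(spec.sf_strokes)
    if not accepted or not strokes:
        return TruthScore(0, len(accepted), len(strokes), (), ())

    big = 1e12
    cost = np.full((len(accepted), len(strokes)), big)
    swapped = np.zeros_like(cost, dtype=bool)
    for ci, c in enumerate(accepted):
        q0, q1 = c.polyline[0], c.polyline[-1]
        for si, s in enumerate(strokes):
            t0 = np.asarray(spec.fa_blobs[s.fa_i].center)
            t1 = np.asarray(spec.fa_blobs[s.fa_j].center)
            fwd = np.linalg.norm(q0 - t0) + np.linalg.norm(q1 - t1)
            rev = np.linalg.norm(q0 - t1) + np.linalg.norm(q1 - t0)
            fwd_ok = np.linalg.norm(q0 - t0) <= tol_match and np.linalg.norm(q1 - t1) <= tol_match
            rev_ok = np.linalg.norm(q0 - t1) <= tol_match and np.linalg.norm(q1 - t0) <= tol_match
            if fwd_ok and (fwd <= rev or not rev_ok):
                cost[ci, si] = fwd
            elif rev_ok:
                cost[ci, si] = rev
                swapped[ci, si] = True
    rows, cols = linear_sum_assignment(cost)
    a_errs, rl_errs = [], []
    matched_curves: set[int] = set()
    matched_strokes: set[int] = set()
    for ci, si in zip(rows, cols):
        if cost[ci, si] >= big:
            continue
        matched_curves.add(ci)
        matched_strokes.add(si)
        c = accepted[ci]
        s = strokes[si]
        a_true = -s.a if swapped[ci, si] else s.a
        a_errs.append(abs(c.params.a - a_true))
        rl_errs.append(abs(c.rel_length - relative_length(spec.stroke_params(s))))
    return TruthScore(
        true_positives=len(matched_curves),
        false_positives=len(accepted) - len(matched_curves),
        false_negatives=len(strokes) - len(matched_strokes),
        a_errors=tuple(a_errs),
        rel_length_errors=tuple(rl_errs),
    )
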