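"""Shared fixtures: compact synthetic scenes and cached pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest

import sftrace as sft
from sftrace.synth import CellBody, FABlob, FreeStroke, GroundTruthSpec, Stroke


def small_scene_spec() -> GroundTruthSpec:
    """A 512x512 two-stroke scene with one distractor, fast to analyze."""
    return GroundTruthSpec(
        width=512,
        height=512,
        fa_blobs=(
            FABlob((140, 150), 18, 8, 20.0, 0.85),
            FABlob((370, 130), 18, 8, -10.0, 0.80),
            FABlob((150, 360), 18, 8, 45.0, 0.80),
            FABlob((360, 380), 18, 8, 0.0, 0.85),
        ),
        sf_strokes=(
            Stroke(0, 1, a=0.0010, theta=0.10, width_px=5, peak=0.90),
            Stroke(2, 3, a=-0.0012, theta=-0.15, width_px=5, peak=0.90),
        ),
        distractor_strokes=(
            FreeStroke((430, 200), (440, 330), a=0.0, theta=0.0, width_px=5, peak=0.85),
        ),
        background=0.12,
        cell_body=CellBody((256, 256), 235, 200, 15.0),
        texture_periods=(60.25, 70.75),
    )


def single_stroke_spec(a: float = 0.002, theta: float = 0.1) -> GroundTruthSpec:
    """Two blobs joined by one stroke; the parameter-recovery scene."""
    return GroundTruthSpec(
        width=512,
        height=512,
        fa_blobs=(
            FABlob((120, 230), 18, 8, 0.0, 0.85),
            FABlob((390, 260), 18, 8, 0.0, 0.85),
        ),
        sf_strokes=(Stroke(0, 1, a=a, theta=theta, width_px=5, peak=0.9),),
        background=0.12,
        cell_body=CellBody((256, 256), 235, 200, 0.0),
        texture_periods=(60.25, 70.75),
    )


@pytest.fixture(scope="session")
def small_scene() -> GroundTruthSpec:
    return small_scene_spec()


@pytest.fixture(scope="session")
def small_planes(small_scene):
    return sft.render_scene(small_scene, seed=0)


@pytest.fixture(scope="session")
def small_result(small_scene, small_planes):
    fa_plane, sf_plane = small_planes
    return sft.analyze_planes(fa_plane, sf_plane, sft.PipelineConfig())


@pytest.fixture(scope="session")
def default_scene_result():
    """Full-scale (2048^2) default-scene pipeline run; shared, computed once."""
    spec = sft.default_scene()
    fa_plane, sf_plane = sft.render_scene(spec, seed=0)
    result = sft.analyze_planes(fa_plane, sf_plane, sft.PipelineConfig())
    return spec, result


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
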