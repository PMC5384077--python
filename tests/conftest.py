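"""Shared fixtures: small rendered scenes reused across test modules."""

import numpy as np
import pytest

from conjflow.registration import register_sequence
from conjflow.synthetic import SceneSpec, VesselSpec, render_sequence

# Standard test field: tall enough for +/-48 px diameter profiles, with a
# main measurable vessel and an off-axis anchor vessel so translational
# registration is constrained in both axes.
FIELD = (232, 356)
MAIN_POINTS = [(15, 116), (340, 123)]
ANCHOR = dict(points=[(40, 180), (52, 226)], diameter_um=12.0,
              velocity_mm_s=0.3)


DIAGONAL = dict(points=[(230, 190), (330, 215)], diameter_um=14.0,
                velocity_mm_s=0.4)

# A vessel-dense field like a real conjunctival view: many orientations, so
# whole-frame registration is well conditioned in both axes.
DENSE_VESSELS = [
    dict(points=[(15, 116), (340, 123)], diameter_um=20.0, velocity_mm_s=0.5),
    dict(points=[(40, 180), (52, 226)], diameter_um=12.0, velocity_mm_s=0.3),
    dict(points=[(230, 190), (330, 215)], diameter_um=14.0, velocity_mm_s=0.4),
    dict(points=[(80, 20), (200, 60)], diameter_um=10.0, velocity_mm_s=-0.3),
    dict(points=[(300, 20), (340, 80)], diameter_um=16.0, velocity_mm_s=0.6),
    dict(points=[(120, 200), (160, 150)], diameter_um=8.0, velocity_mm_s=0.2),
]


def make_dense_scene(noise_sd=2.0, jitter_offsets=None, **kw):
    vessels = [VesselSpec(**v) for v in DENSE_VESSELS]
    return SceneSpec(shape=FIELD, vessels=vessels, noise_sd=noise_sd,
                     jitter_offsets=jitter_offsets, **kw)


def make_flow_scene(velocity_mm_s=0.5, diameter_um=20.0, noise_sd=2.0,
                    jitter_offsets=None, blink_frames=(), n_frames=50,
                    with_anchor=True, rich=False, **kw):
    """Two- or three-vessel scene; `rich` adds a third, oblique vessel so
    translational registration is well constrained in both axes."""
    vessels = [VesselSpec(points=MAIN_POINTS, diameter_um=diameter_um,
                          velocity_mm_s=velocity_mm_s)]
    if with_anchor:
        vessels.append(VesselSpec(**ANCHOR))
    if rich:
        vessels.append(VesselSpec(**DIAGONAL))
    return SceneSpec(shape=FIELD, vessels=vessels, noise_sd=noise_sd,
                     jitter_offsets=jitter_offsets, blink_frames=blink_frames,
                     n_frames=n_frames, **kw)


@pytest.fixture(scope="session")
def flow_sequence():
    """Rendered two-vessel scene with moderate flow and mild noise."""
    seq, truth = render_sequence(make_flow_scene(), seed=3)
    return seq, truth


@pytest.fixture(scope="session")
def registered_flow(flow_sequence):
    seq, truth = flow_sequence
    reg, report = register_sequence(seq)
    return reg, report, truth


@pytest.fixture(scope="session")
def static_sequence():
    """Zero-velocity, zero-noise scene: every frame identical."""
    scene = make_flow_scene(velocity_mm_s=0.0, noise_sd=0.0, with_anchor=False)
    scene.vessels[0].velocity_mm_s = 0.0
    return render_sequence(scene, seed=1)
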