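"""Shared fixtures: deterministic scenes and renderings.

Expensive renderings are session-scoped so detection tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Polygon as ShapelyPolygon

import frlquant as fq
from frlquant.geometry import Point, convex_hull
from frlquant.render import render_image
from frlquant.synthetic import ParticleRecord, SynapseScene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def wt12_preset():
    return fq.make_preset("WT", 12, "spine")


@pytest.fixture(scope="session")
def wt12_scenes(wt12_preset):
    """The 12-month wild-type spine dataset at the study's sample size."""
    return fq.generate_dataset(wt12_preset, 111, 1)


@pytest.fixture(scope="session")
def mixed_particle_scene():
    """A field of 100 particles (50 of each size class) over an IMP cluster,
    used to score the detector."""
    rng = np.random.default_rng(5)
    pts = rng.uniform(60.0, 440.0, size=(100, 2))
    particles = []
    for i, (x, y) in enumerate(pts):
        if i % 2:
            particles.append(ParticleRecord(Point(x, y), 10, "panAMPA", "E"))
        else:
            particles.append(ParticleRecord(Point(x, y), 5, "GluN1", "E"))
    imps = rng.uniform(150.0, 350.0, size=(60, 2))
    return SynapseScene(
        scene_id=0,
        imp_points=imps,
        true_polygon=convex_hull(imps),
        particles=particles,
        complete=True,
        pface_region=ShapelyPolygon(),
        genotype="WT",
        age_months=12,
        compartment="spine",
    )


@pytest.fixture(scope="session")
def renderings_by_noise(mixed_particle_scene):
    """Renderings of the mixed-particle scene at increasing noise."""
    return {
        sigma: render_image(mixed_particle_scene, noise_sigma=sigma, rng=2)
        for sigma in (0, 8, 16, 32)
    }
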