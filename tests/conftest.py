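"""Shared fixtures: small synthetic face sets, schedules, HRF kernels.

Everything is generated programmatically and seeded; session scope keeps
the more expensive face-space fixtures to a single build.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from facespace import boldsim, design, faces, space

settings.register_profile("repro", database=None, derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def face_population():
    """12 rendered faces (images + landmark sets) from one seeded population."""
    pop = faces.sample_population(12, seed=42)
    imgs, lsets = [], []
    for p in pop:
        img, lm = faces.render_face(p)
        imgs.append(img)
        lsets.append(lm)
    return imgs, lsets


@pytest.fixture(scope="session")
def small_space(face_population):
    """Warp-texture vectors + PCA model over the 12-face population."""
    imgs, lsets = face_population
    vectors, avg_lms = space.vectorize_faces(imgs, lsets)
    model = space.build_face_space(vectors)
    return vectors, model


@pytest.fixture(scope="session")
def condition_set():
    return design.caricature_condition_set(4.0, 1.0, components=3)


@pytest.fixture(scope="session")
def canonical_schedules(condition_set):
    """Three seeded event-related caricature runs (the per-subject scan set)."""
    return [design.event_related_schedule(condition_set, seed=s) for s in (11, 12, 13)]


@pytest.fixture(scope="session")
def hrf():
    return boldsim.double_gamma_hrf()
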