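"""Shared fixtures: small synthetic scenes rendered once per session."""

import numpy as np
import pytest

from fundusqc import (
    SceneSpec,
    build_projection,
    device_scene,
    render_scene,
    stripe_levels_from_samples,
)
from fundusqc.synthetic_eye import DIRECTIONS


def make_scene(f=6.0, k3=0.0, transverse=6.0, max_angle=85.0,
               levels=(40.0, 220.0), background=10.0, per_direction=None,
               **kwargs):
    """Build a simple scene; ``per_direction`` overrides (f, k3, t) tuples."""
    projections, stripe_levels = {}, {}
    reach = 0.0
    hw = 0.0
    for d in DIRECTIONS:
        fd, k3d, td = (per_direction or {}).get(d, (f, k3, transverse))
        proj = build_projection(
            f=fd, k3=k3d, transverse_samples=[(0.0, td)],
            max_angle=max_angle, direction=d)
        projections[d] = proj
        stripe_levels[d] = stripe_levels_from_samples(
            {0.0: levels}, max_angle)
        reach = max(reach, float(proj.radial(max_angle)))
        hw = max(hw, 2.5 * td)
    half = int(np.ceil(reach + hw)) + 10
    defaults = dict(
        image_shape=(2 * half + 1, 2 * half + 1),
        center=(float(half), float(half)),
        projections=projections,
        stripe_levels=stripe_levels,
        background_level=background,
    )
    defaults.update(kwargs)
    return SceneSpec(**defaults)


@pytest.fixture(scope="session")
def isotropic_scene():
    """Linear isotropic mapping: 6 px/deg radially and transversely."""
    return make_scene()


@pytest.fixture(scope="session")
def isotropic_render(isotropic_scene):
    return render_scene(isotropic_scene)


@pytest.fixture(scope="session")
def device_renders():
    """Both device-like scenes rendered noiselessly, keyed by name."""
    out = {}
    for name in ("200Tx", "California"):
        spec = device_scene(name)
        out[name] = (spec,) + render_scene(spec)
    return out
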