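import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quadpoisson import DeformationPair, DeformationScenario, MarkerQuad, apply_deformation, make_quad

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def rect_quad() -> MarkerQuad:
    """10 x 3 mm rectangle (a strip specimen's marked footprint), centred at origin."""
    return make_quad("rectangle", size=10.0, aspect=0.3)


@pytest.fixture
def worked_pair(rect_quad) -> DeformationPair:
    """Axis-aligned stretch with axial strain 0.4 and transverse strain -0.08."""
    return DeformationPair(rect_quad, rect_quad.transformed(np.diag([0.92, 1.40])))


def random_simple_quad(seed: int) -> MarkerQuad:
    return make_quad("random_simple", size=10.0, aspect=0.8, seed=seed)


def _is_convex(quad: MarkerQuad) -> bool:
    v = quad.vertices
    cross = []
    for i in range(4):
        a = v[(i + 1) % 4] - v[i]
        b = v[(i + 2) % 4] - v[(i + 1) % 4]
        cross.append(float(a[0] * b[1] - a[1] * b[0]))
    return min(cross) > 1e-6


def random_convex_quad(seed: int) -> MarkerQuad:
    """Random strictly convex quad: the bilinear Jacobian is then positive on
    the whole reference square, the domain where pointwise evaluation is
    defined."""
    for k in range(100):
        quad = random_simple_quad(seed * 997 + k)
        if _is_convex(quad):
            return quad
    raise AssertionError("no convex quad found")


def deformed_pair(quad: MarkerQuad, eps: float, nu: float, theta_deg: float = 0.0, **kw) -> DeformationPair:
    return apply_deformation(
        quad, DeformationScenario(axial_strain=eps, nu_true=nu, material_axis_deg=theta_deg, **kw)
    )
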