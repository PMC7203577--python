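import numpy as np
import pytest

from amylv import geometry
from amylv.forward import ReducedOrderInflation
from amylv.mechanics import DEFAULT_HEALTHY
from amylv.template import LVTemplateSpec, coarse_template_spec, generate_template


@pytest.fixture(scope="session")
def coarse_mesh():
    """Coarse mechanics template with fibers (thick-walled, amyloid-like)."""
    spec = coarse_template_spec(
        n_long=5, endo_base_radius=1.9, epi_base_radius=3.0
    )
    return geometry.assign_fibers(generate_template(spec))


@pytest.fixture(scope="session")
def tiny_mesh():
    """Smallest usable template (fast fits in inference tests)."""
    spec = coarse_template_spec(n_long=4)
    return geometry.assign_fibers(generate_template(spec))


@pytest.fixture(scope="session")
def hemisphere_mesh():
    """Concentric hemispherical shell, r_endo = 3 cm, r_epi = 4 cm."""
    spec = LVTemplateSpec(
        endo_base_radius=3.0,
        epi_base_radius=4.0,
        apex_to_base_length=4.0,
        truncation_fraction=0.0,
        n_circ=40,
        n_long=40,
        n_trans=3,
    )
    return generate_template(spec)


@pytest.fixture(scope="session")
def inflated_case(coarse_mesh):
    """One quasi-static inflation of the coarse template (13 frames)."""
    model = ReducedOrderInflation()
    series, curve = __import__("amylv.forward", fromlist=["inflate_lv"]).inflate_lv(
        coarse_mesh, DEFAULT_HEALTHY.scaled(8.0), 15.0, n_time=13, model=model
    )
    return coarse_mesh, series, curve, model


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation from a QR decomposition."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
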