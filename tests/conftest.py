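import numpy as np
import pytest

from cranioshape.synthetic import CohortSpec, generate_cohort, make_template


@pytest.fixture(scope="session")
def template2():
    """Coarse symmetric head template (162 vertices)."""
    return make_template(subdivisions=2)


@pytest.fixture(scope="session")
def template3():
    """Head template at the resolution used by the synthetic study."""
    return make_template(subdivisions=3)


@pytest.fixture(scope="session")
def small_cohort():
    """12-scan cohort (3 per class) at coarse resolution."""
    spec = CohortSpec(
        counts={c: 3 for c in ("control", "coronal", "sagittal", "metopic")},
        noise=0.3,
        subdivisions=2,
        seed=11,
    )
    scans, table = generate_cohort(spec)
    return scans, table


@pytest.fixture(scope="session")
def corresponded_shapes(template2):
    """Corresponded shape set: template deformed by smooth random fields
    (shared topology, no morphing needed)."""
    rng = np.random.default_rng(3)
    base = template2.mesh.vertices
    u = base / np.linalg.norm(base, axis=1, keepdims=True)
    shapes = []
    for _ in range(8):
        c = rng.normal(0, 0.02, 4)
        radial = 1.0 + c[0] * u[:, 0] ** 2 + c[1] * u[:, 1] + c[2] * u[:, 2] + c[3] * u[:, 1] * u[:, 2]
        shapes.append(base * radial[:, None])
    return np.stack(shapes), template2.mesh.faces
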