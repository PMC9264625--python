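import warnings

import numpy as np
import pytest

import facesym as fs
from facesym.synthetic_face import RaterSimConfig

# ICP non-convergence warnings on strongly asymmetric faces are expected
# behaviour (best transform returned), not test failures.
warnings.filterwarnings("ignore", message="ICP did not converge")


@pytest.fixture(scope="session")
def base_face():
    """The default exactly-symmetric synthetic face and its landmarks."""
    return fs.generate_face()


@pytest.fixture(scope="session")
def base_planes(base_face):
    _, lm = base_face
    return fs.build_planes(lm)


@pytest.fixture()
def tetrahedron():
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return fs.TriangleMesh(verts, faces)


@pytest.fixture()
def unit_cube():
    """The 12-triangle surface of the unit cube [0,1]^3."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],  # x = 0
        [4, 6, 7], [4, 7, 5],  # x = 1
        [0, 4, 5], [0, 5, 1],  # y = 0
        [2, 3, 7], [2, 7, 6],  # y = 1
        [0, 2, 6], [0, 6, 4],  # z = 0
        [1, 5, 7], [1, 7, 3],  # z = 1
    ])
    return fs.TriangleMesh(v, f)


def flat_grid(n=8, spacing=1.0, z=0.0):
    """A flat square grid mesh in the z-plane."""
    xs = np.arange(n) * spacing
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.full(n * n, float(z))])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = i * n + j, (i + 1) * n + j, (i + 1) * n + j + 1, i * n + j + 1
            faces += [[a, b, c], [a, c, d]]
    return fs.TriangleMesh(verts, np.asarray(faces))


@pytest.fixture(scope="session")
def demo_cohort_results():
    """The seeded end-to-end demo: 60 subjects, 80% symmetric, 10 raters at
    accuracy 0.9 — shared across pipeline and acceptance tests."""
    cohort = fs.generate_cohort(60, symmetric_fraction=0.8, seed=0)
    panel = fs.simulate_rater_panel(
        cohort.true_labels, RaterSimConfig(n_raters=10, accuracy=0.9, seed=1),
        subjects=cohort.subject_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fs.run_cohort(cohort, panel, fs.PipelineConfig(seed=0))
    return cohort, panel, result
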