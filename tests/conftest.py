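import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from arborgeom import synth
from arborgeom.decompose import SegmentPath
from arborgeom.swc import NeuronNode, NeuronTree


def make_tree(rows, source_name="fixture"):
    """Build a NeuronTree from (id, x, y, z, parent) tuples."""
    nodes = {
        nid: NeuronNode(nid, 2, np.array([x, y, z], float), 1.0, parent)
        for nid, x, y, z, parent in rows
    }
    root = next(n.id for n in nodes.values() if n.parent_id == -1)
    return NeuronTree(nodes=nodes, root_id=root, source_name=source_name)


@pytest.fixture
def path3():
    """Straight three-node path along x."""
    return make_tree([(1, 0, 0, 0, -1), (2, 1, 0, 0, 1), (3, 2, 0, 0, 2)])


@pytest.fixture
def y_tree():
    """Seven-node Y: 5-point trunk along x, 2 extra points branching at node 3."""
    return make_tree(
        [
            (1, 0, 0, 0, -1),
            (2, 1, 0, 0, 1),
            (3, 2, 0, 0, 2),
            (4, 3, 0, 0, 3),
            (5, 4, 0, 0, 4),
            (6, 2, 1, 0, 3),
            (7, 2, 2, 0, 6),
        ]
    )


@pytest.fixture
def helix_spec():
    return synth.CurveSpec("helix", length=100.0, point_spacing=0.5,
                           radius=1.0, pitch=1.0)


@pytest.fixture
def helix_segment(helix_spec):
    return SegmentPath(synth.make_curve_points(helix_spec), "primary", "helix")


@pytest.fixture(scope="session")
def planted_cohort():
    """30 neurons with planted curvature C>T>P and torsion C>P>T orderings."""
    return synth.make_cohort(30, rng_seed=2024)


@pytest.fixture(scope="session")
def planted_class_values(planted_cohort):
    from arborgeom import stats

    geometry = stats.cohort_geometry(planted_cohort)
    return stats.class_value_table(geometry)


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
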