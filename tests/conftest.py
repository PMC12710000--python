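import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rsaeval as rv

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def straight_root(root_id="r0", start=(0, 0, 0), direction=(0, 0, 1),
                  n_nodes=5, spacing=1.0, diameter=0.1, order=0, parent=None):
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    nodes = [
        rv.Node(position=tuple(start + i * spacing * d), diameter=diameter)
        for i in range(n_nodes)
    ]
    return rv.Root(root_id=root_id, nodes=nodes, order=order, parent_root_id=parent)


@pytest.fixture
def simple_system():
    """Taproot (9 cm down) with two perpendicular 4 cm laterals."""
    tap = straight_root("tap", n_nodes=10, spacing=1.0, diameter=0.3)
    lat1 = straight_root("lat1", start=(0, 0, 2), direction=(1, 0, 0),
                         n_nodes=5, spacing=1.0, order=1, parent="tap")
    lat2 = straight_root("lat2", start=(0, 0, 5), direction=(-1, 0, 0),
                         n_nodes=5, spacing=1.0, order=1, parent="tap")
    return rv.RootSystem(roots=[tap, lat1, lat2], label="simple")


@pytest.fixture(scope="session")
def default_rsa():
    """One default generated faba-bean-like RSA, shared across tests."""
    return rv.generate_root_system(rv.GeneratorParams(seed=42))


def translate(rsa, offset):
    offset = np.asarray(offset, dtype=float)
    out = rv.copy_system(rsa)
    for root in out.roots:
        root.nodes = [
            rv.Node(position=tuple(np.asarray(n.position) + offset),
                    diameter=n.diameter)
            for n in root.nodes
        ]
    return out


def rigid_transform(rsa, rotation, offset):
    """Apply a rotation matrix then a translation to every node."""
    rotation = np.asarray(rotation, dtype=float)
    offset = np.asarray(offset, dtype=float)
    out = rv.copy_system(rsa)
    for root in out.roots:
        root.nodes = [
            rv.Node(position=tuple(rotation @ np.asarray(n.position) + offset),
                    diameter=n.diameter)
            for n in root.nodes
        ]
    return out


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
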