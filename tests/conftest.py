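import numpy as np
import pytest

from caninebsp.inertial_math import GeometricSolid


def random_solid(shape: str, rng: np.random.Generator) -> GeometricSolid:
    """A random well-conditioned solid of the given shape (segment-like sizes)."""
    length = rng.uniform(0.1, 0.5)
    r = rng.uniform(0.02, 0.12)
    density = rng.uniform(900.0, 1100.0)
    if shape == "cylinder":
        dims = {"radius": r, "length": length}
    elif shape == "cone":
        dims = {"radius": r, "length": length}
    elif shape == "conical_frustum":
        dims = {"r_proximal": r, "r_distal": r * rng.uniform(0.4, 1.6), "length": length}
    elif shape == "rectangular_pyramid":
        dims = {"base_a": 2 * r, "base_b": 2 * r * rng.uniform(0.5, 1.5), "length": length}
    elif shape == "ellipsoid":
        dims = {
            "semi_a": r,
            "semi_b": r * rng.uniform(0.5, 1.5),
            "semi_c": length / 2.0,
        }
    else:
        raise ValueError(shape)
    return GeometricSolid(shape=shape, dimensions=dims, density=density)


def random_tensor(rng: np.random.Generator):
    """A random physically realizable inertia tensor (from a point cloud)."""
    from caninebsp.inertial_math import InertiaTensor

    pts = rng.normal(scale=0.2, size=(30, 3))
    masses = rng.uniform(0.1, 1.0, size=30)
    pts -= np.average(pts, axis=0, weights=masses)
    i_xx = float(np.sum(masses * (pts[:, 1] ** 2 + pts[:, 2] ** 2)))
    i_yy = float(np.sum(masses * (pts[:, 0] ** 2 + pts[:, 2] ** 2)))
    i_zz = float(np.sum(masses * (pts[:, 0] ** 2 + pts[:, 1] ** 2)))
    p_xy = float(np.sum(masses * pts[:, 0] * pts[:, 1]))
    p_xz = float(np.sum(masses * pts[:, 0] * pts[:, 2]))
    p_yz = float(np.sum(masses * pts[:, 1] * pts[:, 2]))
    return InertiaTensor(i_xx, i_yy, i_zz, p_xy, p_xz, p_yz)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
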