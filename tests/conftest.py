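import numpy as np
import pandas as pd
import pytest

from allohub.alphabet import FragmentLibrary, default_library
from allohub.traj_io import Trajectory


@pytest.fixture(scope="session")
def library() -> FragmentLibrary:
    return default_library()


@pytest.fixture(scope="session")
def tiny_library() -> FragmentLibrary:
    """Three well-separated prototypes: extended, right-angle, zig-zag."""
    s = 0.38
    protos = np.array(
        [
            [[0, 0, 0], [s, 0, 0], [2 * s, 0, 0], [3 * s, 0, 0]],
            [[0, 0, 0], [s, 0, 0], [s, s, 0], [s, 2 * s, 0]],
            [[0, 0, 0], [s, 0, 0], [s, s, 0], [2 * s, s, 0]],
        ]
    )
    return FragmentLibrary(letters=["A", "B", "C"], prototypes=protos, name="tiny3")


def poly_ca_trajectory(
    coords_per_frame: np.ndarray, chain_id: str = "A"
) -> Trajectory:
    """Wrap (frames, atoms, 3) Cα coordinates into a Trajectory."""
    coords = np.asarray(coords_per_frame, dtype=float)
    n_atoms = coords.shape[1]
    topo = pd.DataFrame(
        {
            "chain_id": chain_id,
            "res_id": np.arange(1, n_atoms + 1),
            "res_name": "ALA",
            "atom_name": "CA",
            "element": "C",
            "mass": 12.011,
        }
    )
    return Trajectory(
        coords=coords, times=np.arange(coords.shape[0], dtype=float), topology=topo
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
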