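import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)


@pytest.fixture
def minimal_pdb_text() -> str:
    return MINIMAL_PDB


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def blob_cloud():
    """A medium star-shaped cloud with known per-octant dispersions."""
    from sriselect import CloudSpec, generate_blob_cloud

    sd = np.array([1.0, 1.4, 0.8, 1.2, 1.0, 1.3, 0.9, 1.1])
    spec = CloudSpec(
        points_per_octant=100, radial_mean=20.0, radial_sd_per_octant=sd, seed=7
    )
    return generate_blob_cloud(spec), sd


def random_rotation(seed: int) -> np.ndarray:
    """Uniform random proper rotation matrix (QR-based, deterministic)."""
    g = np.random.default_rng(seed)
    q, r = np.linalg.qr(g.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
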