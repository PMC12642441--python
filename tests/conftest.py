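import numpy as np
import pytest

from medstates import eigenmodes as em
from medstates import simulate as sim


@pytest.fixture(scope="session")
def sphere2_basis():
    """Full eigenmode basis of a subdivisions-2 icosphere (162 vertices)."""
    mesh = sim.generate_mesh("icosphere", 2)
    A, M = em.assemble_lbo(mesh.vertices, mesh.faces)
    basis = em.solve_eigenmodes(A, M, n_modes=len(mesh.vertices))
    return mesh, A, M, basis


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
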