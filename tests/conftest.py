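import numpy as np
import pytest

from colonymech.mesh import TissueMesh, build_disc_colony


@pytest.fixture(scope="session")
def disc_mesh():
    """Small relaxed disc colony reused across read-only tests."""
    return build_disc_colony(30, np.sqrt(30 / np.pi), seed=7, boundary_segments=256)


@pytest.fixture()
def jittered_mesh():
    """Random mesh: relaxed tiling plus vertex noise (no vertex sits exactly
    on the confinement circle, where the hinge penalty has a kink)."""

    def make(seed: int, n_cells: int = 12) -> TissueMesh:
        m = build_disc_colony(
            n_cells, np.sqrt(n_cells / np.pi), seed=seed, boundary_segments=64, n_lloyd=15
        )
        rng = np.random.default_rng(seed + 1000)
        m.vertices += rng.normal(0.0, 0.015, m.vertices.shape)
        m.invalidate()
        return m

    return make


@pytest.fixture()
def unit_square_cell():
    return TissueMesh(
        np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]), [np.arange(4)]
    )


def four_cell_cross(center_len: float = 0.5):
    """Quartet of cells around a central vertical edge of given length.

    Cells: left and right share the central edge; top and bottom flank it.
    Built so a T1 on the central edge is geometrically clean.
    """
    h = center_len / 2
    verts = np.array(
        [
            [0.0, h],      # 0 top end of central edge
            [0.0, -h],     # 1 bottom end
            [-1.0, 1.2], [-1.4, 0.0], [-1.0, -1.2],   # 2,3,4 left outer
            [1.0, -1.2], [1.4, 0.0], [1.0, 1.2],      # 5,6,7 right outer
            [0.0, 1.8], [0.0, -1.8],                  # 8 top apex, 9 bottom apex
        ]
    )
    cells = [
        np.array([0, 2, 3, 4, 1]),     # left (traverses central edge 1 -> 0)
        np.array([0, 1, 5, 6, 7]),     # right (central edge 0 -> 1)
        np.array([0, 7, 8, 2]),        # top
        np.array([9, 5, 1, 4]),        # bottom
    ]
    m = TissueMesh(verts, cells)
    m.validate()
    return m
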