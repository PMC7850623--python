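"""Per-cell polarity directors and their nematic alignment dynamics.

Each cell carries a unit vector p whose dynamics are strictly nematic: all
torques are 2-psi-periodic, so every rule is exactly invariant under
flipping any p to -p.  Boundary cells are anchored to the local colony
boundary tangent, interior cells align with their neighbours, and an
optional stretch-alignment term turns polarities toward an externally
imposed stretch axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TissueMesh
from .nematic import defect_field


@dataclass
class AlignmentParams:
    """Rates (1/time) of the polarity torques.

    ``k_neighbor``: relaxation toward the mean neighbour nematic;
    ``k_boundary``: anchoring of boundary cells to the boundary tangent;
    ``m_stretch``: alignment to the stretch axis, active only in the
    stretching scenario; ``noise``: std of the Gaussian angular increment
    per unit time (default 0); ``stretch_axis``: stretch-axis angle
    (radians, default 0 = x axis).
    """

    k_neighbor: float = 0.1
    k_boundary: float = 0.1
    m_stretch: float = 1.0
    noise: float = 0.0
    stretch_axis: float = 0.0

    def __post_init__(self):
        for name in ("k_neighbor", "k_boundary", "m_stretch", "noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class PolarityField:
    """Unit director per cell, stored as angles with a vector view."""

    def __init__(self, angles: np.ndarray):
        self.angles = np.asarray(angles, dtype=float).copy()

    @property
    def vectors(self) -> np.ndarray:
        return np.stack([np.cos(self.angles), np.sin(self.angles)], axis=1)

    def __len__(self) -> int:
        return len(self.angles)

    def copy(self) -> "PolarityField":
        return PolarityField(self.angles)

    def flip(self, cells) -> None:
        """Flip p -> -p for the given cells (dynamics are invariant)."""
        self.angles[cells] = self.angles[cells] + np.pi


def init_polarity_two_defects(
    mesh: TissueMesh,
    defect_charges: np.ndarray | list,
    defect_positions: np.ndarray | list,
    alpha0: float,
    seed: int,
) -> PolarityField:
    """Initial polarity mimicking a nematic pattern with prescribed defects.

    Each cell's axis is the one-constant-approximation defect field
    ``alpha0 + sum_i k_i atan2(y - y_i, x - x_i)`` evaluated at its
    centroid; the +/- sign along the axis is assigned at random and then
    greedily flipped to minimize the magnitude of the total polarity, so
    the colony carries no net polar order.  Deterministic for a fixed seed.
    """
    charges = np.asarray(defect_charges, dtype=float)
    positions = np.asarray(defect_positions, dtype=float).reshape(-1, 2)
    centroids = mesh.cell_centroids()
    if len(charges):
        axes = defect_field(charges, positions, alpha0, centroids)
    else:
        axes = np.full(mesh.n_cells, alpha0 % np.pi)
    if not np.all(np.isfinite(axes)):
        raise ValueError("defect field evaluated to a non-finite angle")

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=mesh.n_cells)
    vecs = np.stack([np.cos(axes), np.sin(axes)], axis=1)
    # greedy descent on |sum p|: flip any cell whose flip shortens the sum
    total = np.sum(signs[:, None] * vecs, axis=0)
    for _ in range(20):
        changed = False
        for i in rng.permutation(mesh.n_cells):
            trial = total - 2.0 * signs[i] * vecs[i]
            if np.dot(trial, trial) < np.dot(total, total) - 1e-15:
                total = trial
                signs[i] = -signs[i]
                changed = True
        if not changed:
            break
    angles = np.where(signs > 0, axes, axes + np.pi)
    return PolarityField(angles)


def boundary_tangent_angles(mesh: TissueMesh) -> np.ndarray:
    """Local boundary-tangent nematic angle per cell (nan for interior cells).

    The tangent is the length-weighted nematic average of the cell's own
    boundary edges.
    """
    e = mesh.edges
    out = np.full(mesh.n_cells, np.nan)
    bnd = ~e.interior
    if not np.any(bnd):
        return out
    vec = mesh.edge_vectors()[bnd]
    lengths = np.linalg.norm(vec, axis=1)
    ang = np.arctan2(vec[:, 1], vec[:, 0])
    cells = e.c1[bnd]
    c2 = np.bincount(cells, weights=lengths * np.cos(2 * ang), minlength=mesh.n_cells)
    s2 = np.bincount(cells, weights=lengths * np.sin(2 * ang), minlength=mesh.n_cells)
    has = np.bincount(cells, minlength=mesh.n_cells) > 0
    out[has] = 0.5 * np.arctan2(s2[has], c2[has])
    return out


def update_polarity(
    mesh: TissueMesh,
    field: PolarityField,
    params: AlignmentParams,
    dt: float,
    stretching: bool = False,
    rng: np.random.Generator | None = None,
) -> PolarityField:
    """Advance all director angles by one step of the alignment dynamics.

    d(psi_a)/dt = k_n sin 2(psibar_a - psi_a)
                + [boundary] k_b sin 2(psi_t - psi_a)
                + [stretching] m_stretch sin 2(psi_s - psi_a)  + noise

    where psibar_a is the angle of the average neighbour nematic tensor,
    psi_t the local boundary tangent and psi_s the stretch axis.  The field
    is updated in place and returned.
    """
    if len(field) != mesh.n_cells:
        raise ValueError("polarity field does not match the mesh")
    psi = field.angles
    torque = np.zeros(mesh.n_cells)

    if params.k_neighbor > 0:
        e = mesh.edges
        interior = e.interior
        ci, cj = e.c1[interior], e.c2[interior]
        c2 = np.bincount(ci, weights=np.cos(2 * psi[cj]), minlength=mesh.n_cells)
        s2 = np.bincount(ci, weights=np.sin(2 * psi[cj]), minlength=mesh.n_cells)
        c2 += np.bincount(cj, weights=np.cos(2 * psi[ci]), minlength=mesh.n_cells)
        s2 += np.bincount(cj, weights=np.sin(2 * psi[ci]), minlength=mesh.n_cells)
        has = (c2**2 + s2**2) > 1e-300
        # sin 2(psibar - psi) built from the tensor average, magnitude-normalized
        psibar = 0.5 * np.arctan2(s2, c2)
        torque[has] += params.k_neighbor * np.sin(2 * (psibar[has] - psi[has]))

    if params.k_boundary > 0:
        tang = boundary_tangent_angles(mesh)
        isb = np.isfinite(tang)
        torque[isb] += params.k_boundary * np.sin(2 * (tang[isb] - psi[isb]))

    if stretching and params.m_stretch > 0:
        torque += params.m_stretch * np.sin(2 * (params.stretch_axis - psi))

    psi += dt * torque
    if params.noise > 0:
        if rng is None:
            raise ValueError("noise > 0 requires an rng")
        psi += params.noise * np.sqrt(dt) * rng.standard_normal(mesh.n_cells)
    return field
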