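"""Mechanics of the active vertex model.

The tissue energy has an area-elastic and an edge-tension term,

    E = sum_cells K/2 (A - A0)^2 + sum_edges Lambda_e * l_e  (+ confinement),

and vertices move overdamped, gamma dx/dt = F, with F the sum of the
passive force -dE/dx, the anisotropic active-stress traction, and a
polarity-directed motility force.  Simulation units are nondimensional with
A0 = K = gamma = 1; nondimensional ("primed") activity magnitudes are
measured against the passive junctional tension Lambda (see
``ModelParams.from_primed``).

Sign conventions: the per-cell active stress is S = sigma_a (p p - I/2);
negative sigma_a is extensile and elongates the cell along its polarity p,
positive sigma_a is contractile and elongates it perpendicular to p.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .mesh import TissueMesh
from .topology import (
    T1Event,
    collapse_short_boundary_edges,
    t1_transitions,
    t2_transitions,
)


class ContractViolation(ValueError):
    """A caller-supplied map does not cover the mesh (e.g. missing tension)."""


class IntegrationFailure(RuntimeError):
    """Non-finite positions produced by a time step."""


@dataclass
class ModelParams:
    """Mechanical parameters of the vertex model.

    All values in nondimensional simulation units (A0 = K = gamma = 1).

    Attributes
    ----------
    K : area stiffness (energy / length^4).
    Lambda : base interior edge tension (energy / length).
    Lambda_b : boundary edge tension; defaults to ``Lambda`` (set in
        ``__post_init__`` when left as None).
    sigma_a : active stress magnitude (signed; < 0 extensile along p).
    lam : edge-tension bias amplitude; positive values lower the tension of
        edges parallel to p and raise it for perpendicular ones.
    v0 : motility speed fed to internal cells.
    gamma : vertex friction coefficient.
    dt : integration time step upper bound (adaptively reduced, see ``step``).
    eps_cls, eps_opn : T1 closing/opening edge-length thresholds,
        ``eps_opn > eps_cls > 0``.
    t1_cooldown : steps during which a freshly created edge cannot re-flip.
    confine_radius : radius of the circular confinement.
    confine_stiffness : harmonic penalty stiffness on vertices outside the
        confinement radius.
    motility_includes_boundary : whether boundary cells contribute to the
        motility force on their vertices (default: internal cells only).
    dt_disp_frac : adaptive-step safety factor: the maximum vertex
        displacement in one step is capped at ``dt_disp_frac * eps_cls``.
    """

    K: float = 1.0
    Lambda: float = 0.1
    Lambda_b: float | None = None
    sigma_a: float = 0.0
    lam: float = 0.0
    v0: float = 0.0
    gamma: float = 1.0
    dt: float = 5e-3
    eps_cls: float = 0.06
    eps_opn: float = 0.13
    t1_cooldown: int = 10
    confine_radius: float = 1.0
    confine_stiffness: float = 100.0
    motility_includes_boundary: bool = False
    dt_disp_frac: float = 0.2
    # lower bound on biased junctional tension: a cortical cable can relax
    # to zero tension but cannot push, and unchecked negative tension makes
    # edges extend through neighbouring cells.  None disables the floor.
    tension_floor: float | None = 0.0
    # area below which a crushed cell is removed (T2); 0 disables
    t2_area: float = 0.02

    def __post_init__(self):
        if self.Lambda_b is None:
            self.Lambda_b = self.Lambda
        if not (self.eps_opn > self.eps_cls > 0):
            raise ValueError("need eps_opn > eps_cls > 0")
        for name in ("K", "gamma", "dt", "confine_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # Nondimensional ("primed") activity values measure the active terms
    # against the passive junctional tension: stress unit Lambda / sqrt(A0),
    # tension unit Lambda, speed unit Lambda / (gamma sqrt(A0)).  With
    # A0 = gamma = 1 in simulation units the conversion is a bare factor
    # Lambda.  Measuring activity against the area modulus K A0 instead
    # would put the quoted primed magnitudes (5-50) far above the cell
    # collapse threshold, so the tension scale is the one that keeps the
    # stated parameter sets physical.
    @property
    def sigma_a_prime(self) -> float:
        return self.sigma_a / self.Lambda

    @property
    def lam_prime(self) -> float:
        return self.lam / self.Lambda

    @property
    def v0_prime(self) -> float:
        return self.v0 * self.gamma / self.Lambda

    @classmethod
    def from_primed(
        cls,
        sigma_a_prime: float = 0.0,
        lam_prime: float = 0.0,
        v0_prime: float = 0.0,
        Lambda: float = 0.1,
        bias_scale: float = 0.12,
        **kwargs,
    ) -> "ModelParams":
        """Build params from nondimensional activity magnitudes.

        ``bias_scale`` is the ratio of the tension-bias unit to the stress
        unit; it locates the crossover between shape-dominated and
        rearrangement-dominated elongation and is calibrated once so the
        quoted primed parameter sets fall in their respective regimes.
        """
        return cls(
            Lambda=Lambda,
            sigma_a=sigma_a_prime * Lambda,
            lam=lam_prime * Lambda * bias_scale,
            v0=v0_prime * Lambda,
            **kwargs,
        )

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Tensions
# ---------------------------------------------------------------------------

def _polarity_vectors(polarity, n_cells: int) -> np.ndarray:
    """Accept a PolarityField or a raw (Nc, 2) array of directors."""
    vec = getattr(polarity, "vectors", polarity)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n_cells, 2):
        raise ContractViolation("polarity must be defined for every cell")
    return vec


def biased_edge_tensions(
    mesh: TissueMesh,
    polarity: np.ndarray,
    Lambda: float,
    Lambda_b: float,
    lam: float,
    tension_floor: float | None = None,
) -> np.ndarray:
    """Polarity-biased tension per edge (aligned with ``mesh.edges``).

    Interior edge between cells a, b:

        Lambda_ab = Lambda - lam/2 * [ (e.p_a)^2 + (e.p_b)^2 - 1 ]

    with e the edge unit vector.  The bias is nematic (invariant under
    p -> -p), has zero mean over director orientations, is minimal when the
    edge is parallel to both polarities and maximal when perpendicular.
    Boundary edges get the unbiased ``Lambda_b``.
    """
    polarity = _polarity_vectors(polarity, mesh.n_cells)
    e = mesh.edges
    vec = mesh.edge_vectors()
    lengths = np.linalg.norm(vec, axis=1)
    tensions = np.full(len(e), Lambda_b, dtype=float)
    interior = e.interior & (lengths > 0)
    if lam != 0.0 or Lambda != Lambda_b:
        ehat = np.zeros_like(vec)
        ehat[lengths > 0] = vec[lengths > 0] / lengths[lengths > 0, None]
        pa = polarity[e.c1[interior]]
        pb = polarity[e.c2[interior]]
        dots_a = np.einsum("ij,ij->i", ehat[interior], pa) ** 2
        dots_b = np.einsum("ij,ij->i", ehat[interior], pb) ** 2
        tensions[interior] = Lambda - 0.5 * lam * (dots_a + dots_b - 1.0)
    else:
        tensions[interior] = Lambda
    # degenerate (zero-length) interior edges: direction undefined, keep base
    tensions[e.interior & (lengths == 0)] = Lambda
    if tension_floor is not None:
        np.maximum(tensions, tension_floor, out=tensions)
    return tensions


# ---------------------------------------------------------------------------
# Energy and passive forces
# ---------------------------------------------------------------------------


def _scatter_add(F: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """Accumulate 2-D vectors into F by index (bincount is much faster
    than np.add.at for the repeated small scatters in the force kernels)."""
    n = len(F)
    F[:, 0] += np.bincount(idx, weights=vals[:, 0], minlength=n)
    F[:, 1] += np.bincount(idx, weights=vals[:, 1], minlength=n)


def _confinement_energy(mesh: TissueMesh, params: ModelParams) -> float:
    r = np.linalg.norm(mesh.vertices, axis=1)
    excess = np.maximum(0.0, r - params.confine_radius)
    return 0.5 * params.confine_stiffness * float(np.sum(excess**2))


def tissue_energy(
    mesh: TissueMesh,
    params: ModelParams,
    tensions: np.ndarray,
    confined: bool = False,
) -> float:
    """Total mechanical energy: area elasticity + edge tension (+ confinement)."""
    tensions = np.asarray(tensions, dtype=float)
    if tensions.shape != (len(mesh.edges),):
        raise ContractViolation(
            f"need one tension per edge ({len(mesh.edges)}), got shape {tensions.shape}"
        )
    A = mesh.cell_areas()
    e_area = 0.5 * params.K * float(np.sum((A - mesh.preferred_areas) ** 2))
    e_edge = float(np.sum(tensions * mesh.edge_lengths()))
    e_conf = _confinement_energy(mesh, params) if confined else 0.0
    return e_area + e_edge + e_conf


def _outward_normals(mesh: TissueMesh) -> np.ndarray:
    """Half-edge-midpoint outward normal per flat-loop entry.

    For a CCW polygon the vector with components
    (y_next - y_prev, x_prev - x_next)/2 points outward and has length
    half the distance between the two neighbouring vertices; it equals the
    gradient of the cell area with respect to the entry's vertex.
    """
    f = mesh.flat
    x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
    return 0.5 * np.stack([y[f.vnext] - y[f.vprev], x[f.vprev] - x[f.vnext]], axis=1)


def passive_forces(
    mesh: TissueMesh,
    params: ModelParams,
    tensions: np.ndarray,
    confined: bool = False,
) -> np.ndarray:
    """Per-vertex force -dE/dx for the area, tension (and confinement) terms."""
    tensions = np.asarray(tensions, dtype=float)
    if tensions.shape != (len(mesh.edges),):
        raise ContractViolation("need one tension per edge")
    F = np.zeros_like(mesh.vertices)

    # area term: F_i -= K (A_c - A0_c) * dA_c/dx_i, with dA/dx the outward normal
    f = mesh.flat
    n = _outward_normals(mesh)
    A = mesh.cell_areas()
    coef = -params.K * (A - mesh.preferred_areas)
    _scatter_add(F, f.vi, coef[f.ci, None] * n)

    # tension term: each edge pulls its endpoints together with force T along it
    e = mesh.edges
    vec = mesh.edge_vectors()
    lengths = np.linalg.norm(vec, axis=1)
    ok = lengths > 0  # zero-length edges are the T1 machinery's job
    unit = np.zeros_like(vec)
    unit[ok] = vec[ok] / lengths[ok, None]
    pull = tensions[:, None] * unit
    _scatter_add(F, e.v1, pull)
    _scatter_add(F, e.v2, -pull)

    if confined:
        r = np.linalg.norm(mesh.vertices, axis=1)
        out = r > params.confine_radius
        if np.any(out):
            F[out] -= (
                params.confine_stiffness
                * (r[out] - params.confine_radius)[:, None]
                * mesh.vertices[out]
                / r[out, None]
            )
    return F


# ---------------------------------------------------------------------------
# Active forces
# ---------------------------------------------------------------------------

def active_stress_forces(
    mesh: TissueMesh, polarity: np.ndarray, sigma_a: float
) -> np.ndarray:
    """Vertex forces from the per-cell anisotropic active stress.

    Each cell carries the traceless stress S = sigma_a (p p - I/2).  Its
    boundary traction is discretized with the half-edge-midpoint rule: the
    force the cell exerts on vertex i is -S . n_i with n_i the outward
    normal of length half the prev-to-next vertex distance.  The sign makes
    sigma_a < 0 (extensile) push the polygon outward along p.  Per cell the
    contributions sum to zero exactly (closed polygon).
    """
    polarity = _polarity_vectors(polarity, mesh.n_cells)
    norms = np.linalg.norm(polarity, axis=1)
    if np.any(norms == 0):
        raise ContractViolation("zero-norm polarity vector")
    F = np.zeros_like(mesh.vertices)
    if sigma_a == 0.0:
        return F
    p = polarity / norms[:, None]
    # S components per cell: S = sigma_a (pp - I/2)
    sxx = sigma_a * (p[:, 0] ** 2 - 0.5)
    sxy = sigma_a * (p[:, 0] * p[:, 1])
    syy = sigma_a * (p[:, 1] ** 2 - 0.5)
    f = mesh.flat
    n = _outward_normals(mesh)
    cx, cy = f.ci, f.ci
    fx = -(sxx[cx] * n[:, 0] + sxy[cx] * n[:, 1])
    fy = -(sxy[cy] * n[:, 0] + syy[cy] * n[:, 1])
    _scatter_add(F, f.vi, np.stack([fx, fy], axis=1))
    return F


def motility_forces(
    mesh: TissueMesh,
    polarity: np.ndarray,
    v0: float,
    gamma: float,
    include_boundary_cells: bool = False,
) -> np.ndarray:
    """gamma * v0 * (mean polarity of the vertex's adjoining internal cells).

    Boundary cells are excluded from the average by default (motility is fed
    to internal cells); vertices touching only boundary cells then feel no
    motility force.  Set ``include_boundary_cells`` to average over all
    adjoining cells instead.
    """
    if v0 < 0:
        raise ValueError("v0 must be non-negative")
    polarity = _polarity_vectors(polarity, mesh.n_cells)
    F = np.zeros_like(mesh.vertices)
    if v0 == 0.0:
        return F
    f = mesh.flat
    use = np.ones(mesh.n_cells, dtype=bool)
    if not include_boundary_cells:
        use = ~mesh.boundary_cells
    sel = use[f.ci]
    psum = np.zeros_like(mesh.vertices)
    _scatter_add(psum, f.vi[sel], polarity[f.ci[sel]])
    count = np.bincount(f.vi[sel], minlength=mesh.n_vertices).astype(float)
    ok = count > 0
    F[ok] = gamma * v0 * psum[ok] / count[ok, None]
    return F


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

def total_forces(
    mesh: TissueMesh,
    polarity: np.ndarray,
    params: ModelParams,
    confined: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """(forces, tensions) for the current state."""
    tensions = biased_edge_tensions(
        mesh,
        polarity,
        params.Lambda,
        params.Lambda_b,
        params.lam,
        tension_floor=params.tension_floor,
    )
    F = passive_forces(mesh, params, tensions, confined=confined)
    if params.sigma_a != 0.0:
        F += active_stress_forces(mesh, polarity, params.sigma_a)
    if params.v0 != 0.0:
        F += motility_forces(
            mesh,
            polarity,
            params.v0,
            params.gamma,
            include_boundary_cells=params.motility_includes_boundary,
        )
    return F, tensions


def step(
    mesh: TissueMesh,
    polarity: np.ndarray,
    params: ModelParams,
    confined: bool = False,
    adaptive: bool = True,
) -> tuple[float, list[T1Event], float]:
    """One overdamped explicit-Euler step followed by T1 processing.

    The step size is ``params.dt``, adaptively reduced so that no vertex
    moves farther than ``dt_disp_frac * eps_cls`` (short-edge resolution).
    The mesh is updated in place.  Returns ``(dt_used, t1_events,
    max_displacement)``.
    """
    F, _ = total_forces(mesh, polarity, params, confined=confined)
    vmax = float(np.max(np.linalg.norm(F, axis=1))) / params.gamma
    dt = params.dt
    if adaptive and vmax > 0:
        dt = min(dt, params.dt_disp_frac * params.eps_cls / vmax)
    x0 = mesh.vertices.copy()
    alive = mesh.alive
    for _ in range(12):
        mesh.vertices = x0 + (dt / params.gamma) * F
        mesh.invalidate()
        if np.all(mesh.cell_areas()[alive] > 0):
            break
        dt *= 0.5  # a polygon would invert: bisect the step
    else:
        mesh.vertices = x0
        mesh.invalidate()
        raise IntegrationFailure(f"cannot avoid cell inversion at t={mesh.time:.6g}")
    if not np.all(np.isfinite(mesh.vertices)):
        bad = int(np.nonzero(~np.isfinite(mesh.vertices).all(axis=1))[0][0])
        raise IntegrationFailure(
            f"non-finite position at vertex {bad}, t={mesh.time:.6g}"
        )
    mesh.time += dt
    mesh.invalidate()
    events: list = t1_transitions(mesh, params.eps_cls, params.eps_opn, params.t1_cooldown)
    events += collapse_short_boundary_edges(mesh, params.eps_cls)
    if params.t2_area > 0:
        events += t2_transitions(mesh, params.t2_area)
    return dt, events, vmax * dt
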