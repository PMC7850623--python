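"""Polygonal tissue mesh: the simulated colony state.

A confluent epithelial colony is represented as a planar tiling of simple
polygons (cells).  Vertices are shared between cells; each interior edge is
shared by exactly two cells and each boundary edge belongs to exactly one.
Cell identity is the index into the cell list and is never reused, so cells
can be tracked through topological rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon


class MeshInvariantError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class _FlatLoops:
    """Flattened cell-loop arrays for vectorized geometry kernels.

    One entry per (cell, loop position).  ``vi`` is the vertex id of the
    entry, ``vnext``/``vprev`` the neighbouring vertex ids along the loop,
    and ``ci`` the owning cell id.
    """

    ci: np.ndarray
    vi: np.ndarray
    vnext: np.ndarray
    vprev: np.ndarray


@dataclass
class _EdgeTable:
    """Unique undirected edges with their adjoining cells.

    ``c2`` is -1 for boundary edges.
    """

    v1: np.ndarray
    v2: np.ndarray
    c1: np.ndarray
    c2: np.ndarray

    def __len__(self) -> int:
        return len(self.v1)

    @property
    def interior(self) -> np.ndarray:
        return self.c2 >= 0

    def key(self, i: int) -> tuple[int, int]:
        a, b = int(self.v1[i]), int(self.v2[i])
        return (a, b) if a < b else (b, a)


class TissueMesh:
    """Vertices, polygonal cells and derived edge/adjacency structure.

    Parameters
    ----------
    vertices : (Nv, 2) float array
        Vertex positions in simulation length units.
    cells : list of int arrays
        Counter-clockwise vertex loops, one per cell.
    preferred_areas : (Nc,) array, optional
        Per-cell preferred area ``A0``; defaults to the initial areas.
    time : float
        Simulation time, monotonically increasing.
    """

    def __init__(self, vertices, cells, preferred_areas=None, time: float = 0.0):
        self.vertices = np.asarray(vertices, dtype=float).copy()
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise MeshInvariantError("vertices must be an (Nv, 2) array")
        self.cells = [np.asarray(c, dtype=np.int64) for c in cells]
        for loop in self.cells:
            # empty loops are placeholders for removed (extruded) cells so
            # that cell ids stay stable through topological events
            if 0 < len(loop) < 3:
                raise MeshInvariantError("every living cell needs at least 3 vertices")
        self.time = float(time)
        self._cache: dict = {}
        if preferred_areas is None:
            self.preferred_areas = self.cell_areas().copy()
        else:
            self.preferred_areas = np.asarray(preferred_areas, dtype=float).copy()
            if len(self.preferred_areas) != len(self.cells):
                raise MeshInvariantError("one preferred area per cell required")
        # T1 bookkeeping: (v1, v2) sorted pair -> remaining cooldown steps
        self.t1_cooldown: dict[tuple[int, int], int] = {}

    # ------------------------------------------------------------------ basic
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def alive(self) -> np.ndarray:
        """Boolean mask of living cells (empty loops mark removed cells)."""
        return np.array([len(loop) >= 3 for loop in self.cells])

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def copy(self) -> "TissueMesh":
        m = TissueMesh(
            self.vertices, [c.copy() for c in self.cells], self.preferred_areas, self.time
        )
        m.t1_cooldown = dict(self.t1_cooldown)
        return m

    def invalidate(self, topology: bool = False) -> None:
        """Drop caches; call after mutating positions (or topology)."""
        if topology:
            self._cache.clear()
        else:
            for k in ("areas", "centroids"):
                self._cache.pop(k, None)

    # ------------------------------------------------------------- structure
    @property
    def flat(self) -> _FlatLoops:
        if "flat" not in self._cache:
            ci = np.concatenate(
                [np.full(len(loop), i, dtype=np.int64) for i, loop in enumerate(self.cells)]
            )
            vi = np.concatenate(self.cells)
            vnext = np.concatenate([np.roll(loop, -1) for loop in self.cells])
            vprev = np.concatenate([np.roll(loop, 1) for loop in self.cells])
            self._cache["flat"] = _FlatLoops(ci, vi, vnext, vprev)
        return self._cache["flat"]

    @property
    def edges(self) -> _EdgeTable:
        if "edges" not in self._cache:
            emap: dict[tuple[int, int], list[int]] = {}
            for c, loop in enumerate(self.cells):
                for a, b in zip(loop, np.roll(loop, -1)):
                    key = (int(a), int(b)) if a < b else (int(b), int(a))
                    emap.setdefault(key, []).append(c)
            v1, v2, c1, c2 = [], [], [], []
            for (a, b), cs in emap.items():
                if len(cs) > 2:
                    raise MeshInvariantError(f"edge {(a, b)} adjoins {len(cs)} cells")
                v1.append(a)
                v2.append(b)
                c1.append(cs[0])
                c2.append(cs[1] if len(cs) == 2 else -1)
            self._cache["edges"] = _EdgeTable(
                np.array(v1, dtype=np.int64),
                np.array(v2, dtype=np.int64),
                np.array(c1, dtype=np.int64),
                np.array(c2, dtype=np.int64),
            )
        return self._cache["edges"]

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices lying on a boundary edge."""
        if "bverts" not in self._cache:
            e = self.edges
            mask = np.zeros(self.n_vertices, dtype=bool)
            bnd = ~e.interior
            mask[e.v1[bnd]] = True
            mask[e.v2[bnd]] = True
            self._cache["bverts"] = mask
        return self._cache["bverts"]

    @property
    def boundary_cells(self) -> np.ndarray:
        """Boolean mask of cells owning at least one boundary edge."""
        if "bcells" not in self._cache:
            e = self.edges
            mask = np.zeros(self.n_cells, dtype=bool)
            mask[e.c1[~e.interior]] = True
            self._cache["bcells"] = mask
        return self._cache["bcells"]

    def vertex_cells(self) -> list[list[int]]:
        """Cells adjoining each vertex."""
        if "vcells" not in self._cache:
            out: list[list[int]] = [[] for _ in range(self.n_vertices)]
            for c, loop in enumerate(self.cells):
                for v in loop:
                    out[int(v)].append(c)
            self._cache["vcells"] = out
        return self._cache["vcells"]

    def cell_neighbors(self) -> list[set[int]]:
        """Edge-sharing neighbour sets per cell."""
        if "cneigh" not in self._cache:
            out: list[set[int]] = [set() for _ in range(self.n_cells)]
            e = self.edges
            for c1, c2 in zip(e.c1[e.interior], e.c2[e.interior]):
                out[int(c1)].add(int(c2))
                out[int(c2)].add(int(c1))
            self._cache["cneigh"] = out
        return self._cache["cneigh"]

    # -------------------------------------------------------------- geometry
    def _cross_terms(self):
        f = self.flat
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        cross = x[f.vi] * y[f.vnext] - x[f.vnext] * y[f.vi]
        return f, x, y, cross

    def cell_areas(self) -> np.ndarray:
        if "areas" not in self._cache:
            f, _, _, cross = self._cross_terms()
            self._cache["areas"] = 0.5 * np.bincount(
                f.ci, weights=cross, minlength=self.n_cells
            )
        return self._cache["areas"]

    def cell_centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            f, x, y, cross = self._cross_terms()
            A = self.cell_areas()
            cx = np.bincount(f.ci, weights=(x[f.vi] + x[f.vnext]) * cross, minlength=self.n_cells)
            cy = np.bincount(f.ci, weights=(y[f.vi] + y[f.vnext]) * cross, minlength=self.n_cells)
            with np.errstate(divide="ignore", invalid="ignore"):
                c = np.stack([cx, cy], axis=1) / (6.0 * A[:, None])
            self._cache["centroids"] = c
        return self._cache["centroids"]

    def edge_vectors(self) -> np.ndarray:
        e = self.edges
        return self.vertices[e.v2] - self.vertices[e.v1]

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        """Check all structural invariants; raise MeshInvariantError on failure."""
        _ = self.edges  # raises if an edge adjoins >2 cells
        areas = self.cell_areas()
        alive = self.alive
        if not np.all(areas[alive] > 0):
            bad = np.nonzero(alive & (areas <= 0))[0]
            raise MeshInvariantError(f"non-positive (or CW) cell areas at {bad[:5]}")
        for c, loop in enumerate(self.cells):
            if not alive[c]:
                continue
            if len(np.unique(loop)) != len(loop):
                raise MeshInvariantError(f"cell {c} repeats a vertex")
            if not Polygon(self.vertices[loop]).is_simple:
                raise MeshInvariantError(f"cell {c} polygon self-intersects")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshInvariantError("non-finite vertex positions")

    # ------------------------------------------------------------ shape
    def cell_moment_tensor(self, cell: int) -> np.ndarray:
        """Area-normalized second central moment tensor of one cell polygon."""
        loop = self.cells[cell]
        return polygon_moment_tensor(self.vertices[loop])

    def cell_shape_nematic(self, cell: int) -> tuple[np.ndarray, float]:
        """Cell-elongation nematic from the moment-equivalent ellipse.

        Returns ``(q, theta)`` where ``q = |q| (cos 2θ, sin 2θ)`` with
        ``|q| = ½ ln(a/b)``, the log axis ratio of the ellipse with the same
        normalized second central area moments, and θ the major-axis angle.
        A degenerate polygon yields a zero tensor and ``theta = nan``.
        """
        M = self.cell_moment_tensor(cell)
        return _nematic_from_moments(M)

    def all_cell_nematics(self) -> tuple[np.ndarray, np.ndarray]:
        """(Nc, 2) array of q components and (Nc,) angles for all cells."""
        qs = np.zeros((self.n_cells, 2))
        th = np.zeros(self.n_cells)
        for c in range(self.n_cells):
            q, t = self.cell_shape_nematic(c)
            qs[c] = q
            th[c] = t
        return qs, th


def polygon_moment_tensor(pts: np.ndarray) -> np.ndarray:
    """Second central area moments (area-normalized) of a simple polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    A = 0.5 * np.sum(cross)
    if abs(A) < 1e-300:
        return np.zeros((2, 2))
    cx = np.sum((x + xn) * cross) / (6 * A)
    cy = np.sum((y + yn) * cross) / (6 * A)
    mxx = np.sum((x * x + x * xn + xn * xn) * cross) / 12.0
    myy = np.sum((y * y + y * yn + yn * yn) * cross) / 12.0
    mxy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    M = np.array([[mxx / A - cx * cx, mxy / A - cx * cy], [mxy / A - cx * cy, myy / A - cy * cy]])
    return M


def _nematic_from_moments(M: np.ndarray) -> tuple[np.ndarray, float]:
    w, V = np.linalg.eigh(M)
    if w[0] <= 0 or not np.all(np.isfinite(w)):
        return np.zeros(2), float("nan")
    # eigh sorts ascending: w[1] is the major axis
    mag = 0.25 * np.log(w[1] / w[0])  # = ½ ln(a/b) with a/b = sqrt(w1/w0)
    theta = float(np.arctan2(V[1, 1], V[0, 1])) % np.pi
    return mag * np.array([np.cos(2 * theta), np.sin(2 * theta)]), theta


# ---------------------------------------------------------------------------
# Disc colony construction
# ---------------------------------------------------------------------------

def build_disc_colony(
    n_cells: int,
    radius: float,
    seed: int,
    n_lloyd: int = 40,
    boundary_segments: int = 4096,
) -> TissueMesh:
    """Confluent disc-shaped colony of ``n_cells`` cells.

    Random seed points in the disc are Lloyd-relaxed (Voronoi + centroid
    iterations, clipped to the disc) and the final clipped Voronoi
    tessellation becomes the cell tiling.  The disc boundary is the
    ``boundary_segments``-gon inscribed in the circle; cell areas therefore
    tile that polygon's area (within 1e-6 of pi r^2 at the default
    resolution).  Deterministic for a fixed seed.
    """
    if n_cells < 7:
        raise ValueError("n_cells must be at least 7")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(0, 1, n_cells))
    phi = rng.uniform(0, 2 * np.pi, n_cells)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)

    disc = Point(0.0, 0.0).buffer(radius, quad_segs=max(boundary_segments // 4, 8))
    n_ghost = max(64, 2 * n_cells)
    gang = np.linspace(0, 2 * np.pi, n_ghost, endpoint=False)
    ghosts = 3.0 * radius * np.stack([np.cos(gang), np.sin(gang)], axis=1)

    def _clipped_regions(points):
        vor = Voronoi(np.vstack([points, ghosts]))
        polys = []
        for i in range(len(points)):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) < 3:
                raise RuntimeError("unbounded Voronoi region despite ghost ring")
            poly = Polygon(vor.vertices[region]).intersection(disc)
            if poly.is_empty or poly.geom_type != "Polygon":
                raise RuntimeError(f"degenerate clipped region for point {i}")
            polys.append(poly)
        return polys

    for _ in range(n_lloyd):
        polys = _clipped_regions(pts)
        pts = np.array([[p.centroid.x, p.centroid.y] for p in polys])

    polys = _clipped_regions(pts)

    # Deduplicate shared vertices by snapping to a fine grid (1e-7 of radius).
    quant = radius * 1e-7
    vid: dict[tuple[int, int], int] = {}
    verts: list[tuple[float, float]] = []
    loops: list[np.ndarray] = []
    for poly in polys:
        coords = np.asarray(poly.exterior.coords)[:-1]
        # shapely exteriors are CCW for positive-area polygons after
        # intersection, but normalize anyway
        if _signed_area(coords) < 0:
            coords = coords[::-1]
        loop = []
        for xy in coords:
            key = (int(round(xy[0] / quant)), int(round(xy[1] / quant)))
            if key not in vid:
                vid[key] = len(verts)
                verts.append((xy[0], xy[1]))
            idx = vid[key]
            if not loop or loop[-1] != idx:
                loop.append(idx)
        if loop[0] == loop[-1]:
            loop.pop()
        loops.append(np.array(loop, dtype=np.int64))

    mesh = TissueMesh(np.array(verts), loops, time=0.0)
    mesh.validate()
    return mesh


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
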