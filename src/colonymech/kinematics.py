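"""Colony-scale shape tensors and the triangle-method shear decomposition.

Colony anisotropy is measured by ellipse fitting:

    Q_xx = 1/2 ln(a/b) cos 2(theta - alpha),
    Q_xy = 1/2 ln(a/b) sin 2(theta - alpha),

with a, b, theta the moment-equivalent ellipse axes/orientation and alpha a
reference angle (final colony angle, or the stretch axis = 0).

Cellular contributions to tissue shear follow the dynamic-triangulation
method: cell centers of each tri-cellular contact form a triangle; tissue
pure shear over a time interval is the area-weighted mean of the
symmetric-traceless log deformation gradient of persistent triangles, and
topological changes (T1, division, extrusion) enter through the elongation
carried by appearing/disappearing triangles.  A correlation term closes the
balance exactly, so the five contributions always sum to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import polygon_moment_tensor


# ---------------------------------------------------------------------------
# Ellipse / Q tensor
# ---------------------------------------------------------------------------

@dataclass
class EllipseFit:
    """Moment-equivalent ellipse of a region: semi-axes a >= b, angle theta."""

    a: float
    b: float
    theta: float
    centroid: tuple[float, float]

    def __post_init__(self):
        if not self.a >= self.b > 0:
            raise ValueError("need a >= b > 0")
        self.theta = float(self.theta) % np.pi

    @property
    def aspect(self) -> float:
        return self.a / self.b


def _ellipse_from_moments(M: np.ndarray, centroid, tol: float = 1e-12) -> EllipseFit:
    w, V = np.linalg.eigh(M)
    if w[0] <= 0:
        raise ValueError("degenerate region (zero minor moment)")
    a, b = 2 * np.sqrt(w[1]), 2 * np.sqrt(w[0])
    if (a - b) / a < tol:
        theta = 0.0  # deterministic tie-break for circles
    else:
        theta = np.arctan2(V[1, 1], V[0, 1]) % np.pi
    return EllipseFit(a=a, b=b, theta=theta, centroid=tuple(centroid))


def fit_ellipse(region) -> EllipseFit:
    """Moment-equivalent ellipse of a binary mask or a polygon.

    ``region`` is either a 2-D boolean/0-1 raster (pixel coordinates
    x = column, y = row) or an (N, 2) polygon vertex array.  The ellipse
    has the region's centroid and normalized second central moments; the
    semi-axes are ``2 sqrt(lambda)`` of the moment eigenvalues, so a solid
    disc maps to a = b = its radius.
    """
    region = np.asarray(region)
    if region.ndim == 2 and region.shape[1] == 2 and region.dtype.kind == "f":
        M = polygon_moment_tensor(region)
        x, y = region[:, 0], region[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        A = 0.5 * np.sum(cross)
        if A == 0:
            raise ValueError("degenerate polygon")
        cx = np.sum((x + xn) * cross) / (6 * A)
        cy = np.sum((y + yn) * cross) / (6 * A)
        return _ellipse_from_moments(M, (cx, cy))
    mask = region.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    M = np.array([[np.mean(dx * dx), np.mean(dx * dy)], [np.mean(dx * dy), np.mean(dy * dy)]])
    return _ellipse_from_moments(M, (cx, cy))


def shape_Q(fit: EllipseFit, alpha_ref: float = 0.0) -> tuple[float, float]:
    """(Q_xx, Q_xy) of an ellipse fit relative to the reference angle."""
    mag = 0.5 * np.log(fit.aspect)
    return (
        float(mag * np.cos(2 * (fit.theta - alpha_ref))),
        float(mag * np.sin(2 * (fit.theta - alpha_ref))),
    )


def mean_cell_speed(trajectory: np.ndarray, dt: float) -> float:
    """Mean speed along a tracked trajectory: sum of per-interval
    displacement magnitudes divided by the trajectory duration."""
    traj = np.asarray(trajectory, dtype=float).reshape(-1, 2)
    if len(traj) < 2:
        raise ValueError("need at least 2 frames")
    steps = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    return float(np.sum(steps) / (dt * (len(traj) - 1)))


# ---------------------------------------------------------------------------
# Tracked frames
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """Single frame of a tracked segmentation: ids, centroids, adjacency."""

    ids: np.ndarray
    positions: np.ndarray
    neighbors: dict[int, set[int]]
    tags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("cell ids must be unique within a frame")
        for i, ns in self.neighbors.items():
            for j in ns:
                if i not in self.neighbors.get(j, set()):
                    raise ValueError(f"asymmetric neighbor relation {i}-{j}")

    def pos_of(self) -> dict[int, np.ndarray]:
        return {int(i): self.positions[k] for k, i in enumerate(self.ids)}


@dataclass
class TrackedFrames:
    """Time series of tracked frames (simulated or converted TA/TM export)."""

    times: np.ndarray
    frames: list[Frame]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("one time per frame required")

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------

def _triangles_of_frame(frame: Frame, log: list | None = None) -> list[tuple[int, int, int]]:
    """Triangles = triples of mutually neighbouring cells, K4s split.

    Four mutually adjacent cells would produce four overlapping triangles;
    the clique is split along its shortest diagonal (the two non-hull-edge
    pairs of a convex quad), deterministically.
    """
    adj = {int(i): {int(j) for j in frame.neighbors.get(int(i), set())} for i in frame.ids}
    ids_sorted = sorted(adj)
    tris: set[tuple[int, int, int]] = set()
    for i in ids_sorted:
        ni = [j for j in adj[i] if j > i]
        for a_idx in range(len(ni)):
            for b_idx in range(a_idx + 1, len(ni)):
                a, b = ni[a_idx], ni[b_idx]
                if b in adj[a]:
                    tris.add((i, a, b))
    # resolve K4 cliques
    pos = frame.pos_of()
    quads: set[tuple[int, int, int, int]] = set()
    for (i, a, b) in list(tris):
        common = (adj[i] & adj[a] & adj[b]) - {i, a, b}
        for c in common:
            quads.add(tuple(sorted((i, a, b, c))))
    for quad in sorted(quads):
        drop = _split_quad(quad, pos, log)
        tris -= drop
    return sorted(tris)


def _split_quad(quad, pos, log) -> set[tuple[int, int, int]]:
    """Triangles of a K4 clique to discard, keeping a shortest-diagonal split."""
    pts = np.array([pos[q] for q in quad])
    hull = _convex_hull_order(pts)
    all_tris = {tuple(sorted(t)) for t in
                [(quad[0], quad[1], quad[2]), (quad[0], quad[1], quad[3]),
                 (quad[0], quad[2], quad[3]), (quad[1], quad[2], quad[3])]}
    if len(hull) < 4:
        # one point inside the others: keep the three small triangles,
        # drop the enclosing one
        inner = [k for k in range(4) if k not in hull]
        if len(inner) != 1:
            return set()
        outer_tri = tuple(sorted(quad[k] for k in hull[:3])) if len(hull) == 3 else None
        if log is not None:
            log.append(f"K4 {quad}: interior point, outer triangle dropped")
        return {outer_tri} if outer_tri in all_tris else set()
    # convex: diagonals are the two non-adjacent hull pairs
    d1 = (quad[hull[0]], quad[hull[2]])
    d2 = (quad[hull[1]], quad[hull[3]])
    l1 = np.linalg.norm(pos[d1[0]] - pos[d1[1]])
    l2 = np.linalg.norm(pos[d2[0]] - pos[d2[1]])
    keep_diag = set(d1) if l1 <= l2 else set(d2)
    keep = {t for t in all_tris if keep_diag <= set(t)}
    if log is not None:
        log.append(f"K4 {quad}: split along diagonal {sorted(keep_diag)}")
    return all_tris - keep


def _convex_hull_order(pts: np.ndarray) -> list[int]:
    """Indices of hull points in CCW order (tiny n; cross-product walk)."""
    from scipy.spatial import ConvexHull, QhullError

    try:
        return list(ConvexHull(pts).vertices)
    except QhullError:
        return [0, 1, 2]


def triangulate_frames(frames: TrackedFrames, log: list | None = None) -> list[list[tuple[int, int, int]]]:
    """Per-frame triangle lists (sorted id triples) of tri-cellular contacts."""
    return [_triangles_of_frame(f, log) for f in frames.frames]


# ---------------------------------------------------------------------------
# Triangle tensors
# ---------------------------------------------------------------------------

def triangle_elongation(points: np.ndarray) -> tuple[float, float]:
    """Elongation nematic (q_xx, q_xy) of a triangle.

    Defined through the vertex moment (gyration) tensor
    G = mean_i (x_i - xbar)(x_i - xbar)^T: q is half the traceless part of
    log(G / sqrt(det G)).  Zero iff the triangle is equilateral,
    rotation-equivariant, independent of vertex labeling, and equal to the
    log pure-strain of the affine map from an equal-area equilateral
    reference triangle.
    """
    pts = np.asarray(points, dtype=float).reshape(3, 2)
    c = pts.mean(axis=0)
    d = pts - c
    G = d.T @ d / 3.0
    det = np.linalg.det(G)
    if det <= 0:
        raise DegenerateTriangleError("collinear centroids")
    Ghat = G / np.sqrt(det)
    # closed-form log of a symmetric unimodular 2x2 matrix
    w, V = np.linalg.eigh(Ghat)
    L = V @ np.diag(np.log(w)) @ V.T
    return float(0.5 * L[0, 0]), float(0.5 * L[0, 1])


class DegenerateTriangleError(ValueError):
    pass


def _triangle_area(pts: np.ndarray) -> float:
    (x1, y1), (x2, y2), (x3, y3) = pts
    return 0.5 * abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1))


def sym_traceless_log_F(ref: np.ndarray, cur: np.ndarray) -> tuple[float, float]:
    """Symmetric-traceless part of log F for the triangle map ref -> cur.

    F maps the edge matrix of the reference triangle onto the current one
    (vertex correspondence by position in the array).  The matrix log is
    evaluated in closed form on SL(2) after removing the isotropic part; a
    rotation contributes only to the antisymmetric part, so rigid motions
    give exactly zero.
    """
    D0 = np.stack([ref[1] - ref[0], ref[2] - ref[0]], axis=1)
    D1 = np.stack([cur[1] - cur[0], cur[2] - cur[0]], axis=1)
    det0 = np.linalg.det(D0)
    if det0 == 0:
        raise DegenerateTriangleError("degenerate reference triangle")
    F = D1 @ np.linalg.inv(D0)
    detF = np.linalg.det(F)
    if detF <= 0:
        raise DegenerateTriangleError("orientation-reversing or singular map")
    A = F / np.sqrt(detF)
    L = _logm_sl2(A)
    return float(0.5 * (L[0, 0] - L[1, 1])), float(0.5 * (L[0, 1] + L[1, 0]))


def _logm_sl2(A: np.ndarray) -> np.ndarray:
    """Real matrix logarithm of a 2x2 matrix with det 1 and tr > -2."""
    h = 0.5 * (A[0, 0] + A[1, 1])
    B = A - h * np.eye(2)  # traceless part; B^2 = (h^2 - 1) I
    if h >= 1.0 + 1e-12:
        mu = np.arccosh(h)
        return (mu / np.sinh(mu)) * B
    if h <= 1.0 - 1e-12:
        if h <= -1.0:
            raise DegenerateTriangleError("matrix log undefined (trace <= -2)")
        phi = np.arccos(h)
        return (phi / np.sin(phi)) * B
    return B  # h ~ 1: log A ~ A - I, and tr B = 0


# ---------------------------------------------------------------------------
# Shear decomposition
# ---------------------------------------------------------------------------

CHANNELS = ("total", "elongation", "t1", "division", "extrusion", "correlation")


@dataclass
class ShearDecomposition:
    """Per-interval and cumulative pure shear split into contributions.

    ``per_interval`` and ``cumulative`` are DataFrames with columns
    ``time`` and ``<channel>_xx`` / ``<channel>_xy`` for each of total,
    elongation (cell-elongation change), t1, division, extrusion and
    correlation; ``mean_q`` holds the area-weighted mean triangle
    elongation per frame.  Per interval the five contributions sum to the
    total exactly (the correlation term is defined as the closure of the
    mean-field balance).
    """

    per_interval: pd.DataFrame
    cumulative: pd.DataFrame
    mean_q: pd.DataFrame
    warnings: list = field(default_factory=list)

    def cumulative_channel(self, channel: str, axis_angle: float = 0.0) -> float:
        """Final cumulative xx component of a channel along an axis."""
        row = self.cumulative.iloc[-1]
        return project_xx(row[f"{channel}_xx"], row[f"{channel}_xy"], axis_angle)


def project_xx(t_xx: float, t_xy: float, axis_angle: float) -> float:
    """xx component of a traceless symmetric tensor in a rotated frame."""
    return float(t_xx * np.cos(2 * axis_angle) + t_xy * np.sin(2 * axis_angle))


def decompose_shear(
    frames: TrackedFrames,
    triangulations: list[list[tuple[int, int, int]]] | None = None,
) -> ShearDecomposition:
    """Triangle-method decomposition of cumulative pure shear.

    Per interval [t_k, t_{k+1}]:

    * total: area-weighted mean symmetric-traceless log deformation
      gradient of triangles persisting through the interval;
    * elongation: change of the area-weighted mean triangle elongation
      restricted to persistent triangles (weights at interval start);
    * t1 / division / extrusion: minus the jump of the mean triangle
      elongation caused by triangle turnover, i.e. +(area-share weighted
      elongation of disappearing triangles) - (that of appearing ones):
      a neighbour exchange that extends the tissue along x swaps
      x-elongated triangles for y-elongated ones and therefore registers
      positive xx rearrangement shear while the tissue itself has not yet
      deformed.  Channels are attributed by the lineage tags of the cells
      involved; untagged topology changes count as T1 for neighbour
      exchanges among persisting cells and are otherwise folded into the
      correlation closure with a warning;
    * correlation: total minus all other contributions (exact closure).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    if triangulations is None:
        triangulations = triangulate_frames(frames)
    warnings: list = []
    rows = []
    meanq_rows = []

    def frame_tri_data(k: int):
        f = frames.frames[k]
        pos = f.pos_of()
        out = {}
        for t in triangulations[k]:
            pts = np.array([pos[c] for c in t])
            area = _triangle_area(pts)
            if area <= 0:
                warnings.append(f"frame {k}: degenerate triangle {t} excluded")
                continue
            try:
                q = triangle_elongation(pts)
            except DegenerateTriangleError:
                warnings.append(f"frame {k}: degenerate triangle {t} excluded")
                continue
            out[t] = (pts, area, np.array(q))
        return out

    data = [frame_tri_data(k) for k in range(len(frames))]

    for k in range(len(frames)):
        tris = data[k]
        tot_area = sum(a for (_, a, _) in tris.values())
        mq = (
            sum(a * q for (_, a, q) in tris.values()) / tot_area
            if tot_area > 0
            else np.zeros(2)
        )
        meanq_rows.append(
            {"time": frames.times[k], "mean_q_xx": mq[0], "mean_q_xy": mq[1]}
        )

    for k in range(len(frames) - 1):
        d0, d1 = data[k], data[k + 1]
        keys0, keys1 = set(d0), set(d1)
        persistent = keys0 & keys1
        disappearing = keys0 - keys1
        appearing = keys1 - keys0

        area0_all = sum(d0[t][1] for t in d0) or 1.0
        area1_all = sum(d1[t][1] for t in d1) or 1.0

        # total shear from persistent triangles
        tot = np.zeros(2)
        wsum = 0.0
        for t in persistent:
            pts0, a0, _ = d0[t]
            pts1, _, _ = d1[t]
            try:
                g = np.array(sym_traceless_log_F(pts0, pts1))
            except DegenerateTriangleError:
                warnings.append(f"interval {k}: degenerate map for {t} excluded")
                continue
            tot += a0 * g
            wsum += a0
        if wsum > 0:
            tot /= wsum

        # cell-elongation change on persistent triangles, start-area weights
        elong = np.zeros(2)
        if wsum > 0:
            q0 = sum(d0[t][1] * d0[t][2] for t in persistent) / wsum
            q1 = sum(d0[t][1] * d1[t][2] for t in persistent) / wsum
            elong = q1 - q0

        # topological terms, classified by tags
        gain_loss = {"t1": np.zeros(2), "division": np.zeros(2), "extrusion": np.zeros(2)}
        f0, f1 = frames.frames[k], frames.frames[k + 1]
        daughters = {
            int(i)
            for i in f1.ids
            if f1.tags.get(int(i), "none").startswith("divided")
            and int(i) not in set(int(j) for j in f0.ids)
        }
        mothers = set()
        for dgt in daughters:
            tag = f1.tags.get(dgt, "")
            if ":" in tag:
                try:
                    mothers.add(int(tag.split(":", 1)[1]))
                except ValueError:
                    pass
        extruded = {
            int(i)
            for i in f0.ids
            if f0.tags.get(int(i), "none") == "extruded"
            and int(i) not in set(int(j) for j in f1.ids)
        }
        ext_neigh = set()
        for e in extruded:
            ext_neigh |= set(f0.neighbors.get(e, set()))
        lost_untagged = (
            set(int(i) for i in f0.ids) - set(int(i) for i in f1.ids)
        ) - extruded
        new_untagged = (
            set(int(i) for i in f1.ids) - set(int(i) for i in f0.ids)
        ) - daughters
        if lost_untagged or new_untagged:
            warnings.append(
                f"interval {k}: untagged appearing/disappearing cells "
                f"{sorted(new_untagged | lost_untagged)} fall into the correlation closure"
            )

        def classify(tri, appearing_side: bool) -> str | None:
            cells = set(tri)
            if cells & (daughters | mothers):
                return "division"
            if (not appearing_side and cells & extruded) or (
                appearing_side and extruded and cells <= ext_neigh
            ):
                return "extrusion"
            if cells & (lost_untagged | new_untagged):
                return None  # closure handles it
            return "t1"

        for t in disappearing:
            ch = classify(t, appearing_side=False)
            if ch is not None:
                _, a, q = d0[t]
                gain_loss[ch] += (a / area0_all) * q
        for t in appearing:
            ch = classify(t, appearing_side=True)
            if ch is not None:
                _, a, q = d1[t]
                gain_loss[ch] -= (a / area1_all) * q

        corr = tot - elong - gain_loss["t1"] - gain_loss["division"] - gain_loss["extrusion"]
        rows.append(
            {
                "time": frames.times[k + 1],
                "total_xx": tot[0],
                "total_xy": tot[1],
                "elongation_xx": elong[0],
                "elongation_xy": elong[1],
                "t1_xx": gain_loss["t1"][0],
                "t1_xy": gain_loss["t1"][1],
                "division_xx": gain_loss["division"][0],
                "division_xy": gain_loss["division"][1],
                "extrusion_xx": gain_loss["extrusion"][0],
                "extrusion_xy": gain_loss["extrusion"][1],
                "correlation_xx": corr[0],
                "correlation_xy": corr[1],
            }
        )

    per = pd.DataFrame(rows)
    cum = per.copy()
    for col in per.columns:
        if col != "time":
            cum[col] = per[col].cumsum()
    # prepend the zero row at t0 so cumulative curves start at the origin
    zero = {c: 0.0 for c in per.columns if c != "time"}
    zero["time"] = frames.times[0]
    cum = pd.concat([pd.DataFrame([zero]), cum], ignore_index=True)
    return ShearDecomposition(
        per_interval=per,
        cumulative=cum,
        mean_q=pd.DataFrame(meanq_rows),
        warnings=warnings,
    )
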