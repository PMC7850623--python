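"""Seeded synthetic-input generators.

Every analysis operation in the package can be exercised without any
external file: junction images rendered from a mesh (emulating
GFP-E-cadherin movies), stripe/streak textures with a prescribed
orientation field, affine centroid trajectories (an exact oracle for the
shear decomposition), and scripted topology events for channel
attribution.  Each generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.draw import line_aa

from .kinematics import Frame, TrackedFrames
from .mesh import TissueMesh
from .nematic import defect_field


# ---------------------------------------------------------------------------
# Junction image rendering
# ---------------------------------------------------------------------------

def render_junction_image(
    mesh: TissueMesh,
    px_per_unit: float = 20.0,
    line_width: float = 2.0,
    noise_sd: float = 0.05,
    margin: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Render cell edges as bright anti-aliased lines on a dark background.

    The image covers the mesh bounding box plus a relative ``margin``;
    Gaussian noise of standard deviation ``noise_sd`` (intensity units,
    lines ~ 1) is added.  Returns a float image in row (y) x column (x)
    order with the same axis orientation as the mesh.
    """
    if px_per_unit <= 0:
        raise ValueError("px_per_unit must be positive")
    lengths = mesh.edge_lengths()
    if np.median(lengths[lengths > 0]) * px_per_unit < 1.0:
        raise ValueError("px_per_unit too small: edges would be under 1 px")
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    span = hi - lo
    pad = margin * max(span)
    size = np.ceil((span + 2 * pad) * px_per_unit).astype(int) + 1
    img = np.zeros((size[1], size[0]), dtype=float)

    def to_px(xy):
        return (xy - lo + pad) * px_per_unit

    e = mesh.edges
    p1 = to_px(mesh.vertices[e.v1])
    p2 = to_px(mesh.vertices[e.v2])
    for (x1, y1), (x2, y2) in zip(p1, p2):
        rr, cc, val = line_aa(int(round(y1)), int(round(x1)), int(round(y2)), int(round(x2)))
        ok = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
        np.maximum.at(img, (rr[ok], cc[ok]), val[ok])
    if line_width > 1:
        img = ndimage.gaussian_filter(img, line_width / 2.0)
        if img.max() > 0:
            img /= img.max()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


# ---------------------------------------------------------------------------
# Orientation textures
# ---------------------------------------------------------------------------

def stripe_texture(
    charges,
    positions,
    alpha: float,
    size: int = 256,
    wavelength: float = 12.0,
    seed: int = 0,
) -> np.ndarray:
    """Grayscale texture whose local orientation follows the defect field.

    Without defects the texture is an exact cosine grating running along
    the angle ``alpha`` with the requested wavelength.  A single +-1/2
    defect admits an exact grating too: the phase is the harmonic
    conjugate of the director potential (Im of a power of z - z0), whose
    level curves are everywhere tangent to the defect field; the cosine is
    even, so the branch-cut sign flip of the half-integer power is
    invisible.  Its local wavelength drifts like sqrt(r) and is normalized
    to ``wavelength`` at mid-radius.  For several defects no closed form
    exists and the texture is synthesized by line-integral convolution:
    seeded noise repeatedly averaged along the local director and
    band-passed, giving streaks aligned with the field away from cores.
    """
    if wavelength < 4:
        raise ValueError("wavelength must be at least 4 px")
    charges = np.asarray(charges, dtype=float)
    if len(charges) == 0:
        y, x = np.mgrid[0:size, 0:size].astype(float)
        s = -x * np.sin(alpha) + y * np.cos(alpha)  # advances perpendicular to stripes
        return np.cos(2 * np.pi * s / wavelength)
    if len(charges) == 1 and abs(abs(charges[0]) - 0.5) < 1e-12:
        k = float(charges[0])
        x0, y0 = np.asarray(positions, dtype=float).reshape(2)
        y, x = np.mgrid[0:size, 0:size].astype(float)
        z = (x - x0) + 1j * (y - y0)
        z = np.where(z == 0, 1e-9, z)
        # antiderivative of exp(-i alpha) z^{-k}: phase advances
        # perpendicular to the director alpha + k arg(z)
        f = np.exp(-1j * alpha) * z ** (1.0 - k) / (1.0 - k)
        r0 = size / 4.0  # |f'| = r^{-k}: normalize the spacing at mid-radius
        return np.cos(2 * np.pi * f.imag * r0 ** (-k) / wavelength)

    y, x = np.mgrid[0:size, 0:size].astype(float)
    pts = np.stack([x.ravel(), y.ravel()], axis=1)
    # nudge any pixel sitting exactly on a defect core
    positions = np.asarray(positions, dtype=float).reshape(-1, 2) + 0.5 * (
        np.asarray(positions, dtype=float).reshape(-1, 2) % 1 == 0
    )
    phi = defect_field(charges, positions, alpha, pts).reshape(size, size)
    dx, dy = np.cos(phi), np.sin(phi)

    rng = np.random.default_rng(seed)
    img = rng.standard_normal((size, size))
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    n_iter = int(round(2 * wavelength))
    for _ in range(n_iter):
        fwd = ndimage.map_coordinates(img, [rows + dy, cols + dx], order=1, mode="reflect")
        bwd = ndimage.map_coordinates(img, [rows - dy, cols - dx], order=1, mode="reflect")
        img = (img + fwd + bwd) / 3.0
    # band-pass to stripe-like contrast at the requested scale
    img = ndimage.gaussian_filter(img, 1.0) - ndimage.gaussian_filter(img, wavelength / 2.0)
    img /= max(img.std(), 1e-12)
    return img


# ---------------------------------------------------------------------------
# Tracked-frame fixtures
# ---------------------------------------------------------------------------

def frames_from_mesh(mesh: TissueMesh, time: float = 0.0) -> Frame:
    """Single tracked frame (ids, centroids, adjacency) from a mesh.

    Cell ids are mesh cell indices (stable through T1/T2 events); removed
    cells are excluded.
    """
    alive = np.nonzero(mesh.alive)[0]
    pos = mesh.cell_centroids()[alive]
    all_neigh = mesh.cell_neighbors()
    neigh = {int(i): set(map(int, all_neigh[i])) for i in alive}
    return Frame(ids=alive, positions=pos, neighbors=neigh)


def hexagonal_patch(n_rings: int = 2, spacing: float = 1.0) -> Frame:
    """Hexagonally packed cell centroids with lattice adjacency."""
    coords = []
    for qq in range(-n_rings, n_rings + 1):
        for rr in range(-n_rings, n_rings + 1):
            if abs(qq + rr) <= n_rings:
                xx = spacing * (qq + rr / 2.0)
                yy = spacing * (np.sqrt(3) / 2.0) * rr
                coords.append((xx, yy))
    pos = np.array(coords)
    n = len(pos)
    neigh: dict[int, set[int]] = {i: set() for i in range(n)}
    thr = 1.01 * spacing
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pos[i] - pos[j]) < thr:
                neigh[i].add(j)
                neigh[j].add(i)
    return Frame(ids=np.arange(n), positions=pos, neighbors=neigh)


def affine_series(base: Frame, shear: float, n_frames: int, dt: float = 1.0) -> TrackedFrames:
    """Pure-shear affine trajectory: frame k applies
    diag(e^{s k/(n-1)}, e^{-s k/(n-1)}) to all centroids; topology frozen.
    An exact oracle: cumulative total xx shear equals ``shear`` with all
    topological channels zero."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = []
    for k in range(n_frames):
        s = shear * k / (n_frames - 1)
        M = np.diag([np.exp(s), np.exp(-s)])
        frames.append(
            Frame(
                ids=base.ids.copy(),
                positions=base.positions @ M.T,
                neighbors={i: set(ns) for i, ns in base.neighbors.items()},
                tags=dict(base.tags),
            )
        )
    return TrackedFrames(times=np.arange(n_frames) * dt, frames=frames)


def rotated_series(base: Frame, angle: float, n_frames: int, dt: float = 1.0) -> TrackedFrames:
    """Rigid-rotation trajectory (objectivity oracle: zero shear)."""
    frames = []
    for k in range(n_frames):
        a = angle * k / (n_frames - 1)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        frames.append(
            Frame(
                ids=base.ids.copy(),
                positions=base.positions @ R.T,
                neighbors={i: set(ns) for i, ns in base.neighbors.items()},
                tags=dict(base.tags),
            )
        )
    return TrackedFrames(times=np.arange(n_frames) * dt, frames=frames)


class UnrealizableEvent(ValueError):
    pass


def scripted_events(base: TrackedFrames, event: dict | None) -> TrackedFrames:
    """Edit neighbor lists and tags to realize exactly one scripted event.

    ``event`` is None (identity) or a dict with key ``kind``:

    * ``{"kind": "t1", "frame": f, "lose": (a, b), "gain": (c, d)}``:
      from frame f on, cells a-b stop being neighbours and c-d start.
    * ``{"kind": "division", "frame": f, "mother": m, "child": new_id}``:
      from frame f on a child cell appears next to the mother (tagged
      ``divided:<mother>`` on its first frame), splitting the mother's
      neighbourhood along the division axis.
    * ``{"kind": "extrusion", "frame": f, "cell": c}``: cell c is tagged
      ``extruded`` on frame f-1 and removed from frame f on; the hole is
      re-triangulated by fanning its former neighbours.
    """
    out = TrackedFrames(
        times=base.times.copy(),
        frames=[
            Frame(
                ids=f.ids.copy(),
                positions=f.positions.copy(),
                neighbors={i: set(ns) for i, ns in f.neighbors.items()},
                tags=dict(f.tags),
            )
            for f in base.frames
        ],
    )
    if event is None:
        return out
    kind = event["kind"]
    f0 = int(event["frame"])
    if not 1 <= f0 < len(out):
        raise UnrealizableEvent("event frame out of range")

    if kind == "t1":
        a, b = map(int, event["lose"])
        c, d = map(int, event["gain"])
        pre = out.frames[f0 - 1]
        if b not in pre.neighbors.get(a, set()):
            raise UnrealizableEvent(f"cells {a},{b} are not neighbours before the flip")
        for side in (c, d):
            if not {a, b} <= pre.neighbors.get(side, set()):
                raise UnrealizableEvent(f"cell {side} does not flank the {a}-{b} contact")
        for fr in out.frames[f0:]:
            fr.neighbors[a].discard(b)
            fr.neighbors[b].discard(a)
            fr.neighbors[c].add(d)
            fr.neighbors[d].add(c)
    elif kind == "division":
        m = int(event["mother"])
        child = int(event["child"])
        axis = float(event.get("axis", 0.0))
        offset = float(event.get("offset", 0.25))
        for k, fr in enumerate(out.frames):
            if k < f0:
                continue
            if child in fr.ids:
                raise UnrealizableEvent(f"child id {child} already exists")
            pos = fr.pos_of()
            if m not in pos:
                raise UnrealizableEvent(f"mother {m} absent at frame {k}")
            u = np.array([np.cos(axis), np.sin(axis)])
            pm = pos[m]
            child_pos = pm + offset * u
            mother_pos = pm - offset * u
            idx = int(np.nonzero(fr.ids == m)[0][0])
            fr.positions[idx] = mother_pos
            fr.ids = np.append(fr.ids, child)
            fr.positions = np.vstack([fr.positions, child_pos])
            # split neighbourhood by side of the division plane
            child_n = {m}
            for nb in list(fr.neighbors[m]):
                if np.dot(pos[nb] - pm, u) >= 0:
                    child_n.add(nb)
            fr.neighbors[child] = set(child_n)
            for nb in child_n:
                fr.neighbors[nb].add(child)
            if k == f0:
                fr.tags[child] = f"divided:{m}"
    elif kind == "extrusion":
        c = int(event["cell"])
        pre = out.frames[f0 - 1]
        if c not in set(int(i) for i in pre.ids):
            raise UnrealizableEvent(f"cell {c} absent before extrusion")
        pre.tags[c] = "extruded"
        ring = sorted(pre.neighbors.get(c, set()))
        pos_pre = pre.pos_of()
        center = pos_pre[c]
        ring.sort(key=lambda i: np.arctan2(*(pos_pre[i] - center)[::-1]))
        for fr in out.frames[f0:]:
            keep = fr.ids != c
            fr.positions = fr.positions[keep]
            fr.ids = fr.ids[keep]
            fr.neighbors.pop(c, None)
            for ns in fr.neighbors.values():
                ns.discard(c)
            # close the hole: ring neighbours consecutive around the extruded
            # cell stay in contact, plus a fan from the first ring cell
            for i, j in zip(ring, ring[1:] + ring[:1]):
                if i in fr.neighbors and j in fr.neighbors:
                    fr.neighbors[i].add(j)
                    fr.neighbors[j].add(i)
            for j in ring[2:-1]:
                if ring and ring[0] in fr.neighbors and j in fr.neighbors:
                    fr.neighbors[ring[0]].add(j)
                    fr.neighbors[j].add(ring[0])
    else:
        raise UnrealizableEvent(f"unknown event kind {kind!r}")
    return out
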