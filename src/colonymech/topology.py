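"""T1 neighbour exchanges on the tissue mesh.

An interior edge shorter than the closing threshold is rotated 90 degrees
about its midpoint and reopened at the opening length between the two
previously non-adjacent flanking cells.  Cell identities are preserved, so
the cell count and the Euler characteristic of the cell network are
unchanged by a flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshInvariantError, TissueMesh


@dataclass
class T1Event:
    """Record of one neighbour exchange.

    ``cells`` = (loser_a, loser_b, gainer_c, gainer_d): the first two cells
    shared the collapsing edge, the last two share the new one.
    """

    time: float
    cells: tuple[int, int, int, int]
    pre_endpoints: tuple[tuple[float, float], tuple[float, float]]
    post_endpoints: tuple[tuple[float, float], tuple[float, float]]
    pre_length: float
    vertices: tuple[int, int]


def _loop_find_pair(loop: np.ndarray, a: int, b: int) -> bool:
    """True if b follows a somewhere in the cyclic loop."""
    n = len(loop)
    for i in range(n):
        if loop[i] == a and loop[(i + 1) % n] == b:
            return True
    return False


def _remove_vertex(loop: np.ndarray, v: int) -> np.ndarray:
    return loop[loop != v]


def _insert_after(loop: np.ndarray, anchor: int, v: int) -> np.ndarray:
    i = int(np.nonzero(loop == anchor)[0][0])
    return np.insert(loop, i + 1, v)


def t1_transitions(
    mesh: TissueMesh,
    eps_cls: float,
    eps_opn: float,
    cooldown: int = 10,
    log: list | None = None,
) -> list[T1Event]:
    """Flip every eligible interior edge shorter than ``eps_cls``.

    Candidates are processed in ascending length order; each flip rebuilds
    the adjacency before the next candidate is re-checked.  An edge created
    by a flip is immune from re-flipping for ``cooldown`` calls.  Flips that
    would produce a cell with fewer than 3 vertices, involve non-trijunction
    endpoints, or duplicate an existing contact are skipped (and noted in
    ``log`` when given).
    """
    if not eps_opn > eps_cls:
        raise ValueError("need eps_opn > eps_cls")
    events: list[T1Event] = []

    # age the cooldown ledger once per call
    expired = []
    for key in mesh.t1_cooldown:
        mesh.t1_cooldown[key] -= 1
        if mesh.t1_cooldown[key] <= 0:
            expired.append(key)
    for key in expired:
        del mesh.t1_cooldown[key]

    for _ in range(10 * mesh.n_cells):  # safety bound
        e = mesh.edges
        lengths = mesh.edge_lengths()
        cand = np.nonzero(e.interior & (lengths < eps_cls))[0]
        cand = [i for i in cand if e.key(int(i)) not in mesh.t1_cooldown]
        if not cand:
            break
        i = min(cand, key=lambda j: lengths[j])
        ok = _flip_edge(mesh, int(i), eps_opn, max(cooldown, 1), events, log)
        if not ok:
            # mark so we do not retry this edge within this call
            mesh.t1_cooldown[e.key(int(i))] = 1
    return events


def _flip_edge(
    mesh: TissueMesh,
    edge_idx: int,
    eps_opn: float,
    cooldown: int,
    events: list,
    log: list | None,
) -> bool:
    e = mesh.edges
    v1, v2 = int(e.v1[edge_idx]), int(e.v2[edge_idx])
    ca, cb = int(e.c1[edge_idx]), int(e.c2[edge_idx])
    if cb < 0:
        _note(log, f"edge ({v1},{v2}) is boundary; no flip")
        return False

    vcells = mesh.vertex_cells()
    cells_v1, cells_v2 = set(vcells[v1]), set(vcells[v2])
    b1 = bool(mesh.boundary_vertices[v1])
    b2 = bool(mesh.boundary_vertices[v2])
    if b1 or b2:
        # interior edge ending on the colony boundary: the outside plays the
        # role of the fourth cell in the exchange
        return _flip_boundary_edge(
            mesh, v1, v2, ca, cb, b1, b2, vcells, eps_opn, cooldown, events, log
        )
    if len(cells_v1) != 3 or len(cells_v2) != 3:
        _note(log, f"edge ({v1},{v2}) endpoints are not trijunctions; skipped")
        return False
    third_a = cells_v1 - {ca, cb}
    third_b = cells_v2 - {ca, cb}
    if len(third_a) != 1 or len(third_b) != 1:
        _note(log, f"edge ({v1},{v2}) lacks 4 distinct cells; skipped")
        return False
    cg, cd = third_a.pop(), third_b.pop()
    if cg == cd:
        _note(log, f"edge ({v1},{v2}) flanked by a single cell; skipped")
        return False
    if cd in mesh.cell_neighbors()[cg]:
        _note(log, f"flip of ({v1},{v2}) would duplicate contact {cg}-{cd}; skipped")
        return False

    # orient: alpha = cell traversing v2 -> v1, beta = cell traversing v1 -> v2
    if _loop_find_pair(mesh.cells[ca], v2, v1):
        alpha, beta = ca, cb
    elif _loop_find_pair(mesh.cells[cb], v2, v1):
        alpha, beta = cb, ca
    else:  # inconsistent orientation
        _note(log, f"edge ({v1},{v2}) with inconsistent loop orientation; skipped")
        return False
    # relabel endpoints: a is the endpoint alpha keeps
    a, b = v1, v2
    # gamma = third cell at a, delta = third cell at b
    gamma = (set(vcells[a]) - {alpha, beta}).pop()
    delta = (set(vcells[b]) - {alpha, beta}).pop()

    if len(mesh.cells[alpha]) < 4 or len(mesh.cells[beta]) < 4:
        _note(log, f"flip of ({a},{b}) would create a <3-vertex cell; skipped")
        return False

    xa, xb = mesh.vertices[a].copy(), mesh.vertices[b].copy()
    mid = 0.5 * (xa + xb)
    d = xb - xa
    pre_len = float(np.linalg.norm(d))
    if pre_len == 0:
        u = np.array([1.0, 0.0])
    else:
        u = np.array([-d[1], d[0]]) / pre_len  # 90-degree rotation
    # a ends up on alpha's side
    c_alpha = mesh.cell_centroids()[alpha]
    if np.dot(u, c_alpha - mid) < 0:
        u = -u
    new_a = mid + 0.5 * eps_opn * u
    new_b = mid - 0.5 * eps_opn * u

    # topology surgery
    loops = mesh.cells
    new_alpha = _remove_vertex(loops[alpha], b)
    new_beta = _remove_vertex(loops[beta], a)
    new_gamma = _insert_after(loops[gamma], a, b)
    new_delta = _insert_after(loops[delta], b, a)

    loops[alpha] = new_alpha
    loops[beta] = new_beta
    loops[gamma] = new_gamma
    loops[delta] = new_delta
    mesh.vertices[a] = new_a
    mesh.vertices[b] = new_b
    mesh.invalidate(topology=True)

    # sanity: all four touched cells must keep positive area, else revert
    A = mesh.cell_areas()
    if min(A[alpha], A[beta], A[gamma], A[delta]) <= 0:
        loops[alpha] = _insert_after(new_alpha, a, b)
        loops[beta] = _insert_after(new_beta, b, a)
        loops[gamma] = _remove_vertex(new_gamma, b)
        loops[delta] = _remove_vertex(new_delta, a)
        mesh.vertices[a] = xa
        mesh.vertices[b] = xb
        mesh.invalidate(topology=True)
        _note(log, f"flip of ({a},{b}) inverted a cell; reverted")
        return False

    key = (a, b) if a < b else (b, a)
    mesh.t1_cooldown[key] = cooldown
    events.append(
        T1Event(
            time=mesh.time,
            cells=(alpha, beta, gamma, delta),
            pre_endpoints=(tuple(xa), tuple(xb)),
            post_endpoints=(tuple(new_a), tuple(new_b)),
            pre_length=pre_len,
            vertices=(a, b),
        )
    )
    return True


def _flip_boundary_edge(
    mesh: TissueMesh,
    v1: int,
    v2: int,
    ca: int,
    cb: int,
    b1: bool,
    b2: bool,
    vcells,
    eps_opn: float,
    cooldown: int,
    events: list,
    log: list | None,
) -> bool:
    """Neighbour exchange for an interior edge with one boundary endpoint.

    The two cells sharing the collapsing edge separate and the interior
    flanking cell reaches the colony boundary; the new edge becomes a
    boundary edge of that cell (the outside acts as the fourth cell).
    """
    if b1 and b2:
        _note(log, f"edge ({v1},{v2}) spans the boundary twice; skipped")
        return False
    vb, vi = (v1, v2) if b1 else (v2, v1)  # vb on the boundary, vi interior
    if len(set(vcells[vb])) != 2 or len(set(vcells[vi])) != 3:
        _note(log, f"edge ({v1},{v2}) has non-standard valence; skipped")
        return False
    delta = (set(vcells[vi]) - {ca, cb}).pop()
    if delta in (ca, cb):
        return False
    if len(mesh.cells[ca]) < 4 or len(mesh.cells[cb]) < 4:
        _note(log, f"boundary flip of ({vb},{vi}) would create a <3-vertex cell; skipped")
        return False

    # orient: alpha traverses vi -> vb (keeps vb ... recheck below)
    if _loop_find_pair(mesh.cells[ca], vi, vb):
        alpha, beta = ca, cb
    elif _loop_find_pair(mesh.cells[cb], vi, vb):
        alpha, beta = cb, ca
    else:
        _note(log, f"edge ({vb},{vi}) with inconsistent loop orientation; skipped")
        return False
    # treat (a, b) = (vb, vi): alpha traverses b -> a, keeps a = vb
    a, b = vb, vi

    xa, xb = mesh.vertices[a].copy(), mesh.vertices[b].copy()
    mid = 0.5 * (xa + xb)
    d = xb - xa
    pre_len = float(np.linalg.norm(d))
    u = np.array([-d[1], d[0]]) / pre_len if pre_len > 0 else np.array([1.0, 0.0])
    c_alpha = mesh.cell_centroids()[alpha]
    if np.dot(u, c_alpha - mid) < 0:
        u = -u
    loops = mesh.cells
    new_alpha = _remove_vertex(loops[alpha], b)
    new_beta = _remove_vertex(loops[beta], a)
    new_delta = _insert_after(loops[delta], b, a)
    loops[alpha] = new_alpha
    loops[beta] = new_beta
    loops[delta] = new_delta
    mesh.vertices[a] = mid + 0.5 * eps_opn * u
    mesh.vertices[b] = mid - 0.5 * eps_opn * u
    mesh.invalidate(topology=True)

    A = mesh.cell_areas()
    if min(A[alpha], A[beta], A[delta]) <= 0:
        loops[alpha] = _insert_after(new_alpha, a, b)
        loops[beta] = _insert_after(new_beta, b, a)
        loops[delta] = _remove_vertex(new_delta, a)
        mesh.vertices[a] = xa
        mesh.vertices[b] = xb
        mesh.invalidate(topology=True)
        _note(log, f"boundary flip of ({a},{b}) inverted a cell; reverted")
        return False

    key = (a, b) if a < b else (b, a)
    mesh.t1_cooldown[key] = cooldown
    events.append(
        T1Event(
            time=mesh.time,
            cells=(alpha, beta, delta, -1),
            pre_endpoints=(tuple(xa), tuple(xb)),
            post_endpoints=(tuple(mesh.vertices[a]), tuple(mesh.vertices[b])),
            pre_length=pre_len,
            vertices=(a, b),
        )
    )
    return True


def _collapse_edge(mesh: TissueMesh, vk: int, vd: int, log: list | None) -> list | None:
    """Merge vertex ``vd`` into ``vk`` at their midpoint.

    Any cell reduced below 3 vertices by the merge (a 2-gon pinched between
    its neighbours) is removed.  Returns the list of removed cell ids, or
    None if the merge would pinch a loop (a cell containing both endpoints
    non-consecutively).
    """
    for loop in mesh.cells:
        sl = set(map(int, loop))
        if vk in sl and vd in sl:
            n = len(loop)
            pos_k = int(np.nonzero(loop == vk)[0][0])
            if int(loop[(pos_k + 1) % n]) != vd and int(loop[(pos_k - 1) % n]) != vd:
                _note(log, f"collapse of ({vk},{vd}) would pinch a loop; skipped")
                return None
    mid = 0.5 * (mesh.vertices[vk] + mesh.vertices[vd])
    removed = []
    for ci, loop in enumerate(mesh.cells):
        if vd not in loop and vk not in loop:
            continue
        new = [vk if int(v) == vd else int(v) for v in loop]
        dedup: list[int] = []
        for v in new:
            if not dedup or dedup[-1] != v:
                dedup.append(v)
        while len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        if len(dedup) < 3:
            removed.append(ci)
            dedup = []
        mesh.cells[ci] = np.array(dedup, dtype=np.int64)
    mesh.vertices[vk] = mid
    mesh.invalidate(topology=True)
    return removed


def collapse_short_boundary_edges(
    mesh: TissueMesh, eps_cls: float, log: list | None = None
) -> list["T2Event"]:
    """Merge the endpoints of boundary edges shorter than ``eps_cls``.

    A collapsing boundary edge means the colony border is pinching; cells
    squeezed to 2-gons by the merge are removed and reported as T2 events.
    Interior short edges are the T1 machinery's business.
    """
    events: list[T2Event] = []
    skipped: set = set()
    for _ in range(4 * mesh.n_vertices):
        e = mesh.edges
        lengths = mesh.edge_lengths()
        cand = [
            i
            for i in np.nonzero((e.c2 < 0) & (lengths < eps_cls))[0]
            if e.key(int(i)) not in skipped
        ]
        if not cand:
            break
        i = int(min(cand, key=lambda j: lengths[j]))
        vk, vd = int(e.v1[i]), int(e.v2[i])
        areas_before = mesh.cell_areas()
        removed = _collapse_edge(mesh, vk, vd, log)
        if removed is None:
            skipped.add(e.key(i))
            continue
        pos = tuple(mesh.vertices[vk])
        for ci in removed:
            events.append(
                T2Event(time=mesh.time, cell=ci, area=float(areas_before[ci]), position=pos)
            )
            _note(log, f"cell {ci} pinched off the boundary; removed")
    return events


@dataclass
class T2Event:
    """Removal (extrusion) of a cell crushed below the area threshold."""

    time: float
    cell: int
    area: float
    position: tuple[float, float]


def t2_transitions(
    mesh: TissueMesh, area_threshold: float, log: list | None = None
) -> list[T2Event]:
    """Collapse cells whose area fell below ``area_threshold`` to a point.

    A crushed cell (typically a 3-4 sided sliver whose remaining T1s are
    topologically blocked) is removed: all its vertices merge into one at
    its centroid, neighbouring loops are rewired, and the cell id is
    retired (empty loop), mimicking an extrusion.  Events are logged so the
    exported tracking tags them for the shear decomposition.
    """
    events: list[T2Event] = []
    skipped: set[int] = set()
    for _ in range(mesh.n_cells):
        A = mesh.cell_areas()
        alive = mesh.alive
        cand = [
            int(c)
            for c in np.nonzero(alive & (A < area_threshold))[0]
            if int(c) not in skipped
        ]
        if not cand:
            break
        c = min(cand, key=lambda i: A[i])
        if not _collapse_cell(mesh, c, events, log):
            skipped.add(c)
    return events


def _collapse_cell(mesh: TissueMesh, c: int, events: list, log: list | None) -> bool:
    """Remove a crushed cell by collapsing its shortest edges in turn."""
    area = float(mesh.cell_areas()[c])
    for _ in range(len(mesh.cells[c]) + 1):
        loop = mesh.cells[c]
        if len(loop) == 0:
            return True
        pts = mesh.vertices[loop]
        lens = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        order = np.argsort(lens)
        removed = None
        for j in order:
            vk, vd = int(loop[j]), int(loop[(j + 1) % len(loop)])
            removed = _collapse_edge(mesh, vk, vd, log)
            if removed is not None:
                break
        if removed is None:
            _note(log, f"T2 of cell {c}: no collapsible edge; deferred")
            return False
        for ci in removed:
            events.append(
                T2Event(
                    time=mesh.time,
                    cell=ci,
                    area=area if ci == c else float("nan"),
                    position=tuple(mesh.vertices[vk]),
                )
            )
        if c in removed:
            return True
    return len(mesh.cells[c]) == 0


def _note(log: list | None, msg: str) -> None:
    if log is not None:
        log.append(msg)
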