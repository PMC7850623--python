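import numpy as np
import pytest
from scipy.linalg import logm, polar

from colonymech.fixtures import (
    affine_series,
    hexagonal_patch,
    rotated_series,
    scripted_events,
)
from colonymech.kinematics import (
    CHANNELS,
    DegenerateTriangleError,
    EllipseFit,
    Frame,
    TrackedFrames,
    decompose_shear,
    fit_ellipse,
    mean_cell_speed,
    project_xx,
    shape_Q,
    sym_traceless_log_F,
    triangle_elongation,
    triangulate_frames,
)


def disc_mask(n=256, rr=0.45, aspect=1.0, angle=0.0):
    y, x = np.mgrid[0:n, 0:n].astype(float)
    cx = cy = n / 2
    ca, sa = np.cos(angle), np.sin(angle)
    u = (x - cx) * ca + (y - cy) * sa
    v = -(x - cx) * sa + (y - cy) * ca
    return (u / (rr * n * aspect)) ** 2 + (v / (rr * n / aspect)) ** 2 <= 1.0


class TestEllipse:
    def test_disc_is_isotropic(self):
        fit = fit_ellipse(disc_mask())
        assert fit.aspect == pytest.approx(1.0, abs=0.01)
        qxx, qxy = shape_Q(fit, 0.0)
        assert abs(qxx) < 0.01 and abs(qxy) < 0.01

    def test_two_to_one_ellipse_recovered(self):
        fit = fit_ellipse(disc_mask(n=400, rr=0.3, aspect=np.sqrt(2)))
        assert np.log(fit.aspect) == pytest.approx(np.log(2.0), rel=0.01)
        assert fit.theta == pytest.approx(0.0, abs=0.01)

    def test_rotation_equivariance(self):
        a40 = np.radians(40)
        fit = fit_ellipse(disc_mask(n=400, rr=0.3, aspect=np.sqrt(2), angle=a40))
        assert np.degrees(fit.theta) == pytest.approx(40.0, abs=0.5)

    def test_polygon_input(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        poly = np.stack([2.0 * np.cos(t), 1.0 * np.sin(t)], axis=1)
        fit = fit_ellipse(poly)
        assert fit.aspect == pytest.approx(2.0, rel=1e-4)
        assert fit.a == pytest.approx(2.0, rel=1e-4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((10, 10), dtype=bool))


class TestShapeQ:
    def test_isotropic_gives_zero(self):
        fit = EllipseFit(a=1.0, b=1.0, theta=0.0, centroid=(0, 0))
        assert shape_Q(fit, 0.3) == (0.0, 0.0)

    def test_aligned_closed_form(self):
        fit = EllipseFit(a=2.0, b=1.0, theta=0.5, centroid=(0, 0))
        qxx, qxy = shape_Q(fit, 0.5)
        assert qxx == pytest.approx(0.5 * np.log(2))
        assert qxy == pytest.approx(0.0, abs=1e-15)

    def test_forty_five_degrees(self):
        fit = EllipseFit(a=2.0, b=1.0, theta=np.pi / 4, centroid=(0, 0))
        qxx, qxy = shape_Q(fit, 0.0)
        assert qxx == pytest.approx(0.0, abs=1e-15)
        assert qxy == pytest.approx(0.5 * np.log(2))


class TestMeanCellSpeed:
    def test_stationary_and_uniform(self):
        assert mean_cell_speed(np.zeros((5, 2)), dt=1.0) == 0.0
        traj = np.stack([np.arange(6) * 0.7, np.zeros(6)], axis=1)
        assert mean_cell_speed(traj, dt=1.0) == pytest.approx(0.7)

    def test_known_random_walk(self):
        rng = np.random.default_rng(5)
        steps = rng.normal(size=(100, 2))
        steps = 0.3 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        traj = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        assert mean_cell_speed(traj, dt=0.5) == pytest.approx(0.3 / 0.5)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            mean_cell_speed(np.zeros((1, 2)), dt=1.0)


class TestTriangulation:
    def test_hexagonal_center_has_six_triangles(self):
        frame = hexagonal_patch(n_rings=1)
        frames = TrackedFrames(times=np.array([0.0]), frames=[frame])
        tris = triangulate_frames(frames)[0]
        # the 7-cell patch triangulates into 6 triangles around the center
        assert len(tris) == 6
        center = 0  # id 0 is the central cell by construction
        pos = frame.pos_of()
        center_id = min(pos, key=lambda i: np.linalg.norm(pos[i]))
        assert sum(center_id in t for t in tris) == 6

    def test_no_topology_change_same_triangles(self):
        frames = affine_series(hexagonal_patch(2), 0.2, 4)
        t = triangulate_frames(frames)
        assert t[0] == t[1] == t[3]

    def test_scripted_t1_changes_only_incident_triangles(self):
        base = affine_series(hexagonal_patch(2), 0.0, 3)
        pos = base.frames[0].pos_of()
        # choose an interior contact with two flankers
        ids = sorted(pos)
        a, b, flank = None, None, None
        for i in ids:
            for j in base.frames[0].neighbors[i]:
                common = base.frames[0].neighbors[i] & base.frames[0].neighbors[j]
                if j > i and len(common) >= 2:
                    a, b = i, j
                    flank = sorted(common)[:2]
                    break
            if a is not None:
                break
        ev = {"kind": "t1", "frame": 1, "lose": (a, b), "gain": tuple(flank)}
        frames = scripted_events(base, ev)
        t = triangulate_frames(frames)
        changed = set(t[0]) ^ set(t[1])
        assert changed  # something changed
        for tri in changed:
            assert {a, b} & set(tri) or set(flank) & set(tri)


class TestTriangleElongation:
    def equilateral(self, size=1.0, angle=0.0, center=(0, 0)):
        ang = angle + np.array([0, 2 * np.pi / 3, 4 * np.pi / 3])
        return np.array(center) + size * np.stack([np.cos(ang), np.sin(ang)], axis=1)

    @pytest.mark.parametrize("size,angle", [(1.0, 0.0), (3.3, 0.7)])
    def test_equilateral_is_zero(self, size, angle):
        q = triangle_elongation(self.equilateral(size, angle))
        assert np.allclose(q, 0.0, atol=1e-12)

    def test_pure_stretch_closed_form(self):
        s = 0.37
        pts = self.equilateral() @ np.diag([np.exp(s), np.exp(-s)])
        qxx, qxy = triangle_elongation(pts)
        assert qxx == pytest.approx(s, abs=1e-12)
        assert qxy == pytest.approx(0.0, abs=1e-12)

    def test_labeling_invariance(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.3], [0.7, 1.8]])
        q0 = triangle_elongation(pts)
        for perm in [(1, 2, 0), (2, 1, 0), (0, 2, 1)]:
            assert np.allclose(triangle_elongation(pts[list(perm)]), q0, atol=1e-12)

    def test_rotation_equivariance(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.3], [0.7, 1.8]])
        a = 0.6
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        q0 = triangle_elongation(pts)
        q1 = triangle_elongation(pts @ R.T)
        m0, t0 = np.hypot(*q0), 0.5 * np.arctan2(q0[1], q0[0])
        m1, t1 = np.hypot(*q1), 0.5 * np.arctan2(q1[1], q1[0])
        assert m1 == pytest.approx(m0, abs=1e-12)
        d = (t1 - t0 - a) % np.pi
        assert min(d, np.pi - d) == pytest.approx(0.0, abs=1e-10)

    def test_matches_polar_decomposition_oracle(self):
        # independent route: map from an equal-area equilateral reference,
        # polar-decompose F = R U; the gyration-based q equals R log(U) R^T
        rng = np.random.default_rng(3)
        for _ in range(10):
            pts = rng.normal(size=(3, 2)) * 2
            d = np.stack([pts[1] - pts[0], pts[2] - pts[0]], axis=1)
            if np.linalg.det(d) < 0.1:
                continue
            area = 0.5 * abs(np.linalg.det(d))
            ref = self.equilateral(np.sqrt(4 * area / (3 * np.sqrt(3))))
            ref -= ref.mean(axis=0)
            cur = pts - pts.mean(axis=0)
            D0 = np.stack([ref[1] - ref[0], ref[2] - ref[0]], axis=1)
            D1 = np.stack([cur[1] - cur[0], cur[2] - cur[0]], axis=1)
            F = D1 @ np.linalg.inv(D0)
            Rm, U = polar(F / np.sqrt(abs(np.linalg.det(F))))
            L = Rm @ logm(U) @ Rm.T
            q_oracle = (0.5 * (L[0, 0] - L[1, 1]), 0.5 * (L[0, 1] + L[1, 0]))
            q = triangle_elongation(pts)
            assert np.allclose(q, q_oracle, atol=1e-10)

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateTriangleError):
            triangle_elongation(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))


class TestLogF:
    def test_matches_scipy_logm(self):
        rng = np.random.default_rng(7)
        ref = np.array([[0.0, 0.0], [1.0, 0.1], [0.4, 1.2]])
        for _ in range(20):
            M = np.eye(2) + 0.6 * rng.normal(size=(2, 2))
            if np.linalg.det(M) <= 0.05:
                continue
            cur = ref @ M.T
            got = sym_traceless_log_F(ref, cur)
            L = logm(M)
            want = (0.5 * (L[0, 0] - L[1, 1]).real, 0.5 * (L[0, 1] + L[1, 0]).real)
            assert np.allclose(got, want, atol=1e-10)


class TestDecomposeShear:
    def test_identical_frames_all_zero(self):
        frames = affine_series(hexagonal_patch(2), 0.0, 4)
        dec = decompose_shear(frames)
        for ch in CHANNELS:
            assert np.allclose(dec.per_interval[f"{ch}_xx"], 0.0, atol=1e-14)
            assert np.allclose(dec.per_interval[f"{ch}_xy"], 0.0, atol=1e-14)

    @pytest.mark.parametrize("s", [0.3, -0.25])
    def test_affine_exactness(self, s):
        frames = affine_series(hexagonal_patch(2), s, 6)
        dec = decompose_shear(frames)
        assert dec.cumulative["total_xx"].iloc[-1] == pytest.approx(s, abs=1e-8)
        assert dec.cumulative["total_xy"].iloc[-1] == pytest.approx(0.0, abs=1e-8)
        for ch in ("t1", "division", "extrusion"):
            assert np.allclose(dec.per_interval[f"{ch}_xx"], 0.0, atol=1e-12)

    def test_rigid_rotation_objectivity(self):
        frames = rotated_series(hexagonal_patch(2), np.radians(60), 8)
        dec = decompose_shear(frames)
        for ch in CHANNELS:
            assert np.allclose(dec.per_interval[f"{ch}_xx"], 0.0, atol=1e-10)
            assert np.allclose(dec.per_interval[f"{ch}_xy"], 0.0, atol=1e-10)

    def test_additivity_closure(self):
        # on an arbitrary noisy trajectory the five contributions must sum
        # to the total per interval by construction
        rng = np.random.default_rng(1)
        base = hexagonal_patch(2)
        frames = []
        for k in range(5):
            f = Frame(
                ids=base.ids.copy(),
                positions=base.positions + 0.08 * rng.normal(size=base.positions.shape),
                neighbors={i: set(ns) for i, ns in base.neighbors.items()},
            )
            frames.append(f)
        tf = TrackedFrames(times=np.arange(5.0), frames=frames)
        dec = decompose_shear(tf)
        for comp in ("xx", "xy"):
            total = dec.per_interval[f"total_{comp}"]
            parts = sum(
                dec.per_interval[f"{ch}_{comp}"]
                for ch in ("elongation", "t1", "division", "extrusion", "correlation")
            )
            assert np.allclose(total, parts, atol=1e-8)

    def test_project_xx(self):
        assert project_xx(1.0, 0.0, 0.0) == 1.0
        assert project_xx(1.0, 0.0, np.pi / 2) == pytest.approx(-1.0)
        assert project_xx(0.0, 1.0, np.pi / 4) == pytest.approx(1.0)


class TestEventAttribution:
    def make_base(self, n_frames=5):
        return affine_series(hexagonal_patch(2), 0.0, n_frames)

    def find_t1_spec(self, base):
        f = base.frames[0]
        for i in sorted(f.neighbors):
            for j in sorted(f.neighbors[i]):
                if j <= i:
                    continue
                common = f.neighbors[i] & f.neighbors[j]
                if len(common) >= 2:
                    flank = sorted(common)[:2]
                    return {"kind": "t1", "frame": 2, "lose": (i, j), "gain": tuple(flank)}
        raise AssertionError("no T1 site found")

    def test_t1_lands_in_t1_channel_only(self):
        base = self.make_base()
        frames = scripted_events(base, self.find_t1_spec(base))
        dec = decompose_shear(frames)
        mag = lambda ch: np.hypot(
            dec.per_interval[f"{ch}_xx"], dec.per_interval[f"{ch}_xy"]
        ).max()
        assert mag("t1") > 1e-6
        assert mag("division") == 0.0
        assert mag("extrusion") == 0.0

    def test_division_lands_in_division_channel_only(self):
        base = self.make_base()
        f = base.frames[0]
        pos = f.pos_of()
        mother = min(pos, key=lambda i: np.linalg.norm(pos[i]))  # central cell
        ev = {"kind": "division", "frame": 2, "mother": int(mother), "child": 999}
        frames = scripted_events(base, ev)
        dec = decompose_shear(frames)
        mag = lambda ch: np.hypot(
            dec.per_interval[f"{ch}_xx"], dec.per_interval[f"{ch}_xy"]
        ).max()
        assert mag("division") > 1e-6
        assert mag("t1") == 0.0
        assert mag("extrusion") == 0.0

    def test_extrusion_lands_in_extrusion_channel_only(self):
        base = self.make_base()
        f = base.frames[0]
        pos = f.pos_of()
        cell = min(pos, key=lambda i: np.linalg.norm(pos[i]))
        ev = {"kind": "extrusion", "frame": 2, "cell": int(cell)}
        frames = scripted_events(base, ev)
        dec = decompose_shear(frames)
        mag = lambda ch: np.hypot(
            dec.per_interval[f"{ch}_xx"], dec.per_interval[f"{ch}_xy"]
        ).max()
        assert mag("extrusion") > 1e-6
        assert mag("t1") == 0.0
        assert mag("division") == 0.0

    def test_empty_event_is_identity(self):
        base = self.make_base()
        dec0 = decompose_shear(base)
        dec1 = decompose_shear(scripted_events(base, None))
        assert np.allclose(
            dec0.per_interval.to_numpy(), dec1.per_interval.to_numpy(), atol=1e-14
        )
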