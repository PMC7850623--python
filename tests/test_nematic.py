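import numpy as np
import pytest

from colonymech.fixtures import stripe_texture
from colonymech.nematic import (
    DefectSet,
    OrientationGrid,
    SingularPointError,
    defect_field,
    defect_field_grid,
    delta_theta_cdf,
    detect_defects,
    fit_alpha,
    fold_nematic_difference,
    mean_nematic_angle,
    orientation_field,
)


def nematic_diff(a, b):
    d = np.abs(a - b) % np.pi
    return np.minimum(d, np.pi - d)


class TestOrientationField:
    @pytest.mark.parametrize("angle_deg", [0.0, 30.0, 90.0, 121.0])
    def test_stripes_recovered(self, angle_deg):
        img = stripe_texture([], [], np.radians(angle_deg), size=256, wavelength=16)
        grid = orientation_field(img, smoothing_window=20, grid_spacing=20)
        inner = grid.phi[1:-1, 1:-1]
        err = np.degrees(nematic_diff(inner, np.radians(angle_deg)))
        assert np.median(err) < 1.0
        assert np.median(grid.coherence[1:-1, 1:-1]) > 0.9

    def test_rotating_stripes_by_90_shifts_phi(self):
        a = orientation_field(stripe_texture([], [], 0.0, 256, 16), 20, 20)
        b = orientation_field(stripe_texture([], [], np.pi / 2, 256, 16), 20, 20)
        d = nematic_diff(a.phi[1:-1, 1:-1], b.phi[1:-1, 1:-1] - np.pi / 2)
        assert np.median(np.degrees(d)) < 1.0

    def test_white_noise_has_low_coherence(self):
        vals = []
        for seed in range(3):
            img = np.random.default_rng(seed).standard_normal((256, 256))
            grid = orientation_field(img, smoothing_window=40, grid_spacing=20)
            vals.append(np.mean(grid.coherence))
        assert np.mean(vals) < 0.1

    def test_constant_image_flagged_not_nan(self):
        grid = orientation_field(np.full((128, 128), 3.7), 20, 20)
        assert np.all(np.isfinite(grid.phi))
        assert np.all(grid.coherence == 0.0)

    def test_image_too_small_rejected(self):
        with pytest.raises(ValueError):
            orientation_field(np.zeros((30, 200)), smoothing_window=20)


class TestDefectField:
    def test_no_defects_is_constant(self):
        pts = np.random.default_rng(0).uniform(-5, 5, (40, 2))
        phi = defect_field([], [], 0.8, pts)
        assert np.allclose(phi, 0.8)

    def test_single_plus_half_closed_form(self):
        # k=+1/2 at origin, alpha=0: phi = atan2(y,x)/2 mod pi
        phi = defect_field([0.5], [(0.0, 0.0)], 0.0, np.array([[0.0, 1.0]]))
        assert phi[0] == pytest.approx(np.pi / 4)
        phi = defect_field([0.5], [(0.0, 0.0)], 0.0, np.array([[1.0, 0.0]]))
        assert phi[0] == pytest.approx(0.0)

    def test_singular_evaluation_raises(self):
        with pytest.raises(SingularPointError):
            defect_field([0.5], [(1.0, 2.0)], 0.0, np.array([[1.0, 2.0]]))

    def test_pair_has_zero_far_winding(self):
        charges, pos = [0.5, -0.5], [(-1.0, 0.0), (1.0, 0.0)]
        t = np.linspace(0, 2 * np.pi, 721)[:-1]
        loop = 20 * np.stack([np.cos(t), np.sin(t)], axis=1)
        phi = defect_field(charges, pos, 0.0, loop)
        d = np.diff(np.concatenate([phi, phi[:1]]))
        wrapped = -((np.pi / 2 - d) % np.pi - np.pi / 2)
        assert abs(wrapped.sum() / (2 * np.pi)) < 1e-9


class TestDetectDefects:
    def test_uniform_field_empty(self):
        grid = OrientationGrid(
            x=np.arange(10.0), y=np.arange(10.0),
            phi=np.full((10, 10), 0.7), coherence=np.ones((10, 10)),
        )
        assert len(detect_defects(grid)) == 0

    @pytest.mark.parametrize("charge", [0.5, -0.5])
    def test_single_planted_defect(self, charge):
        x = np.arange(0, 200, 10.0)
        grid = defect_field_grid([charge], [(95.0, 95.0)], 0.3, x, x)
        found = detect_defects(grid)
        assert len(found) == 1
        assert found.charges[0] == pytest.approx(charge)
        assert np.allclose(found.positions[0], [95, 95], atol=10.0)

    def test_random_defect_sets_recovered(self):
        # forward-generate then detect, 20 seeded instances
        x = np.arange(0, 300, 10.0)
        hits = 0
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = rng.integers(1, 4)
            for _ in range(40):
                pos = rng.uniform(40, 260, (n, 2))
                if n == 1 or np.min(
                    np.linalg.norm(pos[None] - pos[:, None], axis=-1)[
                        ~np.eye(n, dtype=bool)
                    ]
                ) > 35:
                    break
            charges = rng.choice([-0.5, 0.5], n)
            grid = defect_field_grid(charges, pos + 0.5, rng.uniform(0, np.pi), x, x)
            found = detect_defects(grid)
            total += n
            for k, p in zip(charges, pos):
                match = [
                    i
                    for i in range(len(found))
                    if found.charges[i] == k
                    and np.linalg.norm(found.positions[i] - (p + 0.5)) <= 10 * np.sqrt(2)
                ]
                hits += bool(match)
            assert len(found) == n
        assert hits == total

    def test_masked_plaquettes_skipped(self):
        x = np.arange(0, 200, 10.0)
        mask = np.ones((20, 20), dtype=bool)
        mask[8:12, 8:12] = False  # hide the defect core region
        grid = defect_field_grid([0.5], [(95.0, 95.0)], 0.0, x, x, mask=mask)
        assert len(detect_defects(grid)) == 0


class TestFitAlpha:
    def test_self_consistency_recovers_alpha(self):
        x = np.arange(0, 300, 15.0)
        charges, pos = [0.5, -0.5, 0.5], [(61.5, 70.5), (150.5, 220.5), (237.5, 91.5)]
        grid = defect_field_grid(charges, pos, 0.7, x, x)
        defects = DefectSet(np.array(charges), np.array(pos, dtype=float))
        alpha, resid = fit_alpha(grid, defects)
        assert alpha == pytest.approx(0.7, abs=1e-10)
        assert resid < 1e-12

    def test_matches_bruteforce_grid_search(self):
        rng = np.random.default_rng(42)
        x = np.arange(0, 200, 20.0)
        charges = [0.5, -0.5]
        pos = [(55.0, 66.0), (141.0, 119.0)]
        grid = defect_field_grid(charges, pos, 1.234, x, x)
        grid.phi += rng.normal(0, 0.2, grid.phi.shape)  # noisy observations
        grid.phi %= np.pi
        grid.coherence = rng.uniform(0.2, 1.0, grid.phi.shape)
        defects = DefectSet(np.array(charges), np.array(pos))
        alpha, _ = fit_alpha(grid, defects)
        base = defect_field(charges, pos, 0.0, np.stack(np.meshgrid(x, x)[::1], axis=-1).reshape(-1, 2))
        X, Y = np.meshgrid(x, x)
        base = defect_field(charges, pos, 0.0, np.stack([X.ravel(), Y.ravel()], axis=1))
        trial = np.arange(0, np.pi, 1e-4)
        psi = (grid.phi.ravel() - base)[None, :]
        cost = np.sum(
            grid.coherence.ravel()[None, :] * (1 - np.cos(2 * (psi - trial[:, None]))),
            axis=1,
        )
        best = trial[np.argmin(cost)]
        assert nematic_diff(alpha, best) < 2e-4

    def test_invariant_under_phi_plus_pi(self):
        x = np.arange(0, 200, 20.0)
        grid = defect_field_grid([0.5], [(95.0, 95.0)], 0.5, x, x)
        defects = DefectSet(np.array([0.5]), np.array([[95.0, 95.0]]))
        a0, _ = fit_alpha(grid, defects)
        grid.phi = (grid.phi + np.pi) % np.pi
        a1, _ = fit_alpha(grid, defects)
        assert a0 == pytest.approx(a1, abs=1e-12)


class TestMeanNematic:
    def test_uniform_field(self):
        grid = OrientationGrid(
            x=np.arange(5.0), y=np.arange(5.0),
            phi=np.full((5, 5), 1.1), coherence=np.ones((5, 5)),
        )
        theta, mag = mean_nematic_angle(grid)
        assert theta == pytest.approx(1.1)
        assert mag == pytest.approx(1.0)

    def test_orthogonal_populations_cancel(self):
        phi = np.zeros((4, 4))
        phi[:, 2:] = np.pi / 2
        grid = OrientationGrid(np.arange(4.0), np.arange(4.0), phi, np.ones((4, 4)))
        theta, mag = mean_nematic_angle(grid)
        assert mag == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(theta)

    def test_matches_bruteforce_tensor_average(self):
        x = np.arange(0, 200, 10.0)
        grid = defect_field_grid([0.5], [(95.0, 95.0)], 0.2, x, x)
        X, Y = np.meshgrid(grid.x, grid.y)
        mask = (X - 100) ** 2 + (Y - 100) ** 2 < 90**2
        theta, mag = mean_nematic_angle(grid, mask)
        c = np.mean(np.cos(2 * grid.phi[mask]))
        s = np.mean(np.sin(2 * grid.phi[mask]))
        assert theta == pytest.approx(0.5 * np.arctan2(s, c) % np.pi, abs=1e-12)
        assert mag == pytest.approx(np.hypot(c, s), abs=1e-12)

    def test_empty_mask_rejected(self):
        grid = OrientationGrid(
            np.arange(3.0), np.arange(3.0), np.zeros((3, 3)), np.ones((3, 3))
        )
        with pytest.raises(ValueError):
            mean_nematic_angle(grid, np.zeros((3, 3), dtype=bool))


class TestDeltaThetaCdf:
    def test_point_mass_at_zero(self):
        out = delta_theta_cdf(np.zeros(5))
        assert np.all(out["ecdf"] == np.arange(1, 6) / 5)
        assert np.all(out["values"] == 0)

    def test_single_value(self):
        out = delta_theta_cdf([np.pi / 4])
        assert out["values"][0] == pytest.approx(np.pi / 4)
        assert out["ecdf"][0] == 1.0
        assert out["null"][0] == pytest.approx(0.5)

    def test_uniform_samples_approach_null(self):
        rng = np.random.default_rng(0)
        out = delta_theta_cdf(rng.uniform(0, np.pi / 2, 20000))
        assert out["ks_distance"] < 0.02

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta_theta_cdf([2.0])


def test_fold_nematic_difference_range():
    for a, b in [(0.1, 3.0), (1.5, 0.0), (3.1, 0.05)]:
        d = fold_nematic_difference(a, b)
        assert 0 <= d <= np.pi / 2
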