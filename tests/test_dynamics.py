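"""Integrator correctness: operators, equilibria, linear growth, schemes."""

import numpy as np
import pytest

from phytopattern import (
    ModelParams,
    RunConfig,
    ScalarField,
    dispersion_relation,
    homogeneous_states,
    integrate,
    make_single_patch,
    spatial_operators,
    step,
)
from phytopattern.dynamics import (
    BlowUpError,
    classify_patch_fate,
    count_patches,
    patch_stability_scan,
    patch_threshold,
    reference_plateau,
    self_replication_run,
    stable_dt_bound,
)


class TestSpatialOperators:
    def test_constant_field_annihilated(self):
        f = ScalarField(np.full((32, 48), 1.7), dx=0.5)
        lap, bih = spatial_operators(f)
        np.testing.assert_allclose(lap, 0.0, atol=1e-12)
        np.testing.assert_allclose(bih, 0.0, atol=1e-12)

    def test_cosine_eigenfunction(self):
        n, dx = 64, 0.5
        k = 2 * np.pi * 3 / (n * dx)  # commensurate mode
        x = np.arange(n) * dx
        f = ScalarField(np.tile(np.cos(k * x), (n, 1)), dx=dx)
        lap, bih = spatial_operators(f)
        # second-order accuracy: relative error ~ (k dx)^2 / 12
        tol = (k * dx) ** 2 / 12 * k**2 * 1.1
        assert np.abs(lap - (-(k**2) * f.values)).max() < tol
        assert np.abs(bih - (k**4) * f.values).max() < 2 * tol * k**2

    def test_shift_equivariance(self, rng):
        f = ScalarField(rng.random((32, 32)), dx=0.7)
        lap, bih = spatial_operators(f)
        shifted = ScalarField(np.roll(f.values, (5, -3), axis=(0, 1)), dx=0.7)
        lap_s, bih_s = spatial_operators(shifted)
        np.testing.assert_array_equal(np.roll(lap, (5, -3), axis=(0, 1)), lap_s)
        np.testing.assert_array_equal(np.roll(bih, (5, -3), axis=(0, 1)), bih_s)


class TestStep:
    def test_bare_state_invariant(self, reference_params):
        f = ScalarField(np.zeros((32, 32)), dx=0.5)
        cfg = RunConfig(dt=0.03, n_steps=10)
        out = integrate(f, reference_params, cfg)[-1][1]
        np.testing.assert_array_equal(out.values, 0.0)

    def test_vegetated_equilibrium_fixed_point(self, bistable_params):
        rho = homogeneous_states(bistable_params).vegetated_upper
        f = ScalarField(np.full((32, 32), rho), dx=0.5)
        out = step(f, bistable_params, RunConfig(dt=0.03, n_steps=1))
        assert np.abs(out.values - rho).max() < 1e-12

    def test_deterministic(self, reference_params, rng):
        f = ScalarField(0.3 * rng.random((32, 32)), dx=0.5)
        cfg = RunConfig(dt=0.02, n_steps=50)
        a = integrate(f.copy(), reference_params, cfg)[-1][1].values
        b = integrate(f.copy(), reference_params, cfg)[-1][1].values
        np.testing.assert_array_equal(a, b)

    def test_excessive_dt_rejected(self, reference_params):
        f = ScalarField(np.full((32, 32), 0.4), dx=0.5)
        bound = stable_dt_bound(reference_params, 0.5, 0.4)
        with pytest.raises(ValueError, match="stability bound"):
            step(f, reference_params, RunConfig(dt=5 * bound, n_steps=1))

    def test_translation_equivariance_explicit(self, reference_params):
        ic = make_single_patch((48, 48), 0.5, radius=3.0, amplitude=0.4)
        cfg = RunConfig(dt=0.03, n_steps=100)
        base = integrate(ic, reference_params, cfg)[-1][1].values
        shifted_ic = ScalarField(np.roll(ic.values, (7, 11), axis=(0, 1)), 0.5)
        shifted = integrate(shifted_ic, reference_params, cfg)[-1][1].values
        np.testing.assert_array_equal(np.roll(base, (7, 11), axis=(0, 1)), shifted)


class TestLinearGrowth:
    def test_seeded_mode_grows_at_dispersion_rate(self, bistable_params):
        """Perturbation growth matches the dispersion relation within 5%."""
        p = bistable_params
        rho = homogeneous_states(p).vegetated_upper
        n, dx = 128, 0.5
        x = np.arange(n) * dx
        for m in (12, 13, 14):  # modes bracketing k_c, where sigma is flat
            k = 2 * np.pi * m / (n * dx)
            f = ScalarField(rho + 1e-6 * np.tile(np.cos(k * x), (n, 1)), dx=dx)
            dt, steps = 0.01, 200
            amps = []
            u = f.values
            mode = np.cos(k * x)
            for i in range(steps):
                u = integrate(ScalarField(u, dx), p, RunConfig(dt=dt, n_steps=1))[-1][1].values
                amps.append(2.0 * np.mean(u * mode[None, :]) - 2.0 * rho * np.mean(mode))
            amps = np.asarray(amps)
            rate = np.polyfit(dt * np.arange(1, steps + 1), np.log(np.abs(amps)), 1)[0]
            sigma = dispersion_relation(k, rho, p)
            assert rate == pytest.approx(sigma, rel=0.05)


class TestSchemes:
    def test_explicit_and_spectral_agree(self, reference_params):
        """Both time steppers give the same trajectory to < 1e-3 rel L2 at t=10."""
        ic = make_single_patch((64, 64), 0.5, radius=4.0, amplitude=0.4)
        steps = 334  # t ~ 10 at dt = 0.03
        a = integrate(ic.copy(), reference_params, RunConfig(dt=0.03, n_steps=steps))[-1][1].values
        b = integrate(
            ic.copy(), reference_params,
            RunConfig(dt=0.03, n_steps=steps, scheme="semi-implicit-spectral"),
        )[-1][1].values
        rel = np.linalg.norm(a - b) / np.linalg.norm(a)
        assert rel < 1e-3


class TestSinglePatch:
    def test_center_amplitude_and_symmetry(self):
        f = make_single_patch((64, 64), 0.5, radius=3.0, amplitude=0.4)
        assert f.values.max() == pytest.approx(0.4)
        v = f.values
        np.testing.assert_allclose(v, v.T, atol=1e-12)  # diagonal symmetry
        # mirror symmetry about the center row/column
        c = 32
        np.testing.assert_allclose(v[c - 10, :], v[c + 10, :], atol=1e-12)
        np.testing.assert_allclose(v[:, c - 10], v[:, c + 10], atol=1e-12)

    def test_integrated_biomass_matches_gaussian_integral(self):
        dx, radius, amp = 0.25, 4.0, 0.5
        f = make_single_patch((128, 128), dx, radius=radius, amplitude=amp)
        mass = f.values.sum()
        expected = amp * np.pi * radius**2 / dx**2
        assert mass == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("radius", [0.4, 100.0])
    def test_rejects_bad_radius(self, radius):
        with pytest.raises(ValueError):
            make_single_patch((64, 64), 0.5, radius=radius, amplitude=0.4)


class TestPatchFate:
    def test_high_aridity_patch_dies(self, reference_params):
        p = reference_params.replace(eta=0.3)
        ic = make_single_patch((64, 64), 0.5, radius=3.0, amplitude=0.4)
        final = integrate(ic, p, RunConfig(dt=0.03, n_steps=3000))[-1][1]
        assert final.values.max() < 1e-4

    def test_replication_run_counts_patches(self, reference_params):
        ic = make_single_patch((128, 128), 0.5, radius=3.0, amplitude=0.4)
        cfg = RunConfig(dt=0.03, n_steps=500, snapshot_stride=250)
        snaps, counts = self_replication_run(reference_params, cfg, ic)
        assert [c for _, c in counts] == [1, 1]
        assert len(snaps) == 2

    def test_stability_scan_monotone_labels(self, reference_params):
        cfg = RunConfig(dt=0.03, n_steps=5000)
        res = patch_stability_scan([0.08, 0.104, 0.13], reference_params, cfg)
        assert res.labels == ("replicates", "stable", "decays")
        assert res.consistent
        assert res.eta_I == pytest.approx(0.092)
        assert res.eta_II == pytest.approx(0.117)

    def test_reference_plateau_is_order_vegetated_state(self, bistable_params):
        plat = reference_plateau(bistable_params, 0.5)
        assert 0.3 < plat < 1.0
        assert patch_threshold(bistable_params, 0.5) == pytest.approx(plat / 2)

    def test_count_patches_threshold(self):
        v = np.zeros((32, 32))
        v[4:8, 4:8] = 1.0
        v[20:24, 20:24] = 1.0
        assert count_patches(ScalarField(v, 0.5), 0.5) == 2


class TestFieldValidation:
    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            ScalarField(np.zeros((8, 32)), dx=0.5)

    def test_non_finite_rejected(self):
        v = np.zeros((32, 32))
        v[0, 0] = np.inf
        with pytest.raises(ValueError):
            ScalarField(v, dx=0.5)


class TestExtendedFieldRun:
    def test_bare_scene_stays_bare(self, reference_params):
        from phytopattern import SceneSpec, extended_field_run

        spec = SceneSpec(width=64, height=64, rate=0.0, seed=1)
        final = extended_field_run(spec, reference_params, RunConfig(dt=0.03, n_steps=50))[-1][1]
        np.testing.assert_array_equal(final.values, 0.0)

    def test_accepts_prerendered_field(self, reference_params):
        from phytopattern import extended_field_run

        ic = make_single_patch((64, 64), 0.5, radius=3.0, amplitude=0.4)
        cfg = RunConfig(dt=0.03, n_steps=100)
        a = extended_field_run(ic.copy(), reference_params, cfg)[-1][1].values
        b = integrate(ic.copy(), reference_params, cfg)[-1][1].values
        np.testing.assert_array_equal(a, b)
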