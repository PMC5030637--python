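"""Spatial statistics: NND, root sphere, spectrum, Voronoi, fits."""

import numpy as np
import pytest

from phytopattern import (
    SceneSpec,
    binarize,
    fit_inverse_gaussian,
    fit_rayleigh,
    label_patches,
    nnd_boundary,
    preprocess,
    radial_spectrum,
    render_scene,
    root_sphere_estimate,
    voronoi_summary,
)
from phytopattern.pipeline import label_patches_keep_border


def two_disk_mask(shape, c1, r1, c2, r2):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask[(rr - c1[0]) ** 2 + (cc - c1[1]) ** 2 <= r1**2] = True
    mask[(rr - c2[0]) ** 2 + (cc - c2[1]) ** 2 <= r2**2] = True
    return mask


def brute_force_nnd(patches):
    """O(n^2 b^2) all-pairs boundary distance oracle."""
    labels = patches.table["label"].to_numpy()
    pts = {int(l): patches.boundary_pixels(int(l)).astype(float) for l in labels}
    out = {}
    for li in labels:
        best = np.inf
        for lj in labels:
            if lj == li:
                continue
            a, b = pts[int(li)], pts[int(lj)]
            d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
            best = min(best, np.sqrt(d2.min()))
        out[int(li)] = best * patches.pixel_size
    return out


class TestNND:
    def test_two_disks_geometry(self):
        # disks well inside a large image
        mask = two_disk_mask((200, 200), (100, 80), 10, (100, 120), 8)
        ps = label_patches(mask, pixel_size=0.1, min_diameter_m=0.0)
        nnd = nnd_boundary(ps)
        expected = (40 - 10 - 8) * 0.1
        assert len(nnd) == 2
        for v in nnd["nnd_m"]:
            assert v == pytest.approx(expected, abs=1.5 * 0.1)
        assert nnd["valid"].all()

    def test_edge_proximity_invalidates(self):
        # left disk nearer to the border than to its neighbour
        mask = two_disk_mask((120, 200), (60, 10), 8, (60, 60), 8)
        ps = label_patches_keep_border(mask)
        nnd = nnd_boundary(ps).set_index("label")
        left = ps.table.loc[ps.table["col"].idxmin(), "label"]
        right = ps.table.loc[ps.table["col"].idxmax(), "label"]
        assert not nnd.loc[left, "valid"]
        assert nnd.loc[right, "valid"]

    def test_matches_brute_force_on_random_scenes(self):
        """KD-tree accelerated NND equals the quadratic oracle exactly."""
        for seed in range(10):
            spec = SceneSpec(width=150, height=150, rate=0.002, noise_sd=0.0, seed=seed)
            img, _ = render_scene(spec, mode="image")
            ps = label_patches(binarize(preprocess(img)), 1.0, min_diameter_m=0.0)
            if len(ps) < 2:
                continue
            fast = nnd_boundary(ps).set_index("label")["nnd_m"]
            slow = brute_force_nnd(ps)
            for lab, v in slow.items():
                assert fast.loc[lab] == pytest.approx(v, abs=1e-12)

    def test_fewer_than_two_patches_empty(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:34, 30:34] = True
        ps = label_patches(mask, pixel_size=1.0, min_diameter_m=0.0)
        assert len(nnd_boundary(ps)) == 0


class TestRootSphere:
    def test_field_survey_worked_example(self):
        est = root_sphere_estimate(0.50, 1.83, 0.95)
        assert est.radius_m == pytest.approx(1.415)
        assert est.area_m2 == pytest.approx(np.pi * 1.415**2)
        assert est.area_ratio == pytest.approx(6.62, abs=0.01)

    def test_zero_spacing_degenerates_to_patch_radius(self):
        est = root_sphere_estimate(0.7, 0.0, 1.0)
        assert est.radius_m == pytest.approx(0.7)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            root_sphere_estimate(0.0, 1.0, 1.0)


class TestRadialSpectrum:
    @pytest.mark.parametrize("wavelength_px", [8, 16, 32])
    def test_stripe_wavelength_recovered(self, wavelength_px):
        n = 128
        x = np.arange(n)
        field = np.tile(np.sin(2 * np.pi * x / wavelength_px), (n, 1))
        prof = radial_spectrum(field, pixel_size=1.0)
        dk = 2 * np.pi / n
        assert prof.k_max == pytest.approx(2 * np.pi / wavelength_px, abs=dk)
        assert prof.characteristic_length == pytest.approx(wavelength_px, rel=0.1)

    def test_hexagonal_lattice_peak(self):
        """Spot lattice with spacing a peaks at k = 4 pi / (sqrt(3) a)."""
        a = 16.0
        n = 256
        field = np.zeros((n, n))
        rows = np.arange(0, n + 40, a * np.sqrt(3) / 2)
        for i, r in enumerate(rows):
            offset = (a / 2) if i % 2 else 0.0
            for c in np.arange(offset, n + 40, a):
                rr, cc = np.mgrid[0:n, 0:n]
                field += np.exp(-(((rr - r) % n) ** 2 + ((cc - c) % n) ** 2) / 8.0)
        prof = radial_spectrum(field, pixel_size=1.0)
        dk = 2 * np.pi / n
        assert prof.k_max == pytest.approx(4 * np.pi / (np.sqrt(3) * a), abs=1.5 * dk)

    def test_white_noise_has_no_pronounced_peak(self):
        """Featureless fields: peak-to-median radial amplitude stays below 3."""
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = radial_spectrum(rng.standard_normal((128, 128)), 1.0)
            body = prof.amplitude[2:-1]
            ratios.append(body.max() / np.median(body))
        assert max(ratios) < 3.0

    def test_constant_input_no_peak(self):
        prof = radial_spectrum(np.full((64, 64), 2.5), 1.0)
        assert prof.k_max is None

    def test_pixel_size_scales_wavenumber(self):
        n = 128
        x = np.arange(n)
        field = np.tile(np.sin(2 * np.pi * x / 16), (n, 1))
        k1 = radial_spectrum(field, 1.0).k_max
        k2 = radial_spectrum(field, 2.0).k_max
        assert k2 == pytest.approx(k1 / 2)


def triangular_lattice(a, nx, ny):
    pts = []
    for i in range(ny):
        for j in range(nx):
            pts.append((i * a * np.sqrt(3) / 2, j * a + (a / 2 if i % 2 else 0)))
    return np.asarray(pts)


class TestVoronoi:
    def test_triangular_lattice_hexagonal_cells(self):
        a = 2.0
        pts = triangular_lattice(a, 12, 12)
        summary = voronoi_summary(pts)
        assert summary.modal_vertex_count == 6
        interior = summary.cells
        assert (interior["n_vertices"] == 6).all()
        np.testing.assert_allclose(interior["area"], np.sqrt(3) / 2 * a**2, atol=1e-9)

    def test_square_lattice_four_vertices(self):
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        pts = np.column_stack([ys.ravel(), xs.ravel()])
        summary = voronoi_summary(pts)
        assert summary.modal_vertex_count == 4

    def test_distant_outlier_does_not_change_interior(self):
        pts = triangular_lattice(2.0, 10, 10)
        window = (2.0, 12.0, 2.0, 16.0)
        base = voronoi_summary(pts, window)
        extended = voronoi_summary(
            np.vstack([pts, [[500.0, 500.0]]]), window
        )
        merged = base.cells.merge(extended.cells, on="point_index", suffixes=("_a", "_b"))
        assert (merged["n_vertices_a"] == merged["n_vertices_b"]).all()

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(6.0), np.arange(6.0)])
        with pytest.raises(ValueError):
            voronoi_summary(pts)

    def test_mean_area_equivalent_radius(self):
        summary = voronoi_summary(triangular_lattice(2.0, 10, 10))
        assert summary.equivalent_radius == pytest.approx(
            np.sqrt(summary.mean_area / np.pi)
        )


class TestFits:
    def test_rayleigh_closed_form(self):
        fit = fit_rayleigh([1.0, 1.0])
        assert fit.params["sigma"] == pytest.approx(1 / np.sqrt(2))

    def test_rayleigh_parameter_recovery(self, rng):
        x = rng.rayleigh(2.0, 10_000)
        fit = fit_rayleigh(x)
        assert abs(fit.params["sigma"] - 2.0) < 0.05

    def test_rayleigh_scale_equivariance(self, rng):
        x = rng.rayleigh(1.5, 500)
        s1 = fit_rayleigh(x).params["sigma"]
        s2 = fit_rayleigh(3.0 * x).params["sigma"]
        assert s2 == pytest.approx(3.0 * s1)

    def test_rayleigh_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_rayleigh([1.0, -0.5])

    def test_invgauss_mean_is_sample_mean(self, rng):
        x = rng.wald(3.0, 5.0, 1000)
        fit = fit_inverse_gaussian(x)
        assert fit.params["mu"] == pytest.approx(x.mean())

    def test_invgauss_parameter_recovery(self, rng):
        x = rng.wald(3.0, 5.0, 10_000)
        fit = fit_inverse_gaussian(x)
        assert abs(fit.params["mu"] - 3.0) < 0.1
        assert abs(fit.params["lambda"] - 5.0) < 0.3

    def test_invgauss_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_inverse_gaussian([2.0, 2.0, 2.0])

    def test_loglikelihood_finite_and_reproducible(self, rng):
        x = rng.rayleigh(1.0, 200)
        f1, f2 = fit_rayleigh(x), fit_rayleigh(x)
        assert np.isfinite(f1.log_likelihood)
        assert f1 == f2
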