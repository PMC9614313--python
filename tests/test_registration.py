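"""Registration engines: MI, affine, FFD primitives, demons primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pqctseg.core_raster import (
    AffineTransform,
    Raster2D,
    compose_fields,
    warp_image,
)
from pqctseg.phantom import random_smooth_deformation
from pqctseg.registration import (
    ControlPointGrid,
    RegistrationConfig,
    bending_energy,
    bspline_basis,
    demons_update,
    exp_field,
    ffd_displacement,
    mattes_mi,
    register_affine,
    register_ffd,
    register_sdd,
)


class TestMattesMI:
    def test_constant_image_returns_zero(self, phantom64):
        img, _ = phantom64
        const = Raster2D(np.full(img.shape, 5.0), img.spacing)
        assert mattes_mi(img, const) == 0.0
        assert mattes_mi(const, img) == 0.0

    def test_self_similarity_is_maximal(self, phantom64):
        img, _ = phantom64
        shifted = warp_image(img, AffineTransform(np.eye(2), [5 * img.spacing, 0]))
        assert mattes_mi(img, img) <= mattes_mi(img, shifted)

    def test_symmetry(self, phantom64):
        img, _ = phantom64
        shifted = warp_image(img, AffineTransform(np.eye(2), [1.5, 0.7]))
        assert abs(mattes_mi(img, shifted) - mattes_mi(shifted, img)) < 1e-9

    def test_nonpositive(self, phantom64):
        img, _ = phantom64
        assert mattes_mi(img, img) <= 0.0

    def test_min_bins_enforced(self, phantom64):
        img, _ = phantom64
        with pytest.raises(ValueError, match="bins"):
            mattes_mi(img, img, bins=4)


class TestRegisterAffine:
    def test_identity_optimum(self, phantom64):
        img, _ = phantom64
        mu = register_affine(img, img)
        assert np.abs(mu.translation).max() < 0.2 * img.spacing
        angle = np.rad2deg(np.arctan2(mu.matrix[1, 0], mu.matrix[0, 0]))
        assert abs(angle) < 0.5

    def test_translation_recovery(self, phantom64):
        img, _ = phantom64
        true = AffineTransform(np.eye(2), [3.5, -2.0])
        moving = warp_image(img, true.inverse())
        mu = register_affine(img, moving)
        assert np.abs(mu.translation - true.translation).max() < 0.5 * img.spacing

    def test_rotation_recovery(self, phantom64):
        img, _ = phantom64
        theta = np.deg2rad(10.0)
        c, s = np.cos(theta), np.sin(theta)
        ctr = np.array([(img.width - 1) * img.spacing / 2] * 2)
        R = np.array([[c, -s], [s, c]])
        true = AffineTransform(R, ctr - R @ ctr)
        moving = warp_image(img, true.inverse())
        mu = register_affine(img, moving)
        angle = np.rad2deg(np.arctan2(mu.matrix[1, 0], mu.matrix[0, 0]))
        assert abs(angle - 10.0) < 1.0


class TestBsplinePrimitives:
    @given(st.floats(min_value=0.0, max_value=0.999999))
    @settings(max_examples=50, deadline=None)
    def test_partition_of_unity(self, u):
        assert bspline_basis(u).sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_lattice_zero_field(self):
        grid = ControlPointGrid.for_domain((64, 64), 0.5, 16)
        assert np.all(grid.dense_field((64, 64), 0.5).displacement == 0.0)
        assert ffd_displacement(grid, (10.0, 12.0)) == pytest.approx([0.0, 0.0])

    def test_single_control_point_local_support(self):
        grid = ControlPointGrid.for_domain((64, 64), 0.5, 16)
        grid.phi[4, 4, 0] = 2.0  # lattice coord (3,3) -> 48 px
        disp = grid.dense_field((64, 64), 0.5).displacement[..., 0]
        nz_rows, nz_cols = np.nonzero(np.abs(disp) > 1e-12)
        # support is 4*delta = 64 px wide centered at 48 px
        assert nz_rows.min() >= 48 - 32 and nz_cols.min() >= 48 - 32

    def test_point_outside_lattice_rejected(self):
        grid = ControlPointGrid.for_domain((64, 64), 0.5, 16)
        with pytest.raises(ValueError, match="lattice"):
            ffd_displacement(grid, (1000.0, 0.0))


class TestBendingEnergy:
    def test_zero_lattice(self):
        grid = ControlPointGrid.for_domain((64, 64), 0.5, 16)
        assert bending_energy(grid, (64, 64), 0.5) == 0.0

    def test_affine_lattice_has_zero_energy(self):
        grid = ControlPointGrid.for_domain((64, 64), 0.5, 16)
        iy, ix = np.meshgrid(np.arange(grid.phi.shape[0]),
                             np.arange(grid.phi.shape[1]), indexing="ij")
        grid.phi = np.stack([0.3 * ix + 0.1 * iy + 0.5,
                             -0.2 * ix + 0.4 * iy], axis=-1).astype(float)
        assert bending_energy(grid, (64, 64), 0.5) == pytest.approx(0.0, abs=1e-20)

    def test_matches_finite_difference_quadrature(self):
        grid = ControlPointGrid.for_domain((64, 64), 0.5, 16)
        grid.phi[4, 4, 0] = 2.0
        analytic = bending_energy(grid, (64, 64), 0.5)
        disp = grid.dense_field((64, 64), 0.5).displacement
        numeric = 0.0
        for c in range(2):
            fy, fx = np.gradient(disp[..., c], 0.5)
            fyy, _ = np.gradient(fy, 0.5)
            fxy, fxx = np.gradient(fx, 0.5)
            numeric += np.mean(fxx ** 2 + 2 * fxy ** 2 + fyy ** 2)
        assert analytic == pytest.approx(numeric, rel=0.05)

    def test_gradient_matches_numeric(self):
        grid = ControlPointGrid.for_domain((32, 32), 0.5, 8)
        rng = np.random.default_rng(0)
        grid.phi = rng.normal(0, 0.5, grid.phi.shape)
        e0, g = bending_energy(grid, (32, 32), 0.5, gradient=True)
        h = 1e-6
        for idx in [(2, 3, 0), (4, 1, 1)]:
            grid.phi[idx] += h
            e1 = bending_energy(grid, (32, 32), 0.5)
            grid.phi[idx] -= h
            assert g[idx] == pytest.approx((e1 - e0) / h, rel=1e-3, abs=1e-8)


class TestRegisterFFD:
    def test_identity_optimum(self, phantom64):
        img, _ = phantom64
        field = register_ffd(img, img)
        assert field.magnitude().mean() < 0.2 * img.spacing

    def test_energy_decreases(self, phantom64):
        img, _ = phantom64
        fld = random_smooth_deformation(img.shape, img.spacing, seed=2,
                                        amplitude=2.0, scale=15.0)
        moving = warp_image(img, fld)
        report = {}
        register_ffd(img, moving, report=report)
        assert report["energies"][-1] <= report["energies"][0]


class TestDemonsUpdate:
    def test_zero_residual_gives_zero_update(self):
        a = np.tile(np.arange(16.0), (16, 1))
        u = demons_update(a, a, spacing=1.0, norm_const=1.0)
        assert np.all(u == 0.0)

    def test_hand_worked_single_pixel(self):
        """S - A = 2, J = (1, 0), normalization 1: u = -(2*1)/(1+1) = -1."""
        A = np.tile(np.arange(16.0), (16, 1))
        S = A + 2.0
        u = demons_update(S, A, spacing=1.0, norm_const=1.0)
        assert u[8, 8, 0] == pytest.approx(-1.0)
        assert u[8, 8, 1] == pytest.approx(0.0)

    def test_large_gradient_limit(self):
        """|u| -> |diff|/||J|| -> 0 as the gradient grows."""
        A = np.tile(np.arange(16.0) * 1e6, (16, 1))
        S = A + 2.0
        u = demons_update(S, A, spacing=1.0, norm_const=1.0)
        assert np.abs(u).max() < 1e-4

    def test_magnitude_bound(self, phantom64):
        """AM-GM on the denominator: |u| <= |diff| / (2 sqrt(norm))."""
        img, lab = phantom64
        fld = random_smooth_deformation(img.shape, img.spacing, seed=3,
                                        amplitude=2.0, scale=10.0)
        warped = warp_image(img, fld)
        norm = 1.0
        u = demons_update(img, warped, img.spacing, norm)
        bound = np.abs(img.values - warped.values) / (2 * np.sqrt(norm))
        assert np.all(np.hypot(u[..., 0], u[..., 1]) <= bound + 1e-9)


class TestExpField:
    def test_zero_velocity_is_identity(self):
        out = exp_field(np.zeros((32, 32, 2)), spacing=0.5)
        assert np.all(out.displacement == 0.0)

    def test_constant_velocity_is_exact_translation(self):
        v = np.zeros((32, 32, 2))
        v[..., 0] = 1.3
        out = exp_field(v, spacing=0.5)
        assert np.allclose(out.displacement[..., 0], 1.3, atol=1e-12)
        assert np.allclose(out.displacement[..., 1], 0.0)

    def test_inverse_composition_residual(self):
        fld = random_smooth_deformation((64, 64), 0.5, seed=3,
                                        amplitude=1.0, scale=8.0)
        fwd = exp_field(fld.displacement, 0.5)
        bwd = exp_field(-fld.displacement, 0.5)
        residual = compose_fields(fwd, bwd).magnitude() / 0.5
        assert residual[4:-4, 4:-4].mean() < 0.05


class TestRegisterSDD:
    def test_identity_optimum(self, phantom64):
        img, _ = phantom64
        tau, tau_inv = register_sdd(img, img)
        assert tau.magnitude().mean() < 0.2 * img.spacing
        assert tau_inv.magnitude().mean() < 0.2 * img.spacing

    def test_inverse_consistency_and_diffeomorphism(self, phantom64):
        img, _ = phantom64
        fld = random_smooth_deformation(img.shape, img.spacing, seed=5,
                                        amplitude=3.0, scale=20.0)
        moving = warp_image(img, fld)
        tau, tau_inv = register_sdd(img, moving)
        residual = compose_fields(tau, tau_inv).magnitude() / img.spacing
        assert residual.mean() < 0.1
        assert tau.jacobian_determinant().min() > 0

    def test_energy_decreases_from_start(self, phantom64):
        img, _ = phantom64
        fld = random_smooth_deformation(img.shape, img.spacing, seed=5,
                                        amplitude=3.0, scale=20.0)
        moving = warp_image(img, fld)
        report = {}
        register_sdd(img, moving, report=report)
        assert min(report["energies"]) < report["energies"][0]


class TestConfig:
    def test_round_trip_json(self, tmp_path):
        cfg = RegistrationConfig(mi_bins=16, sdd_iterations=5)
        path = tmp_path / "cfg.json"
        import json
        path.write_text(json.dumps(cfg.to_dict()))
        back = RegistrationConfig.from_file(path)
        assert back == cfg

    def test_yaml_support(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("mi_bins: 16\nsdd_iterations: 7\n")
        cfg = RegistrationConfig.from_file(path)
        assert cfg.mi_bins == 16 and cfg.sdd_iterations == 7

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError):
            RegistrationConfig(mi_bins=4)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"nope": 1}')
        with pytest.raises(ValueError, match="unknown config"):
            RegistrationConfig.from_file(path)
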