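"""Monolayer stress recovery and tensor-derived quantities."""

import numpy as np
import pytest

from monomech.fields import MonolayerSpec, StressTensorField, VectorField2D
from monomech.stress import (average_normal_stress, maximum_shear_stress,
                             principal_stresses, recover_stress,
                             recover_stress_full, stress_anisotropy)


def strip_traction(ny=40, nx=120, spacing=2.0, T0=100.0, band=20):
    """Uniform inward edge-band tractions on a full-grid strip."""
    Tx = np.zeros((ny, nx))
    Tx[:, :band] = T0
    Tx[:, -band:] = -T0
    return VectorField2D(Tx, np.zeros_like(Tx), spacing=spacing, units="Pa")


class TestRecovery:
    def test_zero_traction_zero_stress(self):
        T = VectorField2D(np.zeros((20, 30)), np.zeros((20, 30)),
                          spacing=2.0, units="Pa")
        s = recover_stress(T, np.ones((20, 30), bool), MonolayerSpec())
        np.testing.assert_allclose(s.sxx[s.mask], 0.0, atol=1e-9)

    def test_strip_plateau_matches_1d_integral(self):
        """Interior sigma_xx equals the closed-form (1/h) integral of Tx,
        with linear ramps inside the bands."""
        ny, nx, a, T0, band, h = 40, 120, 2.0, 100.0, 20, 5.0
        T = strip_traction(ny, nx, a, T0, band)
        res = recover_stress_full(T, np.ones((ny, nx), bool),
                                  MonolayerSpec(height=h))
        plateau = T0 * band * a / h
        mid = res.stress.sxx[ny // 2]
        assert abs(mid[nx // 2] - plateau) / plateau < 0.05
        # ramp: halfway into the band the integral is half the plateau
        assert abs(mid[band // 2] - 0.5 * plateau) / plateau < 0.08
        assert res.residual < 0.01

    def test_plateau_independent_of_poisson_m(self):
        """The 1D plateau is statically determinate: poisson_m drops out."""
        T = strip_traction()
        vals = []
        for nu_m in (0.0, 0.3, 0.5):
            s = recover_stress(T, np.ones(T.shape, bool),
                               MonolayerSpec(height=5.0, poisson_m=nu_m))
            vals.append(s.sxx[20, 60])
        assert np.ptp(vals) / np.mean(vals) < 0.01

    def test_rotation_equivariance(self):
        """Rotating traction and mask by 90° rotates the tensor."""
        rng = np.random.default_rng(3)
        base = np.zeros((40, 60))
        base[:, :10] = 100.0
        base[:, -10:] = -100.0
        Ty = 5.0 * rng.standard_normal((40, 60))
        Ty -= Ty.mean()
        T = VectorField2D(base, Ty, spacing=2.0, units="Pa")
        mask = np.ones((40, 60), bool)
        s = recover_stress(T, mask, MonolayerSpec())
        # 90° CCW in xy (y down): array rot90 with (Tx,Ty) -> (Ty, -Tx)
        Trot = VectorField2D(np.rot90(T.v), np.rot90(-T.u),
                             spacing=2.0, units="Pa")
        s2 = recover_stress(Trot, np.rot90(mask).copy(), MonolayerSpec())
        np.testing.assert_allclose(s2.sxx, np.rot90(s.syy), atol=1e-6)
        np.testing.assert_allclose(s2.syy, np.rot90(s.sxx), atol=1e-6)

    def test_boundary_stress_small(self):
        """The free-margin condition holds to discretisation order."""
        T = strip_traction(T0=100.0, band=20)
        s = recover_stress(T, np.ones(T.shape, bool),
                           MonolayerSpec(height=5.0))
        plateau = 100.0 * 20 * 2.0 / 5.0
        edge = np.abs(s.sxx[20, 0])
        assert edge < 0.05 * plateau

    def test_disconnected_islands_warns_and_solves(self):
        ny, nx = 30, 80
        Tx = np.zeros((ny, nx))
        Tx[:, :5] = 50.0
        Tx[:, 30:35] = -50.0
        Tx[:, 45:50] = 50.0
        Tx[:, -5:] = -50.0
        T = VectorField2D(Tx, np.zeros_like(Tx), spacing=2.0, units="Pa")
        mask = np.zeros((ny, nx), bool)
        mask[:, :35] = True
        mask[:, 45:] = True
        with pytest.warns(UserWarning, match="islands"):
            res = recover_stress_full(T, mask, MonolayerSpec())
        assert res.components == 2
        assert np.isfinite(res.stress.sxx[res.stress.mask]).all()

    def test_unbalanced_traction_rejected_without_projection(self):
        Tx = np.full((20, 40), 50.0)      # net force, grossly unbalanced
        T = VectorField2D(Tx, np.zeros_like(Tx), spacing=2.0, units="Pa")
        with pytest.raises(ValueError, match="unbalanced"):
            recover_stress(T, np.ones((20, 40), bool), MonolayerSpec(),
                           project_balance=False)


class TestPrincipal:
    def test_uniaxial(self):
        t = StressTensorField(np.full((3, 3), 100.0), np.zeros((3, 3)),
                              np.zeros((3, 3)), spacing=1.0,
                              mask=np.ones((3, 3), bool))
        p = principal_stresses(t)
        np.testing.assert_allclose(p.smax, 100.0)
        np.testing.assert_allclose(p.smin, 0.0)
        np.testing.assert_allclose(p.alpha, 0.0)

    def test_isotropic_flagged(self):
        t = StressTensorField(np.full((2, 2), 60.0), np.full((2, 2), 60.0),
                              np.zeros((2, 2)), spacing=1.0,
                              mask=np.ones((2, 2), bool))
        p = principal_stresses(t)
        np.testing.assert_allclose(p.smax, 60.0)
        np.testing.assert_allclose(p.smin, 60.0)
        assert p.isotropic.all()

    def test_matches_eigen_oracle(self, rng):
        """Closed-form principal values/axes agree with numpy's eigen
        solver on random symmetric tensors."""
        n = 10_000
        sxx, syy, sxy = rng.normal(scale=50, size=(3, n))
        t = StressTensorField(sxx[None], syy[None], sxy[None],
                              spacing=1.0, mask=np.ones((1, n), bool))
        p = principal_stresses(t)
        mats = np.empty((n, 2, 2))
        mats[:, 0, 0] = sxx
        mats[:, 1, 1] = syy
        mats[:, 0, 1] = mats[:, 1, 0] = sxy
        w = np.linalg.eigvalsh(mats)
        np.testing.assert_allclose(p.smin[0], w[:, 0], rtol=1e-10,
                                   atol=1e-10)
        np.testing.assert_allclose(p.smax[0], w[:, 1], rtol=1e-10,
                                   atol=1e-10)
        # orientation: rotating by alpha diagonalises the tensor
        th = np.radians(p.alpha[0])
        shear_rot = (syy - sxx) * np.sin(th) * np.cos(th) + \
            sxy * (np.cos(th)**2 - np.sin(th)**2)
        np.testing.assert_allclose(shear_rot, 0.0, atol=1e-8)

    def test_alpha_in_range(self, rng):
        sxx, syy, sxy = rng.normal(size=(3, 5, 5))
        p = principal_stresses(StressTensorField(
            sxx, syy, sxy, spacing=1.0, mask=np.ones((5, 5), bool)))
        assert ((p.alpha >= 0) & (p.alpha < 180)).all()


class TestDerived:
    def _field(self, smax, smin):
        shape = np.shape(smax)
        return principal_stresses(StressTensorField(
            np.asarray(smax, float), np.asarray(smin, float),
            np.zeros(shape), spacing=1.0, mask=np.ones(shape, bool)))

    def test_ans_midpoint(self):
        p = self._field(np.full((2, 2), 80.0), np.full((2, 2), 40.0))
        np.testing.assert_allclose(average_normal_stress(p), 60.0)

    def test_ans_pure_shear_is_zero(self):
        p = self._field(np.full((2, 2), 30.0), np.full((2, 2), -30.0))
        np.testing.assert_allclose(average_normal_stress(p), 0.0, atol=1e-12)

    def test_mss_modes(self):
        p = self._field(np.full((2, 2), 80.0), np.full((2, 2), 40.0))
        np.testing.assert_allclose(maximum_shear_stress(p), 20.0)
        np.testing.assert_allclose(
            maximum_shear_stress(p, mode="difference"), 40.0)

    def test_mss_nonnegative(self, rng):
        sxx, syy, sxy = rng.normal(size=(3, 8, 8))
        p = principal_stresses(StressTensorField(
            sxx, syy, sxy, spacing=1.0, mask=np.ones((8, 8), bool)))
        assert (maximum_shear_stress(p) >= 0).all()

    def test_invariants_under_rotation(self, rng):
        """ANS and MSS do not change when the tensor is rotated."""
        sxx, syy, sxy = rng.normal(scale=50, size=(3, 6, 6))
        theta = 0.61
        c, s = np.cos(theta), np.sin(theta)
        rxx = c*c*sxx + s*s*syy + 2*s*c*sxy
        ryy = s*s*sxx + c*c*syy - 2*s*c*sxy
        rxy = (syy - sxx)*s*c + (c*c - s*s)*sxy
        p1 = principal_stresses(StressTensorField(
            sxx, syy, sxy, spacing=1.0, mask=np.ones((6, 6), bool)))
        p2 = principal_stresses(StressTensorField(
            rxx, ryy, rxy, spacing=1.0, mask=np.ones((6, 6), bool)))
        np.testing.assert_allclose(average_normal_stress(p1),
                                   average_normal_stress(p2), atol=1e-9)
        np.testing.assert_allclose(maximum_shear_stress(p1),
                                   maximum_shear_stress(p2), atol=1e-9)

    def test_eccentricity_modes(self):
        p = self._field(np.full((2, 2), 60.0), np.full((2, 2), 60.0))
        np.testing.assert_allclose(stress_anisotropy(p), 0.0)     # circle
        np.testing.assert_allclose(stress_anisotropy(p, mode="ratio"), 1.0)
        q = self._field(np.full((2, 2), 60.0), np.zeros((2, 2)))
        np.testing.assert_allclose(stress_anisotropy(q), 1.0)     # line

    def test_eccentricity_monotone_in_ratio(self):
        ratios = np.linspace(0.95, 0.05, 10)
        e = [float(stress_anisotropy(self._field([[1.0]], [[r]]))[0, 0])
             for r in ratios]
        assert all(np.diff(e) > 0)

    def test_zero_smax_flagged_nan(self):
        e = stress_anisotropy(self._field(np.zeros((2, 2)), np.zeros((2, 2))))
        assert np.isnan(e).all()
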