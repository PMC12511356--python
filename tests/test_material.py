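"""Constitutive oracles for the fibril-reinforced poroelastic law."""

import numpy as np
import pytest

from cartmech.material import (
    FRPEParameters,
    MaterialState,
    fibril_directions,
    fibril_stress_1d,
    material_tangent,
    nonfibrillar_energy,
    nonfibrillar_stress,
    permeability,
    total_effective_stress,
)
from conftest import random_deformation_gradient

ENF, NU = 0.215, 0.15


class TestNonfibrillarMatrix:
    def test_zero_stress_at_identity(self):
        assert np.allclose(nonfibrillar_stress(np.eye(3), ENF, NU), 0.0)

    def test_small_strain_constrained_modulus(self):
        eps = 1e-6
        F = np.diag([1 + eps, 1.0, 1.0])
        sig = nonfibrillar_stress(F, ENF, NU)
        m_c = ENF * (1 - NU) / ((1 + NU) * (1 - 2 * NU))
        assert sig[0, 0] / eps == pytest.approx(m_c, rel=1e-3)

    def test_stress_is_energy_gradient(self, rng):
        F = random_deformation_gradient(rng, 0.15)
        h = 1e-6
        P_num = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                dF = np.zeros((3, 3))
                dF[i, j] = h
                P_num[i, j] = (
                    nonfibrillar_energy(F + dF, ENF, NU) - nonfibrillar_energy(F - dF, ENF, NU)
                ) / (2 * h)
        sig = nonfibrillar_stress(F, ENF, NU)
        P = np.linalg.det(F) * sig @ np.linalg.inv(F).T
        assert np.allclose(P, P_num, atol=1e-6)
        assert np.allclose(sig, sig.T, atol=1e-12)


class TestFibrilLaw:
    @pytest.mark.parametrize("eps,expected", [(-0.05, 0.0), (0.0, 0.0)])
    def test_tension_only(self, eps, expected):
        assert fibril_stress_1d(eps, 1.0, 100.0) == expected

    def test_quadratic_law_scalar_oracle(self):
        E0, Eeps, eps = 1.0, 100.0, 0.1
        assert fibril_stress_1d(eps, E0, Eeps) == pytest.approx(E0 * eps + Eeps * eps**2, rel=1e-15)

    def test_strictly_increasing_in_tension(self):
        eps = np.linspace(1e-4, 0.3, 50)
        s = fibril_stress_1d(eps, 0.92, 150.0)
        assert np.all(np.diff(s) > 0)

    def test_initial_slope_is_E0(self):
        h = 1e-9
        assert fibril_stress_1d(h, 0.92, 150.0) / h == pytest.approx(0.92, rel=1e-6)


class TestFibrilArchitecture:
    def test_deep_zone_along_depth(self):
        d = fibril_directions(0.0, "arcade")[0]
        assert d == pytest.approx([0, 0, 1])

    def test_superficial_zone_surface_parallel(self):
        d = fibril_directions(1.0, "arcade", (1, 0, 0))[0]
        assert d == pytest.approx([1, 0, 0])

    def test_transitional_rotation_angle(self):
        # z/h = 0.65 is halfway through the 0.5-0.8 transition: 45 degrees
        d = fibril_directions(0.65, "arcade", (1, 0, 0))[0]
        theta = 0.5 * np.pi * (0.65 - 0.5) / 0.3
        assert d == pytest.approx([np.sin(theta), 0.0, np.cos(theta)], abs=1e-12)
        assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)

    def test_continuity_in_depth(self):
        zs = np.linspace(0, 1, 101)
        dirs = np.array([fibril_directions(z, "arcade")[0] for z in zs])
        assert np.abs(np.diff(dirs, axis=0)).max() < 0.06


class TestTotalStress:
    def test_zero_at_rest_without_fibril_moduli(self):
        p = FRPEParameters(E0=0, Eeps=0)
        st = MaterialState(np.eye(3), 0.0)
        assert np.allclose(total_effective_stress(st, p), 0.0)

    def test_pore_pressure_term(self):
        p = FRPEParameters(E0=0, Eeps=0)
        st = MaterialState(np.eye(3), 0.5)
        assert np.allclose(total_effective_stress(st, p), -0.5 * np.eye(3))

    def test_single_fibril_family_uniaxial_composition(self):
        lam = 1.1
        prm = FRPEParameters(fibril_architecture="single")
        st = MaterialState(np.diag([lam, 1.0, 1.0]), 0.0, directions=[[1.0, 0.0, 0.0]])
        sig = total_effective_stress(st, prm)
        sf = fibril_stress_1d(np.log(lam), prm.E0, prm.Eeps)
        nf = nonfibrillar_stress(np.diag([lam, 1.0, 1.0]), prm.Enf, prm.nu_nf)
        assert sig[0, 0] == pytest.approx(nf[0, 0] + sf, rel=1e-12)
        assert abs(sig[0, 1]) < 1e-14 and abs(sig[0, 2]) < 1e-14

    def test_tension_only_switch_under_triaxial_compression(self):
        prm = FRPEParameters(fibril_architecture="single")
        F = 0.93 * np.eye(3)  # every direction shortens: no fibril stress
        st = MaterialState(F, 0.0, directions=[[1.0, 0.0, 0.0]])
        sig = total_effective_stress(st, prm)
        nf = nonfibrillar_stress(F, prm.Enf, prm.nu_nf)
        assert np.allclose(sig, nf, atol=1e-14)

    def test_objectivity_under_rotation(self, rng):
        from scipy.spatial.transform import Rotation

        prm = FRPEParameters(fibril_architecture="single", primary_direction=(1, 0, 0))
        for _ in range(5):
            F = random_deformation_gradient(rng, 0.15)
            R = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
            st = MaterialState(F, 0.2, directions=[[1.0, 0.0, 0.0]])
            st_rot = MaterialState(R @ F, 0.2, directions=[[1.0, 0.0, 0.0]])
            sig = total_effective_stress(st, prm)
            sig_rot = total_effective_stress(st_rot, prm)
            assert np.allclose(sig_rot, R @ sig @ R.T, atol=1e-10)


class TestPermeability:
    def test_reference_value(self, default_params):
        assert permeability(1.0, default_params) == pytest.approx(default_params.k0, rel=1e-15)

    def test_exponent_zero_constant(self):
        p = FRPEParameters(M=0.0)
        assert permeability(0.85, p) == pytest.approx(p.k0, rel=1e-15)

    def test_void_ratio_power_law_scalar_oracle(self):
        p = FRPEParameters(M=5.0, fluid_fraction=0.8)  # e0 = 4
        J = 0.9
        e = J * 5.0 - 1.0
        expected = p.k0 * ((1 + e) / 5.0) ** 5.0
        assert permeability(J, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_J(self, default_params):
        Js = np.linspace(0.5, 1.5, 40)
        ks = permeability(Js, default_params)
        assert np.all(np.diff(ks) > 0)

    def test_lockout_guard(self, default_params):
        with pytest.raises(ValueError):
            permeability(default_params.j_floor * 0.99, default_params)


class TestMaterialTangent:
    def test_linear_elastic_limit_matches_isotropic_stiffness(self):
        prm = FRPEParameters(E0=0, Eeps=0, Enf=0.5, nu_nf=0.2)
        st = MaterialState(np.eye(3), 0.0)
        A = material_tangent(st, prm, perturbation=1e-7)
        lam, mu = prm.lame
        eye = np.eye(3)
        C = (
            lam * np.einsum("ij,kl->ijkl", eye, eye)
            + mu * np.einsum("ik,jl->ijkl", eye, eye)
            + mu * np.einsum("il,jk->ijkl", eye, eye)
        )
        assert np.allclose(A, C, rtol=1e-4, atol=1e-8)

    def test_positive_definite_on_symmetric_perturbations_at_rest(self, default_params, rng):
        st = MaterialState(np.eye(3), 0.0)
        A = material_tangent(st, default_params)
        for _ in range(10):
            e = rng.standard_normal((3, 3))
            e = 0.5 * (e + e.T)
            quad = np.einsum("ij,ijkl,kl->", e, A, e)
            assert quad > 0

    def test_richardson_consistency(self, default_params, rng):
        F = random_deformation_gradient(rng, 0.1)
        st = MaterialState(F, 0.1, directions=[[0, 0, 1.0]])
        A1 = material_tangent(st, default_params, perturbation=2e-5)
        A2 = material_tangent(st, default_params, perturbation=1e-5)
        A3 = material_tangent(st, default_params, perturbation=5e-6)
        # central differences: error ~ h^2, so (A1-A2) ~ 4 (A2-A3)
        e12 = np.abs(A1 - A2).max()
        e23 = np.abs(A2 - A3).max()
        assert e12 > 2.0 * e23


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kw", [dict(nu_nf=0.5), dict(k0=0.0), dict(fluid_fraction=1.0), dict(Enf=-1.0)]
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            FRPEParameters(**kw)
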