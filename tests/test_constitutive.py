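import numpy as np
import pytest
from scipy.optimize import brentq

from lumpsim import constitutive as cst


def random_state(rng, with_plastic=True):
    F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
    if np.linalg.det(F) < 0.3:
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    lam_p = 1.0 + (0.2 * rng.random(3) - 0.1 if with_plastic else np.zeros(3))
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    phi = 0.2 + 2.0 * rng.random()
    kappa = rng.random() / 3.0
    return F, lam_p, q, phi, kappa


class TestKinematicSplit:
    def test_identity(self):
        kin = cst.kinematic_split(np.eye(3)[None], np.ones((1, 3)), np.eye(3)[None])
        assert np.isclose(kin.Je[0], 1.0)
        assert np.isclose(kin.I1e[0], 3.0)
        assert np.isclose(kin.I4e[0], 1.0)

    def test_uniaxial_fiber_stretch(self):
        lam = 1.3
        F = np.diag([lam, 1.0, 1.0])
        kin = cst.kinematic_split(F[None], np.ones((1, 3)), np.eye(3)[None])
        assert np.isclose(kin.I4e[0], lam ** 2)

    def test_against_dense_matrix_oracle(self, rng):
        for _ in range(20):
            F, lam_p, q, _, _ = random_state(rng)
            kin = cst.kinematic_split(F[None], lam_p[None], q[None])
            Fp = sum(lam_p[i] * np.outer(q[i], q[i]) for i in range(3))
            Fe = F @ np.linalg.inv(Fp)
            assert np.allclose(kin.Fe[0], Fe, atol=1e-12)
            assert np.isclose(kin.Je[0], np.linalg.det(Fe))
            a = Fe @ q[0]
            assert np.isclose(kin.I4e[0], a @ a)

    def test_multiplicative_split_consistency(self, rng):
        F, lam_p, q, _, _ = random_state(rng)
        kin = cst.kinematic_split(F[None], lam_p[None], q[None])
        assert np.allclose(kin.Fe[0] @ kin.Fp[0], F, atol=1e-12)

    def test_invalid_plastic_stretch(self):
        with pytest.raises(cst.SolverDivergence):
            cst.kinematic_split(np.eye(3)[None], np.array([[1.0, -0.2, 1.0]]),
                                np.eye(3)[None])


class TestPassiveStress:
    params = cst.MechanicalParams()

    def test_zero_at_reference(self):
        kin = cst.kinematic_split(np.eye(3)[None], np.ones((1, 3)), np.eye(3)[None])
        for kappa in (0.0, 0.17, 1 / 3):
            s = cst.passive_stress(kin, [1.0], [kappa], np.eye(3)[None][:, 0, :],
                                   self.params)
            assert np.abs(s).max() < 1e-14

    def test_residual_stress_scales_with_collagen(self):
        kin = cst.kinematic_split(np.eye(3)[None], np.ones((1, 3)), np.eye(3)[None])
        s = cst.passive_stress(kin, [2.0], [1 / 3], np.eye(3)[None][:, 0, :],
                               self.params)
        assert np.allclose(s[0], 2 * self.params.k0 * (2.0 - 1.0) * np.eye(3))

    def test_energy_consistency_oracle(self, rng):
        """Stress from the analytic derivative matches central differences of
        the energy on 100 random states (relative tolerance 1e-4)."""
        eps = 1e-6
        for _ in range(100):
            F, lam_p, q, phi, kappa = random_state(rng)
            kin = cst.kinematic_split(F[None], lam_p[None], q[None])
            sig = cst.passive_stress(kin, [phi], [kappa], q[None][:, 0, :],
                                     self.params)[0]

            def psi(Fm):
                k = cst.kinematic_split(Fm[None], lam_p[None], q[None])
                return cst.strain_energy(k, [phi], [kappa], self.params)[0]

            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp_ = F.copy(); Fm_ = F.copy()
                    Fp_[i, j] += eps; Fm_[i, j] -= eps
                    P[i, j] = (psi(Fp_) - psi(Fm_)) / (2 * eps)
            # psi is energy per intermediate-configuration volume
            sig_fd = P @ F.T / np.linalg.det(F) * lam_p.prod()
            denom = max(np.abs(sig).max(), 1e-8)
            assert np.abs(sig - sig_fd).max() / denom < 1e-4

    def test_symmetry(self, rng):
        for _ in range(20):
            F, lam_p, q, phi, kappa = random_state(rng)
            kin = cst.kinematic_split(F[None], lam_p[None], q[None])
            s = cst.passive_stress(kin, [phi], [kappa], q[None][:, 0, :], self.params)
            assert np.allclose(s[0], s[0].T, atol=1e-14)

    def test_small_strain_modulus_oracle(self):
        """Uniaxial stress-strain slope matches E implied by (k0, k1)."""
        e_kpa, k0, k1 = cst.moduli_from_composition(0.30)
        params = cst.MechanicalParams(k0=k0, k1=k1, kf=0.0)

        def uniaxial_stress(eps_ax):
            lam_ax = 1.0 + eps_ax

            def lateral_residual(lam_lat):
                F = np.diag([lam_ax, lam_lat, lam_lat])
                kin = cst.kinematic_split(F[None], np.ones((1, 3)), np.eye(3)[None])
                s = cst.passive_stress(kin, [1.0], [1 / 3], np.eye(3)[None][:, 0, :],
                                       params)
                return s[0, 1, 1]

            lam_lat = brentq(lateral_residual, 0.9, 1.1, xtol=1e-14)
            F = np.diag([lam_ax, lam_lat, lam_lat])
            kin = cst.kinematic_split(F[None], np.ones((1, 3)), np.eye(3)[None])
            return cst.passive_stress(kin, [1.0], [1 / 3],
                                      np.eye(3)[None][:, 0, :], params)[0, 0, 0]

        h = 1e-4
        slope = (uniaxial_stress(h) - uniaxial_stress(-h)) / (2 * h)
        assert slope * 1e3 == pytest.approx(e_kpa, rel=0.01)  # MPa -> kPa


class TestActiveStress:
    params = cst.MechanobioParams()

    def test_zero_at_zero_density(self):
        s = cst.active_stress(0.0, 0.5, 0.5, np.array([0.1]), np.array([[1.0, 0, 0]]),
                              self.params)
        assert np.abs(s).max() == 0.0

    def test_isotropic_at_full_dispersion(self):
        s = cst.active_stress(1e5, 0.3, 0.4, np.array([1 / 3]),
                              np.array([[0.3, 0.5, 0.8]]), self.params)
        assert np.allclose(s[0], s[0, 0, 0] * np.eye(3))

    def test_unit_trace_structure_tensor(self, rng):
        for _ in range(10):
            a = rng.standard_normal(3)
            kappa = rng.random() / 3
            s = cst.active_stress(2e5, 0.5, 0.3, np.array([kappa]), a[None],
                                  self.params)
            mag = cst.active_magnitude(2e5, 0.5, 0.3, self.params)
            assert np.trace(s[0]) == pytest.approx(float(mag), rel=1e-12)

    def test_magnitude_peaks_at_K_t(self):
        phis = np.linspace(0.01, 2.0, 400)
        mags = cst.active_magnitude(1.0, 0.0, phis, self.params)
        assert phis[np.argmax(mags)] == pytest.approx(self.params.K_t, abs=0.01)

    def test_objectivity(self, rng):
        """Rotating the fiber vector rotates the stress objectively."""
        a = np.array([0.2, -0.4, 0.9])
        kappa = np.array([0.1])
        s = cst.active_stress(1e5, 0.5, 0.3, kappa, a[None], self.params)[0]
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        s_rot = cst.active_stress(1e5, 0.5, 0.3, kappa, (q @ a)[None], self.params)[0]
        assert np.allclose(s_rot, q @ s @ q.T, atol=1e-12)


class TestMechanosensing:
    def test_midpoint(self):
        assert cst.mechanosensing(1.0, 20.0, 1.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert cst.mechanosensing(10.0, 20.0, 1.0) == pytest.approx(1.0)
        assert cst.mechanosensing(0.0, 20.0, 1.0) < 1e-8

    def test_monotone(self):
        je = np.linspace(0.2, 2.0, 50)
        h = cst.mechanosensing(je, 15.0, 1.0)
        assert np.all(np.diff(h) > 0)

    def test_invalid_gain(self):
        with pytest.raises(ValueError):
            cst.mechanosensing(1.0, -1.0, 1.0)


class TestRuleOfMixtures:
    @pytest.mark.parametrize("frac,expected", [(0.15, 14.5), (0.85, 35.5),
                                               (0.30, 19.0), (0.50, 25.0)])
    def test_values(self, frac, expected):
        assert cst.rule_of_mixtures(frac) == pytest.approx(expected)

    def test_moduli_mapping(self):
        e_kpa, k0, k1 = cst.moduli_from_composition(0.30, poisson=0.45)
        mu = e_kpa * 1e-3 / (2 * 1.45)
        assert k0 == pytest.approx(mu / 2)
        assert k1 == pytest.approx(e_kpa * 1e-3 * 0.45 / (1.45 * 0.1))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cst.rule_of_mixtures(1.2)
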