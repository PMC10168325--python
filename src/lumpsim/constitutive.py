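"""Kinematics and stress laws.

Multiplicative elastic/plastic split ``F = Fe Fp`` with ``Fp`` diagonal in
an orthonormal fiber frame; passive anisotropic hyperelasticity with fiber
dispersion; logistic mechanosensing; active (myo)fibroblast stress; and
the adipose/fibroglandular rule of mixtures for the isotropic moduli.

All functions are vectorized over a leading element axis.  Stresses are in
MPa; the fibroblast density carried by the active stress is in cells/mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

E_ADIPOSE_KPA = 10.0
E_FIBROGLANDULAR_KPA = 40.0

_I3 = np.eye(3)

_EXP_CAP = 50.0


def _capped_exp(x):
    """exp with a C1 linear continuation beyond the overflow guard."""
    x = np.asarray(x, dtype=float)
    safe = np.minimum(x, _EXP_CAP)
    return np.where(x < _EXP_CAP, np.exp(safe),
                    np.exp(_EXP_CAP) * (1.0 + (x - _EXP_CAP)))


def _capped_exp_deriv(x):
    x = np.asarray(x, dtype=float)
    return np.exp(np.minimum(x, _EXP_CAP))


def rule_of_mixtures(fibro_fraction: float) -> float:
    """Homogenized breast Young's modulus (kPa) from the fibroglandular fraction."""
    if not 0.0 <= fibro_fraction <= 1.0:
        raise ValueError("fibroglandular fraction must be in [0, 1]")
    return fibro_fraction * E_FIBROGLANDULAR_KPA + (1.0 - fibro_fraction) * E_ADIPOSE_KPA


def moduli_from_composition(fibro_fraction: float, poisson: float = 0.45):
    """(E_breast kPa, k0 MPa, k1 MPa) for a given fibroglandular fraction.

    The neo-Hookean split uses mu = E / (2 (1 + nu)) with k0 = mu / 2 and
    k1 equal to the Lame first parameter, so that the small-strain limit of
    the strain energy reproduces (E, nu).  nu defaults to 0.45
    (near-incompressible soft tissue).
    """
    e_kpa = rule_of_mixtures(fibro_fraction)
    e_mpa = e_kpa * 1e-3
    mu = e_mpa / (2.0 * (1.0 + poisson))
    lam = e_mpa * poisson / ((1.0 + poisson) * (1.0 - 2.0 * poisson))
    return e_kpa, mu / 2.0, lam


@dataclass
class MechanicalParams:
    """Passive stress-law parameters (MPa unless noted)."""

    k0: float = None
    k1: float = None
    k2: float = 10.0     # fiber exponent (dimensionless); supplement stand-in
    kf: float = 0.05     # fiber stiffness, scar-collagen scale; supplement stand-in
    fibro_fraction: float = 0.30
    poisson: float = 0.45

    def __post_init__(self):
        if self.k0 is None or self.k1 is None:
            _, k0, k1 = moduli_from_composition(self.fibro_fraction, self.poisson)
            self.k0 = self.k0 if self.k0 is not None else k0
            self.k1 = self.k1 if self.k1 is not None else k1
        if min(self.k0, self.k1, self.k2, self.kf) < 0:
            raise ValueError("moduli must be non-negative")


@dataclass
class MechanobioParams:
    """Active-stress and mechanosensing parameters.

    ``t_rho``/``t_rho_c`` are per-cell contractile stresses in
    MPa/(cells/mm^3); saturation constants are dimensionless.  gamma_e,
    theta_e (mechanosensing gain/threshold) and K_t_c are supplement
    stand-ins exposed in config.
    """

    t_rho: float = 2.33548e-7
    t_rho_c: float = 3.28571 * 2.33548e-7
    K_t: float = 0.2
    K_t_c: float = 1.4
    gamma_e: float = 20.0
    theta_e: float = 1.0

    def __post_init__(self):
        if self.t_rho < 0 or self.t_rho_c < 0:
            raise ValueError("contractile stresses must be non-negative")
        if self.K_t <= 0 or self.gamma_e <= 0:
            raise ValueError("K_t and gamma_e must be positive")


@dataclass
class Kinematics:
    """Elastic/plastic split of the deformation gradient (element-wise)."""

    F: np.ndarray
    Fp: np.ndarray
    Fe: np.ndarray
    Je: np.ndarray
    I1e: np.ndarray
    I4e: np.ndarray
    a: np.ndarray  # deformed fiber vector Fe a0


class SolverDivergence(RuntimeError):
    """Non-physical kinematic state (Je <= 0 or singular Fp)."""


def plastic_tensor(lam_p: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Assemble Fp = sum_alpha lambda_alpha^p  e_alpha (x) e_alpha.

    ``lam_p``: (..., 3) plastic stretches; ``frame``: (..., 3, 3) with rows
    a0, s0, n0.
    """
    return np.einsum("...a,...ai,...aj->...ij", lam_p, frame, frame)


def kinematic_split(F: np.ndarray, lam_p: np.ndarray, frame: np.ndarray) -> Kinematics:
    """Split F into elastic and plastic parts and compute elastic invariants."""
    lam_p = np.asarray(lam_p, dtype=float)
    if np.any(lam_p <= 0):
        raise SolverDivergence("non-positive plastic stretch")
    Fp = plastic_tensor(lam_p, frame)
    Fp_inv = np.einsum("...a,...ai,...aj->...ij", 1.0 / lam_p, frame, frame)
    Fe = F @ Fp_inv
    Je = np.linalg.det(Fe)
    if np.any(Je <= 0):
        raise SolverDivergence("non-positive elastic volume ratio")
    I1e = np.einsum("...ij,...ij->...", Fe, Fe)
    a0 = frame[..., 0, :]
    a = np.einsum("...ij,...j->...i", Fe, a0)
    I4e = np.einsum("...i,...i->...", a, a)
    return Kinematics(F=F, Fp=Fp, Fe=Fe, Je=Je, I1e=I1e, I4e=I4e, a=a)


def strain_energy(kin: Kinematics, phi, kappa, params: MechanicalParams):
    """Strain energy density (MPa) of the passive law."""
    phi = np.asarray(phi, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    ef = kappa * kin.I1e + (1.0 - 3.0 * kappa) * kin.I4e - 1.0
    return (
        phi * params.k0 * (kin.I1e - 3.0)
        + 0.5 * params.k1 * (kin.Je - 1.0) ** 2
        - 2.0 * params.k0 * np.log(kin.Je)
        + params.kf / (2.0 * params.k2) * _capped_exp(params.k2 * ef ** 2)
    )


def passive_stress(kin: Kinematics, phi, kappa, a0, params: MechanicalParams):
    """Cauchy stress (MPa) of the passive law, push-forward of 2 dPsi/dCe."""
    phi = np.asarray(phi, dtype=float)[..., None, None]
    kappa = np.asarray(kappa, dtype=float)
    Fe, Je = kin.Fe, kin.Je
    Ce = np.einsum("...ki,...kj->...ij", Fe, Fe)
    Ce_inv = np.linalg.inv(Ce)
    ef = kappa * kin.I1e + (1.0 - 3.0 * kappa) * kin.I4e - 1.0
    A0 = np.einsum("...i,...j->...ij", a0, a0)
    # exponent capped (C1): far outside the physiological range the raw
    # exp() overflows the FD tangent and its kink stalls the line search
    fiber = (params.kf * ef * _capped_exp_deriv(params.k2 * ef ** 2))[..., None, None] * (
        kappa[..., None, None] * _I3 + (1.0 - 3.0 * kappa)[..., None, None] * A0
    )
    S = 2.0 * (
        phi * params.k0 * _I3
        + (0.5 * params.k1 * (Je - 1.0) * Je - params.k0)[..., None, None] * Ce_inv
        + fiber
    )
    sigma = np.einsum("...ik,...kl,...jl->...ij", Fe, S, Fe) / Je[..., None, None]
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def active_magnitude(rho, c, phi, params: MechanobioParams):
    """Scalar active-stress magnitude rho (t_rho + t_rho_c c/(K_t_c + c)) phi/(K_t^2 + phi^2)."""
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    phi = np.asarray(phi, dtype=float)
    force = params.t_rho + params.t_rho_c * c / (params.K_t_c + c)
    return rho * force * phi / (params.K_t ** 2 + phi ** 2)


def active_stress(rho, c, phi, kappa, a, params: MechanobioParams):
    """Active Cauchy stress (MPa) along the normalized structure tensor.

    ``a`` is the (deformed) fiber vector; the structure tensor is
    A = I + (1 - 3 kappa) a (x) a, normalized to unit trace.
    """
    kappa = np.asarray(kappa, dtype=float)
    a = np.asarray(a, dtype=float)
    A = _I3 + (1.0 - 3.0 * kappa)[..., None, None] * np.einsum(
        "...i,...j->...ij", a, a
    )
    trA = np.einsum("...ii->...", A)
    mag = active_magnitude(rho, c, phi, params)
    return (mag / trA)[..., None, None] * A


def mechanosensing(Je, gamma_e: float, theta_e: float):
    """Logistic activation H(Je) = 1 / (1 + exp(-gamma_e (Je - theta_e)))."""
    if gamma_e <= 0:
        raise ValueError("gamma_e must be positive")
    return 1.0 / (1.0 + np.exp(-gamma_e * (np.asarray(Je, dtype=float) - theta_e)))
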