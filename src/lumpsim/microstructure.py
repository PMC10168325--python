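"""Local evolution of collagen, plastic stretches, fiber frame, and dispersion.

State lives at one quadrature point per linear tetrahedron.  Collagen
density ``phi`` is normalized to healthy tissue (= 1); plastic stretches
act along an orthonormal fiber frame (a0, s0, n0); dispersion ``kappa``
is in [0, 1/3] (1/3 = isotropic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi


@dataclass
class MicrostructureParams:
    """Collagen kinetics and remodeling parameters (rates in 1/hr).

    ``p_phi``/``p_phi_c`` come from the calibrated optimum; the remaining
    values are documented supplement stand-ins (``d_phi`` is usually closed
    from the homeostatic steady state, see :func:`close_collagen_decay`).
    """

    p_phi: float = 1.4e-8
    p_phi_c: float = 7.0e-8
    K_phi_c: float = 0.1
    p_phi_e: float = 7.0e-9
    K_phi_rho: float = 5.8          # saturation of deposition with existing collagen
    d_phi: float = 2.0e-4
    d_phi_c: float = 1.0e-8         # cytokine+cell accelerated degradation
    tau_lambda: float = 0.05        # plastic flow constant (tabulated units: 1/hr)
    tau_lambda_units: str = "rate"  # "rate": value IS the baseline flow rate [1/hr];
    #                                 "hours": time constant, reciprocal in the rate
    lam_crit: float = 1.0           # tensile plastic threshold stretch
    lam_crit_c: float = 0.975       # compressive plastic threshold stretch
    plastic_mode: str = "additive"  # rate factor (phi_dot+ + 1/tau) vs (phi_dot+/tau)
    plastic_compression: bool = True
    tau_omega: float = 10.0         # fiber reorientation time constant
    tau_kappa: float = 10.0         # dispersion time constant
    gamma_kappa: float = 5.0        # eigenvalue-ratio power law

    def __post_init__(self):
        if self.lam_crit < 1.0:
            raise ValueError("lam_crit must be >= 1")
        if not 0.0 < self.lam_crit_c <= 1.0:
            raise ValueError("lam_crit_c must be in (0, 1]")
        if self.plastic_mode not in ("additive", "multiplicative"):
            raise ValueError("plastic_mode must be 'additive' or 'multiplicative'")
        if self.tau_lambda_units not in ("rate", "hours"):
            raise ValueError("tau_lambda_units must be 'rate' or 'hours'")


@dataclass
class MicrostructureState:
    """Per-element microstructural fields."""

    phi: np.ndarray      # (E,) collagen density
    lam_p: np.ndarray    # (E, 3) plastic stretches along (a0, s0, n0)
    frame: np.ndarray    # (E, 3, 3) rows a0, s0, n0
    kappa: np.ndarray    # (E,) fiber dispersion

    def copy(self) -> "MicrostructureState":
        return MicrostructureState(
            self.phi.copy(), self.lam_p.copy(), self.frame.copy(), self.kappa.copy()
        )

    @property
    def Jp(self) -> np.ndarray:
        return self.lam_p.prod(axis=1)


def random_frames(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random orthonormal frames (rows a0, s0, n0), det = +1."""
    q, _ = np.linalg.qr(rng.standard_normal((n, 3, 3)))
    det = np.linalg.det(q)
    q[det < 0, 2, :] *= -1.0
    return q


def initialize_state(
    n_elements: int, cavity_mask: np.ndarray, seed: int = 0
) -> MicrostructureState:
    """Intact tissue: phi = 1, kappa = 1/3, random frames; cavity: phi = 0."""
    rng = np.random.default_rng(seed)
    phi = np.ones(n_elements)
    phi[cavity_mask] = 0.0
    lam_p = np.ones((n_elements, 3))
    frame = random_frames(n_elements, rng)
    kappa = np.full(n_elements, 1.0 / 3.0)
    return MicrostructureState(phi=phi, lam_p=lam_p, frame=frame, kappa=kappa)


def collagen_rate(phi, rho, c, H, params: MicrostructureParams):
    """d(phi)/dt: saturating deposition by cells minus (cytokine-boosted) decay."""
    phi = np.asarray(phi, dtype=float)
    c = np.asarray(c, dtype=float)
    production = (
        params.p_phi
        + params.p_phi_c * c / (params.K_phi_c + c)
        + params.p_phi_e * np.asarray(H, dtype=float)
    ) * np.asarray(rho, dtype=float) / (params.K_phi_rho + phi)
    decay = (params.d_phi + c * np.asarray(rho, dtype=float) * params.d_phi_c) * phi
    return production - decay


def close_collagen_decay(
    params: MicrostructureParams, rho_0: float, H_0: float
) -> MicrostructureParams:
    """Set d_phi so that (rho_0, c=0, phi=1, H_0) is a collagen steady state."""
    params.d_phi = (params.p_phi + params.p_phi_e * H_0) * rho_0 / (
        params.K_phi_rho + 1.0
    )
    return params


def _plastic_rate_factor(phi_dot_plus, params: MicrostructureParams):
    base = (
        params.tau_lambda
        if params.tau_lambda_units == "rate"
        else 1.0 / params.tau_lambda
    )
    if params.plastic_mode == "additive":
        return np.asarray(phi_dot_plus, dtype=float) + base
    return np.asarray(phi_dot_plus, dtype=float) * base


def plastic_driving(lam_e, params: MicrostructureParams):
    """Thresholded driving term: <lam_e - lam_crit> minus the compressive branch."""
    lam_e = np.asarray(lam_e, dtype=float)
    drive = np.maximum(lam_e - params.lam_crit, 0.0)
    if params.plastic_compression:
        drive = drive - np.maximum(params.lam_crit_c - lam_e, 0.0)
    return drive


def plastic_update(lam_p, lam_e, phi_dot_plus, dt, params: MicrostructureParams):
    """Explicit update of the plastic stretches (one Euler step).

    ``lam_p``, ``lam_e``: (..., 3); ``phi_dot_plus``: (...,) non-negative.
    """
    if np.any(np.asarray(lam_e) <= 0):
        raise ValueError("elastic stretches must be positive")
    rate = _plastic_rate_factor(phi_dot_plus, params)
    return np.asarray(lam_p, dtype=float) + dt * rate[..., None] * plastic_driving(
        lam_e, params
    )


def plastic_update_implicit(
    lam_tot, lam_p, phi_dot_plus, dt, params: MicrostructureParams
):
    """Unconditionally stable update with the total stretch frozen over dt.

    Uses lam_e = lam_tot / lam_p and solves the implicit-Euler relation
    lam_p' = lam_p + dt k <lam_e(lam_p') - lam_crit> per direction in
    closed form (quadratic), clamping at the thresholds.  Required because
    1/tau_lambda is fast (tens per hour) compared to the mechanics step.
    """
    lam_tot = np.asarray(lam_tot, dtype=float)
    lam_p = np.asarray(lam_p, dtype=float)
    k = _plastic_rate_factor(phi_dot_plus, params)[..., None] * dt
    lam_e = lam_tot / lam_p
    out = lam_p.copy()

    def _root(lam_crit, mask):
        kk = np.broadcast_to(k, lam_p.shape)[mask]
        bq = kk * lam_crit - lam_p[mask]
        return 0.5 * (-bq + np.sqrt(bq ** 2 + 4.0 * kk * lam_tot[mask]))

    tension = lam_e > params.lam_crit
    if np.any(tension):
        new = _root(params.lam_crit, tension)
        # do not flow past the threshold surface
        out[tension] = np.minimum(new, lam_tot[tension] / params.lam_crit)
    if params.plastic_compression:
        compression = lam_e < params.lam_crit_c
        if np.any(compression):
            new = _root(params.lam_crit_c, compression)
            out[compression] = np.maximum(new, lam_tot[compression] / params.lam_crit_c)
    return out


def fiber_reorientation(
    frame, lam1, e1, phi_dot_plus, dt, params: MicrostructureParams, tie_tol=1e-8, lam2=None
):
    """Rotate a0 toward the largest-principal-stretch direction e1.

    ``frame``: (..., 3, 3); rows a0, s0, n0.  If ``lam2`` is given, elements
    with lam1 - lam2 < tie_tol keep their frame (eigenvector not unique).
    Returns a re-orthonormalized frame.
    """
    frame = np.asarray(frame, dtype=float).copy()
    a0 = frame[..., 0, :]
    e1 = np.asarray(e1, dtype=float)
    # eigenvectors have sign ambiguity: rotate toward the nearer of +-e1
    sign = np.where(np.einsum("...i,...i->...", a0, e1) < 0.0, -1.0, 1.0)
    e1 = sign[..., None] * e1
    proj = e1 - np.einsum("...i,...i->...", a0, e1)[..., None] * a0
    rate = (
        np.asarray(lam1, dtype=float)
        / TWO_PI
        * np.asarray(phi_dot_plus, dtype=float)
        / params.tau_omega
    )
    if lam2 is not None:
        rate = np.where(np.asarray(lam1) - np.asarray(lam2) < tie_tol, 0.0, rate)
    a_new = a0 + dt * rate[..., None] * proj
    a_new /= np.linalg.norm(a_new, axis=-1, keepdims=True)
    s0 = frame[..., 1, :]
    s_new = s0 - np.einsum("...i,...i->...", s0, a_new)[..., None] * a_new
    s_new /= np.linalg.norm(s_new, axis=-1, keepdims=True)
    n_new = np.cross(a_new, s_new)
    out = np.stack([a_new, s_new, n_new], axis=-2)
    return out


def dispersion_update(kappa, lam1, lam2, phi_dot_plus, dt, params: MicrostructureParams):
    """kappa' = kappa + dt (phi_dot+/tau_kappa)((1/3)(lam2/lam1)^gamma - kappa)."""
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam2 <= 0) or np.any(lam1 < lam2 - 1e-12):
        raise ValueError("require lam1 >= lam2 > 0")
    target = (lam2 / lam1) ** params.gamma_kappa / 3.0
    rate = np.asarray(phi_dot_plus, dtype=float) / params.tau_kappa
    new = kappa + dt * rate * (target - np.asarray(kappa, dtype=float))
    return np.clip(new, 0.0, 1.0 / 3.0)
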