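"""Fibroblast density and cytokine concentration: sources, fluxes, stepping.

Both fields obey reaction-diffusion equations with zero-flux natural
boundaries.  The fibroblast diffusivity depends on collagen (through the
biphasic migration speed) and on cytokine via Michaelis-Menten kinetics.
Time stepping is implicit Euler with Picard iteration on the nonlinear
coefficients; the decay terms are treated implicitly so homeostasis is a
fixed point of the discrete update.

Units: cm, hours; rho in cells/mm^3, c normalized to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem

log = logging.getLogger(__name__)


def _solve_spd(A, b, x0=None, rtol=1e-12):
    """Jacobi-preconditioned CG; the implicit operators are SPD and
    mass-dominated, so this beats a sparse LU by a wide margin."""
    precond = sp.diags(1.0 / A.diagonal())
    x, info = spla.cg(A, b, x0=x0, rtol=rtol, maxiter=500, M=precond)
    if info != 0:
        x = spla.spsolve(A.tocsc(), b)
    return x

RHO_HEALTHY = 55051.0  # homeostatic fibroblast density, cells/mm^3


@dataclass
class BiochemicalParams:
    """Transport and kinetic parameters (rates 1/hr, diffusivities cm^2/hr).

    ``p_rho_c``, ``d_rho_phi`` and ``Delta`` carry the calibrated optima;
    the migration-speed curve (v_max, mode0, mode1, sigma_ln) and the
    remaining kinetic constants are documented supplement stand-ins.
    ``d_rho`` is normally closed from the homeostatic steady state.
    """

    # fibroblast diffusivity terms
    d_rho_phi: float = 1582.3     # dimensionless scaling of v_rho^2/6
    d_rho_c: float = 0.0          # cytokine-enhanced migration
    d_rho_0: float = 1.0e-5       # baseline diffusivity
    K_rho_c: float = 0.2          # cytokine half-saturation
    D_c: float = 4.0e-4           # cytokine diffusivity
    # fibroblast source
    p_rho: float = 1.0e-3
    p_rho_c: float = 0.015314
    p_rho_e: float = 6.0e-4
    K_rho_rho: float = 4.8e5      # carrying capacity, cells/mm^3
    d_rho: float = 1.15e-3        # death rate; closed by steady state
    # cytokine source
    p_c_rho: float = 0.0
    p_c_e: float = 0.0
    K_c_c: float = 0.5
    d_c: float = 2.5e-3           # decay, ~4-week resolution of the seroma
    # migration speed curve v_rho(phi): log-normal bump, peak shifted by Delta
    Delta: float = 0.0
    v_max: float = 2.4e-3         # cm/hr peak fibroblast speed
    speed_mode0: float = 0.45     # peak collagen density at Delta = 0
    speed_mode1: float = 1.45     # peak collagen density at Delta = 1
    speed_sigma: float = 0.8      # log-space width
    rho_0: float = RHO_HEALTHY

    def __post_init__(self):
        for name in ("d_rho_phi", "d_rho_c", "d_rho_0", "D_c", "p_rho", "p_rho_c",
                     "p_rho_e", "d_rho", "d_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.K_rho_rho <= 0:
            raise ValueError("K_rho_rho must be positive")
        if not 0.0 <= self.Delta <= 1.0:
            raise ValueError("Delta must be in [0, 1]")


def close_homeostasis(params: BiochemicalParams, H_0: float) -> BiochemicalParams:
    """Set d_rho so that (rho_0, c = 0, H_0) is a fibroblast steady state."""
    params.d_rho = (params.p_rho + params.p_rho_e * H_0) * (
        1.0 - params.rho_0 / params.K_rho_rho
    )
    return params


def fibroblast_speed(phi, Delta=None, params: BiochemicalParams | None = None):
    """Biphasic migration speed v_rho(phi) (cm/hr).

    Log-normal-shaped bump vanishing at phi = 0; the peak location moves
    linearly from ``speed_mode0`` to ``speed_mode1`` as Delta goes 0 -> 1.
    """
    p = params or BiochemicalParams()
    d = p.Delta if Delta is None else Delta
    mode = p.speed_mode0 + d * (p.speed_mode1 - p.speed_mode0)
    phi = np.asarray(phi, dtype=float)
    out = np.zeros_like(phi)
    pos = phi > 0
    out[pos] = p.v_max * np.exp(
        -((np.log(phi[pos] / mode)) ** 2) / (2.0 * p.speed_sigma ** 2)
    )
    return out if out.ndim else float(out)


def fibroblast_diffusivity(phi, c, params: BiochemicalParams):
    """D_rho = d_rho_phi v_rho(phi)^2 / 6 + d_rho_c c/(K+c) + d_rho_0."""
    v = fibroblast_speed(phi, params=params)
    c = np.asarray(c, dtype=float)
    return (
        params.d_rho_phi * np.asarray(v) ** 2 / 6.0
        + params.d_rho_c * c / (params.K_rho_c + c)
        + params.d_rho_0
    )


def source_fibroblast(rho, c, H, params: BiochemicalParams):
    """s_rho = (p_rho + p_rho_c c/(K+c) + p_rho_e H)(1 - rho/K_rr) rho - d_rho rho."""
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    growth = (
        params.p_rho
        + params.p_rho_c * c / (params.K_rho_c + c)
        + params.p_rho_e * np.asarray(H, dtype=float)
    )
    return growth * (1.0 - rho / params.K_rho_rho) * rho - params.d_rho * rho


def source_cytokine(rho, c, H, params: BiochemicalParams):
    """s_c = (p_c_rho c + p_c_e H) rho / (K_c_c + c) - d_c c."""
    rho = np.asarray(rho, dtype=float)
    c = np.asarray(c, dtype=float)
    return (params.p_c_rho * c + params.p_c_e * np.asarray(H, dtype=float)) * rho / (
        params.K_c_c + c
    ) - params.d_c * c


@dataclass
class BioFieldState:
    """Nodal fibroblast density and cytokine concentration."""

    rho: np.ndarray
    c: np.ndarray

    def copy(self) -> "BioFieldState":
        return BioFieldState(self.rho.copy(), self.c.copy())


class StepRejection(RuntimeError):
    """Picard iteration for the implicit biochemical step did not converge."""


def step_bio_fields(
    state: BioFieldState,
    points: np.ndarray,
    tets: np.ndarray,
    phi_elem: np.ndarray,
    H_elem: np.ndarray,
    dt: float,
    params: BiochemicalParams,
    max_picard: int = 15,
    tol: float = 1e-7,
    ops: fem.FemOperators | None = None,
    lumped: bool = True,
    forcing: tuple | None = None,
) -> BioFieldState:
    """One implicit-Euler step of the coupled (rho, c) transport equations.

    ``points`` are the *current* (deformed) nodal coordinates; ``phi_elem``
    and ``H_elem`` are the per-element collagen density and mechanosensing
    values frozen over the step.  Negative overshoots are clamped to zero
    with a logged warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ops = ops if ops is not None else fem.FemOperators(points, tets)
    M = ops.mass(lumped=lumped)
    c_elem_old = fem.element_average(tets, state.c)
    D_rho = fibroblast_diffusivity(phi_elem, c_elem_old, params)
    K_rho = ops.stiffness(D_rho)
    K_c = ops.stiffness(params.D_c)

    M_dt = M.multiply(1.0 / dt).tocsr()
    A_c_base = M_dt + K_c
    A_r_base = M_dt + K_rho
    H_nodal = ops.elem_to_nodal(H_elem)
    f_rho, f_c = forcing if forcing is not None else (0.0, 0.0)
    rhs_rho = M @ (state.rho / dt + f_rho)

    rho_new, c_new = state.rho.copy(), state.c.copy()
    converged = False
    for _ in range(max_picard):
        rho_prev, c_prev = rho_new, c_new
        # cytokine: (M/dt + K_c + M[d_c - p_c_rho rho/(K+c)]) c = M(c_old/dt + p_c_e H rho/(K+c))
        denom_e = params.K_c_c + fem.element_average(tets, c_prev)
        rho_e = fem.element_average(tets, rho_prev)
        lin_e = params.d_c - params.p_c_rho * rho_e / denom_e
        A_c = A_c_base + ops.mass(coeff=lin_e, lumped=lumped)
        const_c = params.p_c_e * H_nodal * rho_prev / (
            params.K_c_c + np.maximum(c_prev, 0.0)
        )
        c_new = _solve_spd(A_c, M @ (state.c / dt + const_c + f_c), x0=c_prev)

        # fibroblasts: growth coefficient lagged, death implicit
        c_e = fem.element_average(tets, c_new)
        growth_e = (
            params.p_rho
            + params.p_rho_c * c_e / (params.K_rho_c + np.maximum(c_e, 0.0))
            + params.p_rho_e * H_elem
        ) * (1.0 - rho_e / params.K_rho_rho)
        A_r = A_r_base + ops.mass(coeff=params.d_rho - growth_e, lumped=lumped)
        rho_new = _solve_spd(A_r, rhs_rho, x0=rho_prev)

        dr = np.max(np.abs(rho_new - rho_prev)) / max(np.max(np.abs(rho_new)), 1.0)
        dc = np.max(np.abs(c_new - c_prev)) / max(np.max(np.abs(c_new)), 1e-12)
        if dr < tol and dc < tol:
            converged = True
            break
    if not converged:
        raise StepRejection(
            f"biochemical Picard iteration stalled (drho={dr:.2e}, dc={dc:.2e})"
        )
    for name, arr in (("rho", rho_new), ("c", c_new)):
        neg = arr < 0
        if np.any(neg):
            scale = max(arr.max(), 1e-300)
            level = logging.WARNING if -arr.min() > 1e-3 * scale else logging.DEBUG
            log.log(
                level,
                "clamped %d negative %s values (min %.3e)", neg.sum(), name, arr.min(),
            )
            arr[neg] = 0.0
    return BioFieldState(rho=rho_new, c=c_new)
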