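"""Staggered time integration of the coupled healing model.

Each time step advances (1) the biochemical fields on the deformed
configuration, (2) the local microstructural state (collagen, plastic
stretches, fiber frame, dispersion), and (3) the quasi-static momentum
balance div(sigma_pas + sigma_act) = 0 by Newton iteration with a
finite-difference consistent tangent.  The chest-wall face is fixed; the
outer breast surface is traction-free.

Homeostatic active tone (the active stress of healthy tissue at rho_0,
c = 0, phi = 1, kappa = 1/3) is treated as a balanced prestress and
subtracted, so the intact homeostatic configuration is an exact
equilibrium with zero displacement.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import biochem, constitutive as cst, fem, geometry as geo, microstructure as micro

log = logging.getLogger(__name__)

HOURS_PER_WEEK = 168.0

_I3 = np.eye(3)


class NewtonError(RuntimeError):
    """Quasi-static equilibrium solve failed to converge."""


@dataclass
class SimulationConfig:
    """Full configuration of a coupled (or biochemical-only) run."""

    geometry: geo.GeometrySpec = field(default_factory=geo.GeometrySpec.human)
    bio: biochem.BiochemicalParams = field(default_factory=biochem.BiochemicalParams)
    micro: micro.MicrostructureParams = field(
        default_factory=micro.MicrostructureParams
    )
    mech: cst.MechanicalParams = field(default_factory=cst.MechanicalParams)
    mbio: cst.MechanobioParams = field(default_factory=cst.MechanobioParams)
    weeks: float = 16.0
    dt_hours: float = 1.0
    n_snapshots: int = 196
    seed: int = 0
    bio_only: bool = False
    newton_tol: float = 1e-8
    newton_max_iter: int = 40
    max_halvings: int = 4
    mech_interval: int = 1
    active_baseline_relief: bool = True
    steady_state_closure: bool = True
    store_snapshots: bool = False
    # initial wound state (supplement stand-ins): provisional fibrin matrix
    # inside the cavity, and intact cell density on the wound edge itself
    cavity_phi0: float = 0.03
    seed_interface_cells: bool = True

    def __post_init__(self):
        if self.weeks <= 0 or self.dt_hours <= 0:
            raise ValueError("weeks and dt_hours must be positive")
        if self.n_snapshots > self.n_steps + 1:
            raise ValueError("output cadence exceeds the number of steps")
        if self.steady_state_closure:
            h0 = self.homeostatic_H()
            biochem.close_homeostasis(self.bio, h0)
            micro.close_collagen_decay(self.micro, self.bio.rho_0, h0)

    @property
    def n_steps(self) -> int:
        return int(round(self.weeks * HOURS_PER_WEEK / self.dt_hours))

    def homeostatic_H(self) -> float:
        return float(cst.mechanosensing(1.0, self.mbio.gamma_e, self.mbio.theta_e))


@dataclass
class StateTimeSeries:
    """Scalar summary series (every step) plus optional field snapshots."""

    times_weeks: np.ndarray
    scalars: dict
    snapshots: list = field(default_factory=list)
    snapshot_times: list = field(default_factory=list)
    config: SimulationConfig | None = None

    def qoi(self, name: str, at_weeks=None) -> np.ndarray:
        y = np.asarray(self.scalars[name])
        if at_weeks is None:
            return y
        return np.interp(np.asarray(at_weeks, dtype=float), self.times_weeks, y)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_weeks": self.times_weeks, **self.scalars})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def save_manifest(self, path) -> None:
        from . import __version__

        cfg = asdict(self.config) if self.config is not None else {}
        Path(path).write_text(
            json.dumps({"version": __version__, "config": cfg}, indent=2, default=str)
        )


# ---------------------------------------------------------------------------
# mechanics


def _first_piola(x_elem, grads, state: micro.MicrostructureState, rho_e, c_e,
                 mech: cst.MechanicalParams, mbio: cst.MechanobioParams,
                 relief: float):
    """First Piola-Kirchhoff stress per element from current nodal positions."""
    F = np.einsum("eai,eaj->eij", x_elem, grads)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise cst.SolverDivergence("element inversion (det F <= 0)")
    kin = cst.kinematic_split(F, state.lam_p, state.frame)
    a0 = state.frame[:, 0, :]
    sigma = cst.passive_stress(kin, state.phi, state.kappa, a0, mech)
    sigma = sigma + cst.active_stress(rho_e, c_e, state.phi, state.kappa, kin.a, mbio)
    if relief:
        # homeostatic tone is carried by the collagen: fully relieved in
        # intact tissue (phi = 1), absent in the collagen-free cavity
        sigma = sigma - (relief * np.clip(state.phi, 0.0, 1.0))[:, None, None] * _I3
    Finv_T = np.swapaxes(np.linalg.inv(F), -1, -2)
    return J[:, None, None] * np.einsum("eik,ekj->eij", sigma, Finv_T)


def _internal_force(P, grads, vols, tets, n_nodes):
    fe = vols[:, None, None] * np.einsum("eij,eaj->eai", P, grads)
    f = np.zeros((n_nodes, 3))
    np.add.at(f, tets, fe)
    return f


class MechanicsSolver:
    """Newton solver for quasi-static equilibrium on a fixed reference mesh."""

    def __init__(self, mesh: geo.Mesh, mech, mbio, relief=0.0,
                 tol=1e-8, max_iter=25, fd_eps=1e-6):
        self.mesh = mesh
        self.mech, self.mbio = mech, mbio
        self.relief = relief
        self.tol, self.max_iter, self.fd_eps = tol, max_iter, fd_eps
        self.grads, vols = fem.shape_gradients(mesh.points, mesh.tets)
        self.vols = np.abs(vols)
        free = np.ones(mesh.n_nodes, dtype=bool)
        free[mesh.fixed_nodes()] = False
        self.free_dofs = np.repeat(free, 3)
        # cached scatter pattern for the 12x12 element tangents
        E = mesh.n_elements
        dof = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(E, 12)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        n = 3 * mesh.n_nodes
        keys = rows.astype(np.int64) * n + cols
        self._korder = np.argsort(keys, kind="stable")
        skeys = keys[self._korder]
        self._kstarts = np.flatnonzero(np.r_[True, skeys[1:] != skeys[:-1]])
        ukeys = skeys[self._kstarts]
        self._kindices = (ukeys % n).astype(np.int64)
        counts = np.bincount((ukeys // n).astype(np.int64), minlength=n)
        self._kindptr = np.r_[0, np.cumsum(counts)]
        self._ndofs = n
        # reference residual scale: an O(k0) uniform stress over the mesh
        self.force_scale = float(
            (self.vols[:, None, None] * np.abs(self.grads)).sum() * mech.k0 / 10.0
        )

    def residual(self, u, state, rho_e, c_e):
        x = (self.mesh.points + u)[self.mesh.tets]
        P = _first_piola(x, self.grads, state, rho_e, c_e, self.mech, self.mbio,
                         self.relief)
        return _internal_force(P, self.grads, self.vols, self.mesh.tets,
                               self.mesh.n_nodes)

    def _tangent(self, u, state, rho_e, c_e, f0_elem):
        mesh, eps = self.mesh, self.fd_eps
        E = mesh.n_elements
        x0 = (mesh.points + u)[mesh.tets]
        ke = np.empty((E, 12, 12))
        for a in range(4):
            for i in range(3):
                x = x0.copy()
                x[:, a, i] += eps
                P = _first_piola(x, self.grads, state, rho_e, c_e, self.mech,
                                 self.mbio, self.relief)
                fe = self.vols[:, None, None] * np.einsum(
                    "eij,ebj->ebi", P, self.grads
                )
                ke[:, :, 3 * a + i] = (fe - f0_elem).reshape(E, 12) / eps
        data = np.add.reduceat(ke.ravel()[self._korder], self._kstarts)
        return sp.csr_matrix(
            (data, self._kindices, self._kindptr), shape=(self._ndofs, self._ndofs)
        )

    def solve(self, u0, state, rho_nodal, c_nodal):
        """Newton iteration from initial guess u0; returns the displacement."""
        tets = self.mesh.tets
        rho_e = fem.element_average(tets, rho_nodal)
        c_e = fem.element_average(tets, c_nodal)
        u = u0.copy()
        u.reshape(-1)[~self.free_dofs] = 0.0

        def res_norm(uu):
            r = self.residual(uu, state, rho_e, c_e).reshape(-1)[self.free_dofs]
            return r, np.linalg.norm(r)

        r, rn = res_norm(u)
        rn0 = rn
        self._rn0_max = max(getattr(self, "_rn0_max", 0.0), rn0)
        tol_abs = max(self.tol * self.force_scale, 1e-8 * rn0)
        for it in range(self.max_iter):
            if rn < tol_abs:
                log.debug("newton converged in %d iterations (|R|=%.3e)", it, rn)
                return u
            x0 = (self.mesh.points + u)[tets]
            P0 = _first_piola(x0, self.grads, state, rho_e, c_e, self.mech,
                              self.mbio, self.relief)
            f0_elem = self.vols[:, None, None] * np.einsum(
                "eij,ebj->ebi", P0, self.grads
            )
            K = self._tangent(u, state, rho_e, c_e, f0_elem)
            Kff = K[self.free_dofs][:, self.free_dofs]
            improved = False
            mu = 0.0
            KtK = None
            for _ in range(5):  # Levenberg-Marquardt escalation on stall
                if mu == 0.0:
                    du = spla.spsolve(Kff.tocsc(), -r)
                else:
                    # normal equations give a guaranteed descent direction
                    # for ||R|| even when the raw tangent is indefinite
                    if KtK is None:
                        KtK = (Kff.T @ Kff).tocsc()
                        dK = np.abs(KtK.diagonal())
                        dK[dK == 0] = dK.max() if dK.max() > 0 else 1.0
                    du = spla.spsolve(KtK + sp.diags(mu * dK), -(Kff.T @ r))
                step = 1.0
                for _ in range(6):
                    u_try = u.copy()
                    u_try.reshape(-1)[self.free_dofs] += step * du
                    try:
                        r_try, rn_try = res_norm(u_try)
                    except cst.SolverDivergence:
                        step *= 0.5
                        continue
                    if rn_try < rn or rn_try < tol_abs:
                        u, r, rn = u_try, r_try, rn_try
                        improved = True
                        break
                    step *= 0.5
                if improved:
                    break
                mu = 1e-6 if mu == 0.0 else mu * 100.0
            if not improved:
                # stagnation: the FD tangent loses accuracy under extreme
                # fiber stiffening; accept when the remaining out-of-balance
                # force is small on the mesh force scale
                if rn < self.stagnation_tol():
                    log.warning("newton stagnated at |R|=%.3e (|R0|=%.3e)", rn, rn0)
                    return u
                raise NewtonError(f"line search failed at |R|={rn:.3e}")
        if rn < self.stagnation_tol():
            log.warning("newton stopped at |R|=%.3e (tol %.3e)", rn, tol_abs)
            return u
        raise NewtonError(
            f"no convergence after {self.max_iter} iterations "
            f"(|R|={rn:.3e}, |R0|={rn0:.3e}, tol={tol_abs:.3e}, "
            f"stag={self.stagnation_tol():.3e})"
        )

    def stagnation_tol(self) -> float:
        """Out-of-balance force accepted (with a warning) on stagnation:
        a 1e-4 fraction of the largest load level seen during the run."""
        return max(1e-5 * self.force_scale,
                   1e-4 * getattr(self, "_rn0_max", 0.0))


# ---------------------------------------------------------------------------
# summary operations


def deformed_region_volume(mesh: geo.Mesh, u: np.ndarray, region_code: int) -> float:
    vols = fem.tet_volumes(mesh.points + u, mesh.tets)
    return float(np.abs(vols[mesh.region == region_code]).sum())


def cavity_volume_fraction(mesh: geo.Mesh, u: np.ndarray) -> float:
    """Deformed cavity volume / initial cavity volume."""
    v0 = float(mesh.element_volumes()[mesh.region == geo.REGION_CAVITY].sum())
    if v0 == 0:
        return 1.0
    return deformed_region_volume(mesh, u, geo.REGION_CAVITY) / v0


def permanent_volume_field(state: micro.MicrostructureState) -> np.ndarray:
    """Jp = det Fp = product of plastic stretches, per element."""
    return state.Jp


def surface_deformation(mesh: geo.Mesh, u: np.ndarray) -> float:
    """Maximum inward normal displacement (cm) over the free surface."""
    free = mesh.facet_tags == geo.TAG_FREE
    facets = mesh.facets[free]
    areas, normals = fem.facet_areas_normals(mesh.points, facets)
    n_nodal = np.zeros((mesh.n_nodes, 3))
    np.add.at(n_nodal, facets, np.repeat((areas[:, None] * normals)[:, None, :], 3, axis=1))
    nodes = np.unique(facets)
    nrm = np.linalg.norm(n_nodal[nodes], axis=1, keepdims=True)
    n_hat = n_nodal[nodes] / np.where(nrm > 0, nrm, 1.0)
    inward = -(u[nodes] * n_hat).sum(axis=1)
    return float(max(inward.max(initial=0.0), 0.0))


def _interface_elements(mesh: geo.Mesh) -> np.ndarray:
    """Non-cavity elements sharing at least one node with the cavity."""
    cav_nodes = np.unique(mesh.tets[mesh.region == geo.REGION_CAVITY])
    mask = np.isin(mesh.tets, cav_nodes).any(axis=1)
    return mask & (mesh.region != geo.REGION_CAVITY)


# ---------------------------------------------------------------------------
# driver


def _initial_fields(mesh: geo.Mesh, cfg: SimulationConfig):
    cav_elems = mesh.region == geo.REGION_CAVITY
    cav_nodes = np.unique(mesh.tets[cav_elems]) if cav_elems.any() else np.array([], int)
    rho = np.full(mesh.n_nodes, cfg.bio.rho_0)
    c = np.zeros(mesh.n_nodes)
    if cfg.seed_interface_cells and cav_elems.any():
        # nodes strictly interior to the cavity (all adjacent elements cavity)
        outer_nodes = np.unique(mesh.tets[~cav_elems])
        interior = np.setdiff1d(cav_nodes, outer_nodes)
        rho[interior] = 0.0
    else:
        rho[cav_nodes] = 0.0
    c[cav_nodes] = 1.0
    bio_state = biochem.BioFieldState(rho=rho, c=c)
    micro_state = micro.initialize_state(mesh.n_elements, cav_elems, seed=cfg.seed)
    micro_state.phi[cav_elems] = cfg.cavity_phi0
    return bio_state, micro_state


def _micro_step(mesh, u, bio_state, micro_state, cfg, dt, grads, bio_only=False):
    """Advance collagen (+ plasticity, fiber frame, dispersion) by dt."""
    tets = mesh.tets
    rho_e = fem.element_average(tets, bio_state.rho)
    c_e = fem.element_average(tets, bio_state.c)
    F = np.einsum("eai,eaj->eij", (mesh.points + u)[tets], grads)
    kin = cst.kinematic_split(F, micro_state.lam_p, micro_state.frame)
    H_e = cst.mechanosensing(kin.Je, cfg.mbio.gamma_e, cfg.mbio.theta_e)

    phi_dot = micro.collagen_rate(micro_state.phi, rho_e, c_e, H_e, cfg.micro)
    phi_dot_plus = np.maximum(phi_dot, 0.0)

    if not bio_only:
        Ce = np.einsum("eki,ekj->eij", kin.Fe, kin.Fe)
        lam_e = np.sqrt(
            np.maximum(np.einsum("eai,eij,eaj->ea", micro_state.frame, Ce,
                                 micro_state.frame), 1e-12)
        )
        lam_tot = lam_e * micro_state.lam_p
        micro_state.lam_p = micro.plastic_update_implicit(
            lam_tot, micro_state.lam_p, phi_dot_plus, dt, cfg.micro
        )
        w, v = np.linalg.eigh(Ce)  # ascending
        lam1 = np.sqrt(np.maximum(w[:, 2], 1e-12))
        lam2 = np.sqrt(np.maximum(w[:, 1], 1e-12))
        e1 = v[:, :, 2]
        micro_state.frame = micro.fiber_reorientation(
            micro_state.frame, lam1, e1, phi_dot_plus, dt, cfg.micro, lam2=lam2
        )
        micro_state.kappa = micro.dispersion_update(
            micro_state.kappa, lam1, lam2, phi_dot_plus, dt, cfg.micro
        )
    micro_state.phi = np.maximum(micro_state.phi + dt * phi_dot, 0.0)
    return H_e


def run_simulation(config: SimulationConfig, mesh: geo.Mesh | None = None,
                   progress: bool = False) -> StateTimeSeries:
    """Run the coupled (or biochemical-only) healing simulation."""
    cfg = config
    if mesh is None:
        builder = (geo.build_human_geometry if cfg.geometry.kind == "human"
                   else geo.build_porcine_geometry)
        mesh = builder(cfg.geometry)
    bio_state, micro_state = _initial_fields(mesh, cfg)
    u = np.zeros((mesh.n_nodes, 3))

    relief = 0.0
    if cfg.active_baseline_relief and not cfg.bio_only:
        relief = float(
            cst.active_magnitude(cfg.bio.rho_0, 0.0, 1.0, cfg.mbio) / 3.0
        )
    mech_solver = None
    if not cfg.bio_only:
        mech_solver = MechanicsSolver(
            mesh, cfg.mech, cfg.mbio, relief=relief,
            tol=cfg.newton_tol, max_iter=cfg.newton_max_iter,
        )

    ref_grads, _ = fem.shape_gradients(mesh.points, mesh.tets)
    bio_ops = fem.FemOperators(mesh.points, mesh.tets)  # valid while u == 0

    ctr = mesh.spec.cavity_center() if mesh.spec is not None else np.zeros(3)
    node_probe = int(np.argmin(((mesh.points - ctr) ** 2).sum(axis=1)))
    elem_probe = int(np.argmin(((mesh.element_centroids() - ctr) ** 2).sum(axis=1)))
    cav_mask = mesh.region == geo.REGION_CAVITY
    iface_mask = _interface_elements(mesh)

    names = ["cavity_volume_fraction", "rho_center", "c_center", "phi_center",
             "jp_cavity_mean", "jp_interface_mean", "surface_deformation",
             "max_displacement"]
    scalars = {k: [] for k in names}
    times = []
    snapshots, snapshot_times = [], []
    snap_every = max(1, cfg.n_steps // max(cfg.n_snapshots - 1, 1))

    def record(t_hours):
        times.append(t_hours / HOURS_PER_WEEK)
        scalars["cavity_volume_fraction"].append(cavity_volume_fraction(mesh, u))
        scalars["rho_center"].append(float(bio_state.rho[node_probe]))
        scalars["c_center"].append(float(bio_state.c[node_probe]))
        scalars["phi_center"].append(float(micro_state.phi[elem_probe]))
        jp = micro_state.Jp
        scalars["jp_cavity_mean"].append(
            float(jp[cav_mask].mean()) if cav_mask.any() else 1.0
        )
        scalars["jp_interface_mean"].append(
            float(jp[iface_mask].mean()) if iface_mask.any() else 1.0
        )
        scalars["surface_deformation"].append(surface_deformation(mesh, u))
        scalars["max_displacement"].append(float(np.linalg.norm(u, axis=1).max()))

    def store_fields():
        snapshot_times.append(times[-1])
        snapshots.append({
            "u": u.copy(), "rho": bio_state.rho.copy(), "c": bio_state.c.copy(),
            "phi": micro_state.phi.copy(), "Jp": micro_state.Jp.copy(),
            "kappa": micro_state.kappa.copy(),
        })

    record(0.0)
    if cfg.store_snapshots:
        store_fields()

    u_stale = False  # bio_ops valid for the current u?

    def advance(dt, solve_mech, depth=0):
        """One staggered step of size dt, recursively halving on failure."""
        nonlocal bio_state, u, bio_ops, u_stale
        saved = (bio_state.copy(), micro_state.copy(), u.copy())
        try:
            if cfg.bio_only:
                H_e = np.full(mesh.n_elements, cfg.homeostatic_H())
            else:
                F = np.einsum(
                    "eai,eaj->eij", (mesh.points + u)[mesh.tets], ref_grads
                )
                Je = np.linalg.det(F) / micro_state.Jp
                H_e = cst.mechanosensing(Je, cfg.mbio.gamma_e, cfg.mbio.theta_e)
                if u_stale:
                    bio_ops = fem.FemOperators(mesh.points + u, mesh.tets)
                    u_stale = False
            bio_state = biochem.step_bio_fields(
                bio_state, mesh.points + u, mesh.tets, micro_state.phi, H_e,
                dt, cfg.bio, ops=bio_ops,
            )
            _micro_step(mesh, u, bio_state, micro_state, cfg, dt, ref_grads,
                        bio_only=cfg.bio_only)
            if mech_solver is not None and solve_mech:
                u = mech_solver.solve(u, micro_state, bio_state.rho, bio_state.c)
                u_stale = True
        except (NewtonError, biochem.StepRejection, cst.SolverDivergence) as err:
            if depth >= cfg.max_halvings:
                raise NewtonError(
                    f"step failed after {depth} halvings: {err}"
                ) from err
            log.warning("halving step (depth %d): %s", depth + 1, err)
            bio_state, ms, u = saved
            u_stale = True
            micro_state.phi, micro_state.lam_p = ms.phi, ms.lam_p
            micro_state.frame, micro_state.kappa = ms.frame, ms.kappa
            advance(dt / 2, True, depth + 1)
            advance(dt / 2, True, depth + 1)

    t0 = _time.time()
    for step in range(1, cfg.n_steps + 1):
        solve_mech = (step % cfg.mech_interval == 0) or step == cfg.n_steps
        advance(cfg.dt_hours, solve_mech)
        record(step * cfg.dt_hours)
        if cfg.store_snapshots and (step % snap_every == 0 or step == cfg.n_steps):
            store_fields()
        if progress and (step % max(1, cfg.n_steps // 20) == 0):
            log.info("step %d/%d (t=%.1f wk, V/V0=%.3f, %.1fs)", step, cfg.n_steps,
                     times[-1], scalars["cavity_volume_fraction"][-1],
                     _time.time() - t0)

    return StateTimeSeries(
        times_weeks=np.asarray(times),
        scalars={k: np.asarray(v) for k, v in scalars.items()},
        snapshots=snapshots,
        snapshot_times=snapshot_times,
        config=cfg,
    )


def write_vtu_series(series: StateTimeSeries, mesh: geo.Mesh, out_dir) -> list:
    """Write stored snapshots as a VTU time series; returns the file list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (t, snap) in enumerate(zip(series.snapshot_times, series.snapshots)):
        path = out_dir / f"state_{i:04d}.vtu"
        geo.write_vtu(
            mesh, path,
            point_data={"displacement": snap["u"], "rho": snap["rho"], "c": snap["c"]},
            cell_data={"phi": snap["phi"], "Jp": snap["Jp"], "kappa": snap["kappa"]},
        )
        files.append(str(path))
    return files
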