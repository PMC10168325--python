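import numpy as np
import pytest

from lumpsim import biochem, constitutive as cst, fem
from lumpsim import geometry as geo
from lumpsim import microstructure as micro
from lumpsim import solver
from conftest import unit_box_mesh


def tiny_human_cfg(**kw):
    spec = kw.pop("spec", geo.GeometrySpec.human(h_cavity=1.6, h_far=3.5))
    base = dict(geometry=spec, weeks=0.05, dt_hours=2.0, n_snapshots=2)
    base.update(kw)
    return solver.SimulationConfig(**base)


def box_mesh_region(n=3, region=geo.REGION_BREAST):
    points, tets = unit_box_mesh(n)
    return geo.Mesh(points, tets, np.full(len(tets), region, dtype=np.int32),
                    z_fixed=0.0)


class TestHomeostasis:
    def test_no_wound_is_fixed_point(self):
        cfg = tiny_human_cfg(
            spec=geo.GeometrySpec.human(cavity_radius=0.0, h_cavity=2.0, h_far=3.5),
            weeks=0.1,
        )
        ts = solver.run_simulation(cfg)
        assert ts.scalars["max_displacement"].max() == 0.0
        assert np.abs(ts.scalars["rho_center"] / cfg.bio.rho_0 - 1).max() < 1e-10
        assert np.abs(ts.scalars["phi_center"] - 1).max() < 1e-12
        assert np.all(ts.scalars["cavity_volume_fraction"] == 1.0)

    def test_elastic_only_limit(self):
        """Active stress off, sources off, plastic thresholds out of reach,
        collagen intact: Fp stays identity and nothing moves."""
        cfg = tiny_human_cfg(weeks=0.1, cavity_phi0=1.0,
                             steady_state_closure=False)
        cfg.mbio.t_rho = 0.0
        cfg.mbio.t_rho_c = 0.0
        cfg.micro.lam_crit = 5.0
        cfg.micro.lam_crit_c = 1e-3
        for name in ("p_phi", "p_phi_c", "p_phi_e", "d_phi", "d_phi_c"):
            setattr(cfg.micro, name, 0.0)
        ts = solver.run_simulation(cfg)
        assert ts.scalars["max_displacement"].max() == 0.0
        assert np.all(ts.scalars["jp_cavity_mean"] == 1.0)
        assert np.all(ts.scalars["jp_interface_mean"] == 1.0)
        assert np.all(ts.scalars["cavity_volume_fraction"] == 1.0)


class TestSummaries:
    def test_cavity_fraction_undeformed(self, coarse_human_mesh):
        u = np.zeros((coarse_human_mesh.n_nodes, 3))
        assert solver.cavity_volume_fraction(coarse_human_mesh, u) == 1.0

    def test_cavity_fraction_rigid_translation(self, coarse_human_mesh):
        u = np.tile([0.3, -0.2, 0.15], (coarse_human_mesh.n_nodes, 1))
        assert solver.cavity_volume_fraction(coarse_human_mesh, u) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_cavity_fraction_uniform_compaction(self, coarse_human_mesh):
        alpha = 0.5 ** (1.0 / 3.0)
        u = (alpha - 1.0) * coarse_human_mesh.points
        assert solver.cavity_volume_fraction(coarse_human_mesh, u) == pytest.approx(
            0.5, rel=1e-12
        )

    def test_permanent_volume_initial(self):
        state = micro.initialize_state(20, np.zeros(20, dtype=bool), seed=0)
        assert np.allclose(solver.permanent_volume_field(state), 1.0)

    def test_surface_deformation_zero(self, coarse_human_mesh):
        u = np.zeros((coarse_human_mesh.n_nodes, 3))
        assert solver.surface_deformation(coarse_human_mesh, u) == 0.0

    def test_surface_deformation_indentation(self):
        mesh = box_mesh_region(4)
        d = 0.07
        u = np.zeros((mesh.n_nodes, 3))
        top = mesh.points[:, 2] > 1.0 - 1e-9
        u[top, 2] = -d
        assert solver.surface_deformation(mesh, u) == pytest.approx(d, rel=1e-12)

    def test_outward_motion_ignored(self):
        mesh = box_mesh_region(3)
        u = np.zeros((mesh.n_nodes, 3))
        u[mesh.points[:, 2] > 1 - 1e-9, 2] = +0.2
        assert solver.surface_deformation(mesh, u) == 0.0


class TestMechanicsSolver:
    def test_residual_zero_at_equilibrium(self, coarse_human_mesh):
        mesh = coarse_human_mesh
        cfg = solver.SimulationConfig(geometry=mesh.spec, weeks=0.05, dt_hours=2.0,
                                      n_snapshots=2)
        state = micro.initialize_state(mesh.n_elements,
                                       np.zeros(mesh.n_elements, dtype=bool), seed=0)
        ms = solver.MechanicsSolver(mesh, cfg.mech, cfg.mbio, relief=0.0)
        rho_e = np.zeros(mesh.n_elements)
        r = ms.residual(np.zeros((mesh.n_nodes, 3)), state, rho_e, rho_e)
        assert np.abs(r).max() < 1e-12

    def test_spherical_symmetry(self):
        """Centered contracting core, all-fixed outer sphere: the radial
        displacement field has small angular variance (octant means)."""
        R, rc, h = 3.0, 1.0, 0.3
        ax = np.arange(-R, R + h / 2, h)
        points, tets = geo._box_tets(ax, ax, ax)
        rad = np.linalg.norm(points[tets].mean(axis=1), axis=1)
        keep = rad <= R
        tets = tets[keep]
        region = np.where(rad[keep] <= rc, geo.REGION_CAVITY, geo.REGION_BREAST)
        used = np.unique(tets)
        remap = np.full(len(points), -1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        mesh = geo.Mesh(points[used], remap[tets], region.astype(np.int32),
                        z_fixed=np.inf)  # every boundary facet fixed
        cfg = solver.SimulationConfig(weeks=0.05, dt_hours=2.0, n_snapshots=2)
        state = micro.initialize_state(mesh.n_elements, region == geo.REGION_CAVITY,
                                       seed=0)
        # smooth radial collagen/cell profiles (kappa = 1/3: isotropic stress)
        re = np.linalg.norm(mesh.points[mesh.tets].mean(axis=1), axis=1)
        s = np.clip((re - rc) / (2 * h), 0, 1)
        state.phi[:] = 0.3 + 0.7 * (3 * s ** 2 - 2 * s ** 3)
        rnode = np.linalg.norm(mesh.points, axis=1)
        sn = np.clip((rnode - rc - h) / (2 * h), 0, 1)
        rho_full = 2e5 * (1 - (3 * sn ** 2 - 2 * sn ** 3))
        # soft fiber law: the symmetry property is about the discretization,
        # and gentler stiffening keeps the cold-start ramp cheap
        mech = cst.MechanicalParams(kf=0.015, k2=5.0)
        ms = solver.MechanicsSolver(mesh, mech, cfg.mbio, relief=0.0)
        u = np.zeros((mesh.n_nodes, 3))
        for frac in (0.3, 0.6, 1.0):  # load ramp for the cold start
            u = ms.solve(u, state, frac * rho_full, np.zeros(mesh.n_nodes))
        shell = (rnode > 1.4) & (rnode < 1.9)
        r_hat = mesh.points[shell] / rnode[shell, None]
        u_r = (u[shell] * r_hat).sum(axis=1)
        trend = np.polyval(np.polyfit(rnode[shell], u_r, 1), rnode[shell])
        res = u_r - trend
        octant = ((mesh.points[shell, 0] > 0) * 4 + (mesh.points[shell, 1] > 0) * 2
                  + (mesh.points[shell, 2] > 0))
        means = np.array([res[octant == k].mean() for k in range(8)])
        assert abs(u_r.mean()) > 1e-3  # the core actually pulls inward
        assert means.std() < 0.02 * abs(u_r.mean())


class TestStepControl:
    def test_bio_rejection_triggers_halving(self, monkeypatch):
        calls = {"n": 0}
        orig = biochem.step_bio_fields

        def flaky(*args, **kw):
            calls["n"] += 1
            if calls["n"] == 1:
                raise biochem.StepRejection("synthetic failure")
            return orig(*args, **kw)

        monkeypatch.setattr(solver.biochem, "step_bio_fields", flaky)
        cfg = tiny_human_cfg(weeks=2 / 168, dt_hours=2.0, n_snapshots=2)
        ts = solver.run_simulation(cfg)
        assert calls["n"] >= 3  # failed once, then two half steps

    def test_hard_failure_after_max_halvings(self, monkeypatch):
        def always_fail(*args, **kw):
            raise biochem.StepRejection("synthetic failure")

        monkeypatch.setattr(solver.biochem, "step_bio_fields", always_fail)
        cfg = tiny_human_cfg(weeks=2 / 168, dt_hours=2.0, n_snapshots=2,
                             max_halvings=2)
        with pytest.raises(solver.NewtonError):
            solver.run_simulation(cfg)


class TestTimeSeries:
    def test_qoi_interpolation_and_csv(self, tmp_path):
        ts = solver.StateTimeSeries(
            times_weeks=np.array([0.0, 1.0, 2.0]),
            scalars={"cavity_volume_fraction": np.array([1.0, 0.6, 0.4])},
        )
        assert ts.qoi("cavity_volume_fraction", [0.5])[0] == pytest.approx(0.8)
        path = tmp_path / "s.csv"
        ts.save_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["time_weeks", "cavity_volume_fraction"]
        assert len(df) == 3

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            solver.SimulationConfig(weeks=-1.0)
        with pytest.raises(ValueError):
            solver.SimulationConfig(weeks=0.01, dt_hours=2.0, n_snapshots=50)

    def test_vtu_series_output(self, tmp_path):
        cfg = tiny_human_cfg(store_snapshots=True)
        mesh = geo.build_human_geometry(cfg.geometry)
        ts = solver.run_simulation(cfg, mesh=mesh)
        files = solver.write_vtu_series(ts, mesh, tmp_path)
        assert len(files) == len(ts.snapshot_times)
        back = geo.read_vtu(files[0])
        assert back.n_nodes == mesh.n_nodes
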