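"""Gaussian-process emulation and two-stage calibration.

A :class:`GPSurrogate` maps calibration parameters (normalized to the unit
cube) to time-series quantities of interest.  Calibration minimizes the
RMSE of surrogate predictions against packaged data, and an active
refinement loop adds simulator evaluations where the surrogate predicts
low RMSE but is still uncertain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from .datasets import DataSeries, TABLE1

log = logging.getLogger(__name__)


@dataclass
class ParameterSpace:
    """Named parameters with [low, high] ranges."""

    names: list
    lows: np.ndarray
    highs: np.ndarray
    stage: str = "custom"

    def __post_init__(self):
        self.lows = np.asarray(self.lows, dtype=float)
        self.highs = np.asarray(self.highs, dtype=float)
        if np.any(self.lows >= self.highs):
            raise ValueError("every range must satisfy low < high")

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_unit(self, X):
        return (np.atleast_2d(X) - self.lows) / (self.highs - self.lows)

    def from_unit(self, U):
        return self.lows + np.atleast_2d(U) * (self.highs - self.lows)

    def as_dict(self, x) -> dict:
        return dict(zip(self.names, np.asarray(x, dtype=float)))

    def extended(self, name, low, high) -> "ParameterSpace":
        """Space with one extra input (e.g. CBVP or fibroglandular fraction)."""
        return ParameterSpace(
            self.names + [name],
            np.r_[self.lows, low],
            np.r_[self.highs, high],
            stage=self.stage,
        )

    @classmethod
    def theta_b(cls) -> "ParameterSpace":
        names = ["p_rho_c", "d_rho_phi", "Delta", "p_phi", "p_phi_c"]
        lows = [TABLE1[n][0] for n in names]
        highs = [TABLE1[n][1] for n in names]
        return cls(names, lows, highs, stage="theta_b")

    @classmethod
    def theta_m(cls) -> "ParameterSpace":
        names = ["t_rho", "t_rho_c_ratio", "K_t", "tau_lambda"]
        lows = [TABLE1[n][0] for n in names]
        highs = [TABLE1[n][1] for n in names]
        return cls(names, lows, highs, stage="theta_m")


def lhs_sample(space: ParameterSpace, n: int, seed: int) -> np.ndarray:
    """Latin Hypercube design: one sample in each of n strata per dimension."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=space.dim, seed=seed)
    return space.from_unit(sampler.random(n))


class GPSurrogate:
    """Anisotropic-RBF GP over unit-cube inputs, vectorized over outputs.

    ``output_index`` optionally names slices of the output vector, e.g.
    {"rho_center": slice(0, 196), "phi_center": slice(196, 392)} with
    ``output_times`` giving the time stamp of each column within a slice.
    """

    def __init__(self, space: ParameterSpace, output_times=None, output_index=None,
                 noise: float = 1e-12, n_restarts: int = 5, seed: int = 0):
        self.space = space
        self.output_times = None if output_times is None else np.asarray(output_times)
        self.output_index = output_index or {}
        self.noise = noise
        self.n_restarts = n_restarts
        self.seed = seed
        self.gp = None
        self.X_ = None
        self.Y_ = None

    def fit(self, X, Y) -> "GPSurrogate":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if len(X) < 2:
            raise ValueError("need at least two training points")
        if not np.all(np.isfinite(Y)):
            raise ValueError("training outputs must be finite")
        U = self.space.to_unit(X)
        # duplicated inputs make the covariance singular: jitter them
        _, inverse, counts = np.unique(
            np.round(U, 12), axis=0, return_inverse=True, return_counts=True
        )
        if np.any(counts > 1):
            log.warning("duplicated training inputs; adding jitter")
            rng = np.random.default_rng(self.seed)
            dup = counts[inverse] > 1
            U = U.copy()
            U[dup] += 1e-8 * rng.standard_normal((dup.sum(), U.shape[1]))
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            np.full(self.space.dim, 0.3), (1e-2, 1e2)
        )
        self.gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=self.noise,
            normalize_y=True,
            n_restarts_optimizer=self.n_restarts,
            random_state=self.seed,
        )
        import warnings
        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # restarts routinely hit lbfgs iteration limits; harmless here
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.gp.fit(U, Y)
        self.X_, self.Y_ = X, Y
        return self

    def predict(self, X, return_std: bool = False):
        U = self.space.to_unit(np.atleast_2d(np.asarray(X, dtype=float)))
        if return_std:
            mean, std = self.gp.predict(U, return_std=True)
            return np.atleast_2d(mean), np.atleast_2d(std)
        return np.atleast_2d(self.gp.predict(U))

    def qoi_slice(self, name: str) -> slice:
        if not self.output_index:
            return slice(None)
        return self.output_index[name]


def train_gp(space: ParameterSpace, X, Y, **kw) -> GPSurrogate:
    """Convenience wrapper: build and fit a surrogate."""
    return GPSurrogate(space, **kw).fit(X, Y)


def rmse_objective(surrogate: GPSurrogate, data, normalize: bool = False):
    """Build theta -> RMSE of surrogate predictions against observations.

    ``data`` is a DataSeries (or list of them) whose names must match
    ``surrogate.output_index`` when several quantities are emulated.  With
    ``normalize`` the residual of each series is divided by its data range.
    """
    series = [data] if isinstance(data, DataSeries) else list(data)
    if surrogate.output_times is None:
        raise ValueError("surrogate must carry output_times for RMSE fitting")

    def objective(theta, return_std=False):
        theta = np.atleast_2d(theta)
        mean, std = surrogate.predict(theta, return_std=True)
        sq, var, n = 0.0, 0.0, 0
        for s in series:
            sl = surrogate.qoi_slice(s.name)
            times = surrogate.output_times
            pred = np.vstack(
                [np.interp(s.times_weeks, times, row[sl]) for row in mean]
            )
            pstd = np.vstack(
                [np.interp(s.times_weeks, times, row[sl]) for row in std]
            )
            scale = (s.mean.max() - s.mean.min()) if normalize else 1.0
            scale = scale if scale > 0 else 1.0
            sq = sq + (((pred - s.mean) / scale) ** 2).sum(axis=1)
            var = var + ((pstd / scale) ** 2).sum(axis=1)
            n += len(s.times_weeks)
        rmse = np.sqrt(sq / n)
        if return_std:
            return rmse, np.sqrt(var / n)
        return rmse

    return objective


def minimize_rmse(surrogate: GPSurrogate, objective, seed: int = 0):
    """Global minimization of the (cheap) surrogate RMSE over the ranges."""
    space = surrogate.space
    res = differential_evolution(
        lambda u: float(objective(space.from_unit(u[None]))[0]),
        bounds=[(0.0, 1.0)] * space.dim,
        seed=seed,
        tol=1e-8,
        maxiter=200,
        polish=True,
    )
    return space.from_unit(res.x[None])[0], float(res.fun)


@dataclass
class CalibrationResult:
    """Outcome of (actively refined) surrogate calibration."""

    theta_opt: dict
    rmse: float
    history: list = field(default_factory=list)
    X: np.ndarray = None
    Y: np.ndarray = None
    surrogate: GPSurrogate = None


def active_refine(
    simulator,
    space: ParameterSpace,
    data,
    output_times,
    output_index=None,
    n_init: int = 20,
    rounds: int = 2,
    batch: int = 5,
    n_candidates: int = 256,
    seed: int = 0,
    normalize: bool = False,
) -> CalibrationResult:
    """Fit-refine loop: train on an LHS design, then add simulator runs at
    candidates scoring best on (low predicted RMSE, high predicted variance).

    ``simulator`` maps a parameter vector to the output vector emulated by
    the GP.
    """
    X = lhs_sample(space, n_init, seed)
    Y = np.vstack([simulator(x) for x in X])
    history = []
    best_rmse = np.inf
    best_theta = None
    surrogate = None
    for rnd in range(rounds + 1):
        surrogate = GPSurrogate(
            space, output_times=output_times, output_index=output_index, seed=seed
        ).fit(X, Y)
        objective = rmse_objective(surrogate, data, normalize=normalize)
        theta, rmse = minimize_rmse(surrogate, objective, seed=seed + rnd)
        if rmse < best_rmse:
            best_rmse, best_theta = rmse, theta
        history.append({"round": rnd, "n_train": len(X), "rmse": best_rmse})
        if rnd == rounds:
            break
        cand = lhs_sample(space, n_candidates, seed + 1000 + rnd)
        r, s = objective(cand, return_std=True)
        score = np.argsort(np.argsort(r)) + np.argsort(np.argsort(-s))
        pick = cand[np.argsort(score)[:batch]]
        X = np.vstack([X, pick])
        Y = np.vstack([Y, np.vstack([simulator(x) for x in pick])])
    return CalibrationResult(
        theta_opt=space.as_dict(best_theta),
        rmse=best_rmse,
        history=history,
        X=X,
        Y=Y,
        surrogate=surrogate,
    )


def sweep_surface(
    surrogate: GPSurrogate,
    qoi,
    grid: dict,
    fixed: dict,
    variance_cap: float,
) -> pd.DataFrame:
    """Tabulate a 2-D sweep of one emulated quantity with variance masking.

    ``qoi`` is (name, time_weeks); cells whose predictive std exceeds
    ``variance_cap`` are flagged ``masked`` (the not-well-informed region).
    """
    (p1, v1), (p2, v2) = grid.items()
    g1, g2 = np.meshgrid(np.asarray(v1), np.asarray(v2), indexing="ij")
    pts = []
    for a, b in zip(g1.ravel(), g2.ravel()):
        row = dict(fixed)
        row[p1], row[p2] = a, b
        pts.append([row[n] for n in surrogate.space.names])
    pts = np.asarray(pts)
    mean, std = surrogate.predict(pts, return_std=True)
    name, t = qoi
    sl = surrogate.qoi_slice(name)
    times = surrogate.output_times
    vals = np.array([np.interp(t, times, row[sl]) for row in mean])
    errs = np.array([np.interp(t, times, row[sl]) for row in std])
    return pd.DataFrame(
        {
            p1: g1.ravel(),
            p2: g2.ravel(),
            "value": vals,
            "std": errs,
            "masked": errs >= variance_cap,
        }
    )
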