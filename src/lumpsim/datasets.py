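"""Packaged calibration data, default parameter sets, and config I/O.

The porcine histology table (cavity-center fibroblast and collagen
densities at 1/4/16 weeks) and the human cavity-contraction anchors are
the two calibration datasets.  The contraction series interpolates three
published anchor values; the underlying clinical curve is not tabulated,
so the interpolated series is a documented stand-in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biochem, constitutive as cst, geometry as geo, microstructure as micro
from .solver import SimulationConfig


@dataclass
class DataSeries:
    """A measured quantity over time with uncertainty."""

    name: str
    times_weeks: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    units: str
    note: str = ""

    def __post_init__(self):
        self.times_weeks = np.asarray(self.times_weeks, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.times_weeks) == len(self.mean) == len(self.sd)):
            raise ValueError("times, mean, and sd must have equal lengths")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_weeks": self.times_weeks, "mean": self.mean, "sd": self.sd}
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name="", units="", note="") -> "DataSeries":
        df = pd.read_csv(path)
        return cls(name, df["time_weeks"].values, df["mean"].values,
                   df["sd"].values, units, note)


FIBROBLAST_HEALTHY = (55051.0, 15527.0)  # mean, SD (cells/mm^3)


def porcine_histology_table():
    """Cavity-center fibroblast and collagen densities at 1/4/16 weeks.

    Healthy-tissue reference values are attached as ``healthy`` metadata on
    each series (fibroblasts 55,051 +- 15,527 cells/mm^3; collagen 1 +- 0).
    """
    fib = DataSeries(
        name="fibroblast_density",
        times_weeks=[1.0, 4.0, 16.0],
        mean=[0.0, 377504.0, 215893.0],
        sd=[0.0, 94279.0, 45150.0],
        units="cells/mm^3",
        note="porcine lumpectomy histology, cavity center",
    )
    col = DataSeries(
        name="collagen_density",
        times_weeks=[1.0, 4.0, 16.0],
        mean=[0.0, 1.35, 2.33],
        sd=[0.0, 0.25, 0.35],
        units="phi/phi0",
        note="porcine lumpectomy histology, cavity center",
    )
    fib.healthy = FIBROBLAST_HEALTHY
    col.healthy = (1.0, 0.0)
    return fib, col


def human_contraction_targets() -> DataSeries:
    """Normalized cavity-volume anchors for the human calibration.

    Only three fitted values are published (1 wk, 16 d, 4 wk); t = 0 is the
    pre-contraction state.  Intermediate values come from monotone (PCHIP)
    interpolation and are a stand-in for the untabulated clinical curve.
    """
    return DataSeries(
        name="cavity_volume_fraction",
        times_weeks=[0.0, 1.0, 16.0 / 7.0, 4.0],
        mean=[1.0, 0.6649, 0.2090, 0.3143],
        sd=[0.0, 0.05, 0.05, 0.05],
        units="V/V0",
        note="anchor values; interpolation is a documented stand-in",
    )


def interpolate_series(series: DataSeries, times_weeks) -> np.ndarray:
    """Shape-preserving interpolation of a data series."""
    from scipy.interpolate import PchipInterpolator

    f = PchipInterpolator(series.times_weeks, series.mean)
    return f(np.asarray(times_weeks, dtype=float))


# Sensitivity-sweep constant printed alongside the optimized value; the two
# disagree by two orders of magnitude and are kept verbatim with labels.
T_RHO_OPTIMIZED = 2.33548e-7   # MPa, optimized value
T_RHO_SWEEP_CONSTANT = 1.5e-5  # MPa, constant used in the sensitivity contours

TABLE1 = {
    # name: (low, high, optimum)
    "p_rho_c": (0.0092641, 0.04632, 0.015314),
    "d_rho_phi": (62.6793, 12472.9067, 1582.3),
    "Delta": (0.0, 1.0, 0.0),
    "p_phi": (3.633e-9, 3.633e-7, 1.4e-8),
    "p_phi_c": (3.633e-9, 3.633e-7, 7.0e-8),
    "t_rho": (9.08244e-8, 5.44947e-7, 2.33548e-7),
    "t_rho_c_ratio": (1.0, 5.0, 3.28571),       # multiple of t_rho
    "K_t": (0.1, 0.5, 0.2),
    "tau_lambda": (0.00485, 0.2425, 0.05),      # tabulated units 1/hr
}


@dataclass
class ParamSet:
    """Union of all model parameter blocks with the calibrated optima."""

    bio: biochem.BiochemicalParams = field(default_factory=biochem.BiochemicalParams)
    micro: micro.MicrostructureParams = field(
        default_factory=micro.MicrostructureParams
    )
    mech: cst.MechanicalParams = field(default_factory=cst.MechanicalParams)
    mbio: cst.MechanobioParams = field(default_factory=cst.MechanobioParams)

    def validate_ranges(self) -> list:
        """Return names of calibrated parameters outside their declared range."""
        values = {
            "p_rho_c": self.bio.p_rho_c,
            "d_rho_phi": self.bio.d_rho_phi,
            "Delta": self.bio.Delta,
            "p_phi": self.micro.p_phi,
            "p_phi_c": self.micro.p_phi_c,
            "t_rho": self.mbio.t_rho,
            "t_rho_c_ratio": self.mbio.t_rho_c / self.mbio.t_rho,
            "K_t": self.mbio.K_t,
            "tau_lambda": self.micro.tau_lambda,
        }
        bad = []
        for name, (lo, hi, _) in TABLE1.items():
            if not lo - 1e-12 <= values[name] <= hi + 1e-12:
                bad.append(name)
        return bad


def default_parameters() -> ParamSet:
    """All parameter blocks at the calibrated optima plus documented
    stand-in defaults for values only available in supplementary tables."""
    ps = ParamSet()
    assert ps.validate_ranges() == []
    return ps


# ---------------------------------------------------------------------------
# run configuration files


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("breast_axes", "cavity_axes", "box_size"):
        d["geometry"][key] = list(d["geometry"][key])
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    blocks = {
        "geometry": geo.GeometrySpec,
        "bio": biochem.BiochemicalParams,
        "micro": micro.MicrostructureParams,
        "mech": cst.MechanicalParams,
        "mbio": cst.MechanobioParams,
    }
    kwargs = {}
    for key, cls in blocks.items():
        if key in d:
            block = dict(d.pop(key))
            if key == "geometry":
                for tkey in ("breast_axes", "cavity_axes", "box_size"):
                    if tkey in block:
                        block[tkey] = tuple(block[tkey])
            kwargs[key] = cls(**block)
    kwargs.update(d)
    return SimulationConfig(**kwargs)


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
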