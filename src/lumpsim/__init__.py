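"""Finite-element simulation of breast cavity healing after breast-conserving surgery.

The package couples reaction-diffusion fibroblast/cytokine transport,
collagen deposition and remodeling, and quasi-static elastoplastic tissue
mechanics with active cell contraction, on idealized human and porcine
breast geometries.  A Gaussian-process surrogate workflow supports
calibration and parameter sweeps.
"""

__version__ = "0.1.0"

from .geometry import GeometrySpec, Mesh, build_human_geometry, build_porcine_geometry

__all__ = [
    "GeometrySpec",
    "Mesh",
    "build_human_geometry",
    "build_porcine_geometry",
]


def __getattr__(name):  # lazy: solver pulls in the full stack
    if name in ("SimulationConfig", "StateTimeSeries", "run_simulation"):
        from . import solver

        return getattr(solver, name)
    raise AttributeError(name)
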