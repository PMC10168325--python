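"""Idealized human and porcine breast geometries with lumpectomy cavities.

The human breast is a hemisphere (radius 8.58 cm) resting on a 2-cm chest
wall slab, with a spherical cavity in the upper outer quadrant.  The
porcine breast is a half-ellipsoid (a = b = 2.32 cm, c = 2 cm) embedded in
a 15 x 15 x 2 cm connective-tissue slab, with an ellipsoidal cavity
(a = b = 1.5 cm, c = 0.6 cm) centered 1.15 cm below the apex.

Meshes are graded structured tetrahedral grids (Freudenthal subdivision)
with per-element region labels; labeled volumes converge to the analytic
values at first order in the edge length.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from . import fem

REGION_CAVITY = 0
REGION_BREAST = 1
REGION_CONNECTIVE = 2
REGION_CHEST = 3
REGION_NAMES = {
    REGION_CAVITY: "cavity",
    REGION_BREAST: "breast",
    REGION_CONNECTIVE: "connective",
    REGION_CHEST: "chest",
}

TAG_FIXED = 0
TAG_FREE = 1


class GeometryError(ValueError):
    """Invalid geometry: cavity not contained, bad dimensions, missing labels."""


@dataclass
class GeometrySpec:
    """Dimensions (cm) of an idealized breast + cavity geometry."""

    kind: str = "human"
    breast_radius: float = 8.58          # hemisphere radius (human)
    breast_axes: tuple = (2.32, 2.32, 2.0)   # half-ellipsoid semi-axes (porcine)
    cavity_radius: float = 3.02          # sphere radius (human)
    cavity_axes: tuple = (1.5, 1.5, 0.6)     # ellipsoid semi-axes (porcine)
    cavity_depth: float = 1.15           # apex-to-centroid distance (porcine)
    chest_thickness: float = 2.0         # slab below the hemisphere base (human)
    box_size: tuple = (15.0, 15.0, 2.0)  # connective-tissue slab (porcine)
    # Cavity placement (human): 45 deg azimuth in the upper outer quadrant.
    # z-center = cavity_radius * (1 + cavity_margin); lateral offset is
    # placement_frac of the maximum offset keeping the cavity inside.
    cavity_margin: float = 0.05
    placement_frac: float = 0.9
    # Target edge lengths; None -> derived from the cavity size.
    h_cavity: float | None = None
    h_far: float | None = None
    grade_ratio: float = 1.35

    def __post_init__(self):
        if self.kind not in ("human", "porcine"):
            raise GeometryError(f"unknown geometry kind {self.kind!r}")
        for name in ("breast_radius", "chest_thickness"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.cavity_radius < 0:
            raise GeometryError("cavity_radius must be non-negative")

    # -- analytic quantities -------------------------------------------------

    def breast_volume(self) -> float:
        if self.kind == "human":
            return 2.0 / 3.0 * np.pi * self.breast_radius ** 3
        a, b, c = self.breast_axes
        return 2.0 / 3.0 * np.pi * a * b * c

    def cavity_volume(self) -> float:
        if self.kind == "human":
            return 4.0 / 3.0 * np.pi * self.cavity_radius ** 3
        a, b, c = self.cavity_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def cbvp(self) -> float:
        """Cavity-to-breast volume percentage."""
        return 100.0 * self.cavity_volume() / self.breast_volume()

    def cavity_center(self) -> np.ndarray:
        if self.kind == "porcine":
            a, b, c = self.breast_axes
            return np.array([0.0, 0.0, c - self.cavity_depth])
        r = self.cavity_radius
        if r == 0.0:
            return np.zeros(3)
        R = self.breast_radius
        zc = r * (1.0 + self.cavity_margin)
        reach = R - r * (1.0 + self.cavity_margin)
        if reach < zc:
            raise GeometryError(
                f"cavity radius {r} cm cannot be placed inside hemisphere "
                f"radius {R} cm with margin {self.cavity_margin}"
            )
        rho = self.placement_frac * np.sqrt(max(reach ** 2 - zc ** 2, 0.0))
        return np.array([rho / np.sqrt(2.0), rho / np.sqrt(2.0), zc])

    def validate(self) -> None:
        if self.kind == "human":
            if self.cavity_radius >= self.breast_radius:
                raise GeometryError("cavity larger than breast")
            c = self.cavity_center()  # raises if not placeable
            if np.linalg.norm(c) + self.cavity_radius > self.breast_radius + 1e-12:
                raise GeometryError("cavity intersects the breast surface")
            if self.cavity_radius > 0 and c[2] - self.cavity_radius < -1e-12:
                raise GeometryError("cavity intersects the chest wall")
        else:
            a, b, c = self.breast_axes
            ca, cb, cc = self.cavity_axes
            ctr = self.cavity_center()
            if ctr[2] - cc < -1e-12:
                raise GeometryError("porcine cavity extends below the breast base")
            # sample the cavity surface and require containment in the breast
            th = np.linspace(0, np.pi, 24)
            ph = np.linspace(0, 2 * np.pi, 48)
            T, P = np.meshgrid(th, ph)
            pts = np.stack(
                [
                    ca * np.sin(T) * np.cos(P),
                    cb * np.sin(T) * np.sin(P),
                    ctr[2] + cc * np.cos(T),
                ],
                axis=-1,
            ).reshape(-1, 3)
            inside = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2
            if np.any((pts[:, 2] > 0) & (inside > 1 + 1e-9)):
                raise GeometryError("porcine cavity intersects the breast surface")

    @classmethod
    def human(cls, **kw) -> "GeometrySpec":
        return cls(kind="human", **kw)

    @classmethod
    def porcine(cls, **kw) -> "GeometrySpec":
        return cls(kind="porcine", **kw)


def cbvp_to_cavity_radius(cbvp: float, breast_volume: float) -> float:
    """Radius (cm) of a sphere holding ``cbvp`` percent of ``breast_volume``.

    Raises :class:`GeometryError` if the resulting sphere cannot be placed
    inside the hemisphere implied by ``breast_volume`` (radius must not
    exceed half the hemisphere radius under the quadrant placement rule).
    """
    if cbvp < 0:
        raise GeometryError("cbvp must be non-negative")
    if breast_volume <= 0:
        raise GeometryError("breast volume must be positive")
    r = (3.0 * (cbvp / 100.0) * breast_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    R = (3.0 * breast_volume / (2.0 * np.pi)) ** (1.0 / 3.0)
    if r > 0.5 * R + 1e-12:
        raise GeometryError(
            f"CBVP {cbvp}% gives cavity radius {r:.3f} cm exceeding the "
            f"geometric containment limit {0.5 * R:.3f} cm"
        )
    return float(r)


# ---------------------------------------------------------------------------
# structured graded tetrahedral meshing


def graded_axis(lo, hi, fine_lo, fine_hi, h_fine, h_max, ratio=1.35) -> np.ndarray:
    """1-D node coordinates: uniform ``h_fine`` inside [fine_lo, fine_hi],
    geometrically coarsening outward up to ``h_max``."""
    fine_lo = max(lo, fine_lo)
    fine_hi = min(hi, fine_hi)
    if fine_hi <= fine_lo:  # no fine region inside the range
        n = max(1, int(np.ceil((hi - lo) / h_max)))
        return np.linspace(lo, hi, n + 1)
    n_fine = max(1, int(np.round((fine_hi - fine_lo) / h_fine)))
    pts = list(np.linspace(fine_lo, fine_hi, n_fine + 1))
    h = h_fine
    while pts[-1] < hi - 1e-12:
        h = min(h * ratio, h_max)
        pts.append(min(pts[-1] + h, hi))
    if len(pts) >= 2 and pts[-1] - pts[-2] < 0.4 * h_fine:
        pts.pop(-2)
    h = h_fine
    while pts[0] > lo + 1e-12:
        h = min(h * ratio, h_max)
        pts.insert(0, max(pts[0] - h, lo))
    if len(pts) >= 2 and pts[1] - pts[0] < 0.4 * h_fine:
        pts.pop(1)
    return np.asarray(pts)


# Freudenthal subdivision: 6 tets per hex cell sharing the main diagonal.
_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _box_tets(xs, ys, zs):
    """Tet mesh of the tensor grid; returns (points, tets)."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    ii, jj, kk = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    corners = {}
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                corners[(dx, dy, dz)] = nid(ii + dx, jj + dy, kk + dz)
    tets = []
    for e1, e2, e3 in _PERMS:
        steps = [(0, 0, 0)]
        cur = [0, 0, 0]
        for e in (e1, e2, e3):
            cur = cur.copy()
            cur[e] += 1
            steps.append(tuple(cur))
        tets.append(np.stack([corners[s] for s in steps], axis=1))
    tets = np.concatenate(tets, axis=0)
    # fix orientation so all volumes are positive
    vols = fem.tet_volumes(points, tets)
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    return points, tets


def _classify_human(spec: GeometrySpec, p: np.ndarray) -> np.ndarray:
    lab = np.full(len(p), -1, dtype=np.int32)
    r2 = p[:, 0] ** 2 + p[:, 1] ** 2
    R = spec.breast_radius
    in_hemi = (p[:, 2] >= 0) & (r2 + p[:, 2] ** 2 <= R ** 2)
    in_chest = (p[:, 2] < 0) & (p[:, 2] >= -spec.chest_thickness) & (r2 <= R ** 2)
    lab[in_hemi] = REGION_BREAST
    lab[in_chest] = REGION_CHEST
    if spec.cavity_radius > 0:
        c = spec.cavity_center()
        in_cav = ((p - c) ** 2).sum(axis=1) <= spec.cavity_radius ** 2
        lab[in_cav & in_hemi] = REGION_CAVITY
    return lab


def _classify_porcine(spec: GeometrySpec, p: np.ndarray) -> np.ndarray:
    lab = np.full(len(p), -1, dtype=np.int32)
    a, b, c = spec.breast_axes
    lx, ly, lz = spec.box_size
    in_box = (
        (np.abs(p[:, 0]) <= lx / 2)
        & (np.abs(p[:, 1]) <= ly / 2)
        & (p[:, 2] >= 0)
        & (p[:, 2] <= lz)
    )
    in_breast = (p[:, 2] >= 0) & (
        (p[:, 0] / a) ** 2 + (p[:, 1] / b) ** 2 + (p[:, 2] / c) ** 2 <= 1.0
    )
    lab[in_box] = REGION_CONNECTIVE
    lab[in_breast] = REGION_BREAST
    ca, cb, cc = spec.cavity_axes
    ctr = spec.cavity_center()
    q = p - ctr
    in_cav = (q[:, 0] / ca) ** 2 + (q[:, 1] / cb) ** 2 + (q[:, 2] / cc) ** 2 <= 1.0
    lab[in_cav & in_breast] = REGION_CAVITY
    return lab


@dataclass
class Mesh:
    """Labeled tetrahedral mesh with tagged boundary facets."""

    points: np.ndarray          # (N, 3) cm
    tets: np.ndarray            # (E, 4)
    region: np.ndarray          # (E,) in REGION_NAMES
    z_fixed: float              # facets at z <= z_fixed are Dirichlet-fixed
    facets: np.ndarray = field(default=None, repr=False)
    facet_tags: np.ndarray = field(default=None, repr=False)
    spec: GeometrySpec | None = None

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.region = np.ascontiguousarray(self.region, dtype=np.int32)
        if self.facets is None:
            self.facets = fem.boundary_facets(self.tets)
            z = self.points[self.facets, 2]
            fixed = np.all(z <= self.z_fixed + 1e-9, axis=1)
            self.facet_tags = np.where(fixed, TAG_FIXED, TAG_FREE).astype(np.int32)

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def element_volumes(self) -> np.ndarray:
        return np.abs(fem.tet_volumes(self.points, self.tets))

    def region_volumes(self) -> dict:
        vols = self.element_volumes()
        return {
            name: float(vols[self.region == code].sum())
            for code, name in REGION_NAMES.items()
            if np.any(self.region == code)
        }

    def fixed_nodes(self) -> np.ndarray:
        return np.unique(self.facets[self.facet_tags == TAG_FIXED])

    def element_centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)

    def validate(self) -> None:
        vols = fem.tet_volumes(self.points, self.tets)
        if np.any(vols <= 0):
            raise GeometryError("mesh contains inverted or degenerate elements")
        if not np.all(np.isin(self.region, list(REGION_NAMES))):
            raise GeometryError("unknown region labels present")


def _build(spec: GeometrySpec) -> Mesh:
    spec.validate()
    if spec.kind == "human":
        R, t = spec.breast_radius, spec.chest_thickness
        lo = np.array([-R, -R, -t])
        hi = np.array([R, R, R])
        ctr = spec.cavity_center()
        r = spec.cavity_radius
        h_fine = spec.h_cavity or max(0.25 * r, 0.08 * R) or 0.08 * R
        h_max = spec.h_far or 4.0 * h_fine
        flo, fhi = ctr - 1.1 * r, ctr + 1.1 * r
        classify = _classify_human
        z_fixed = -t
    else:
        lx, ly, lz = spec.box_size
        lo = np.array([-lx / 2, -ly / 2, 0.0])
        hi = np.array([lx / 2, ly / 2, lz])
        ctr = spec.cavity_center()
        ca, cb, cc = spec.cavity_axes
        h_fine = spec.h_cavity or 0.25
        h_max = spec.h_far or 12.0 * h_fine
        flo = ctr - 1.1 * np.array([ca, cb, cc])
        fhi = ctr + 1.1 * np.array([ca, cb, cc])
        classify = _classify_porcine
        z_fixed = 0.0

    axes = [
        graded_axis(lo[d], hi[d], flo[d], fhi[d], h_fine, h_max, spec.grade_ratio)
        for d in range(3)
    ]
    points, tets = _box_tets(*axes)
    centroids = points[tets].mean(axis=1)
    lab = classify(spec, centroids)
    keep = lab >= 0
    tets, lab = tets[keep], lab[keep]
    used = np.unique(tets)
    remap = np.full(points.shape[0], -1, dtype=np.int64)
    remap[used] = np.arange(used.size)
    mesh = Mesh(points[used], remap[tets], lab, z_fixed=z_fixed, spec=spec)
    mesh.validate()
    return mesh


def build_human_geometry(spec: GeometrySpec | None = None) -> Mesh:
    """Mesh the hemisphere + chest-slab human geometry with its cavity."""
    spec = spec or GeometrySpec.human()
    if spec.kind != "human":
        raise GeometryError("build_human_geometry requires kind='human'")
    return _build(spec)


def build_porcine_geometry(spec: GeometrySpec | None = None) -> Mesh:
    """Mesh the half-ellipsoid porcine geometry inside its connective slab."""
    spec = spec or GeometrySpec.porcine()
    if spec.kind != "porcine":
        raise GeometryError("build_porcine_geometry requires kind='porcine'")
    return _build(spec)


# ---------------------------------------------------------------------------
# mesh I/O: ASCII VTU (native dialect, bit-exact round trip) and Gmsh MSH 4.1


def _fmt_floats(arr) -> str:
    return " ".join(f"{v:.17g}" for v in np.asarray(arr).ravel())


def write_vtu(mesh: Mesh, path, point_data=None, cell_data=None) -> None:
    """Write an ASCII VTU file with region labels (and optional extra fields)."""
    n, e = mesh.n_nodes, mesh.n_elements
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="1.0" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{e}">',
        "<Points>",
        '<DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">',
        _fmt_floats(mesh.points),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(map(str, mesh.tets.ravel())),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(map(str, range(4, 4 * e + 1, 4))),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(["10"] * e),
        "</DataArray>",
        "</Cells>",
        "<CellData>",
        '<DataArray type="Int32" Name="region" format="ascii">',
        " ".join(map(str, mesh.region)),
        "</DataArray>",
    ]
    for name, data in (cell_data or {}).items():
        lines += [
            f'<DataArray type="Float64" Name="{name}" format="ascii">',
            _fmt_floats(data),
            "</DataArray>",
        ]
    lines.append("</CellData>")
    lines.append("<PointData>")
    for name, data in (point_data or {}).items():
        data = np.asarray(data)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            _fmt_floats(data),
            "</DataArray>",
        ]
    lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>"]
    meta = {"z_fixed": mesh.z_fixed}
    if mesh.spec is not None:
        meta["spec"] = asdict(mesh.spec)
    lines += [
        f"<!-- lumpsim:{json.dumps(meta)} -->",
        "</VTKFile>",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtu(path) -> Mesh:
    """Read a mesh previously written by :func:`write_vtu`."""
    text = Path(path).read_text()
    meta = {}
    marker = "<!-- lumpsim:"
    if marker in text:
        blob = text.split(marker, 1)[1].split("-->", 1)[0]
        meta = json.loads(blob)
        text = text.replace(marker + blob + "-->", "")
    root = ET.fromstring(text)
    piece = root.find(".//Piece")
    arrays = {da.get("Name"): da for da in piece.iter("DataArray")}
    points = np.fromstring(arrays["Points"].text, sep=" ").reshape(-1, 3)
    tets = np.fromstring(arrays["connectivity"].text, dtype=np.int64, sep=" ").reshape(
        -1, 4
    )
    if "region" not in arrays:
        raise GeometryError(f"{path}: no 'region' cell data; not a labeled mesh")
    region = np.fromstring(arrays["region"].text, dtype=np.int32, sep=" ")
    spec = None
    if "spec" in meta:
        d = dict(meta["spec"])
        for key in ("breast_axes", "cavity_axes", "box_size"):
            d[key] = tuple(d[key])
        spec = GeometrySpec(**d)
    return Mesh(points, tets, region, z_fixed=float(meta.get("z_fixed", 0.0)), spec=spec)


def write_msh(mesh: Mesh, path) -> None:
    """Minimal Gmsh MSH 4.1 ASCII export with region labels as entity tags."""
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    n = mesh.n_nodes
    codes = sorted(set(mesh.region.tolist()))
    lines += ["$Entities", f"0 0 0 {len(codes)}"]
    for c in codes:
        lines.append(f"{c + 1} 0 0 0 0 0 0 1 {c + 1}")
    lines.append("$EndEntities")
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 1 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += [_fmt_floats(p) for p in mesh.points]
    lines.append("$EndNodes")
    lines += ["$Elements", f"{len(codes)} {mesh.n_elements} 1 {mesh.n_elements}"]
    eid = 1
    for c in codes:
        sel = np.where(mesh.region == c)[0]
        lines.append(f"3 {c + 1} 4 {len(sel)}")
        for i in sel:
            a, b_, c_, d = mesh.tets[i] + 1
            lines.append(f"{eid} {a} {b_} {c_} {d}")
            eid += 1
    lines.append("$EndElements")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh(mesh: Mesh, path) -> None:
    path = Path(path)
    if path.suffix == ".vtu":
        write_vtu(mesh, path)
    elif path.suffix == ".msh":
        write_msh(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {path.suffix!r} (use .vtu or .msh)")


def read_mesh(path) -> Mesh:
    path = Path(path)
    if path.suffix == ".vtu":
        return read_vtu(path)
    raise ValueError(f"cannot read mesh format {path.suffix!r} (native dialect is .vtu)")


def refine_spec(spec: GeometrySpec, factor: float) -> GeometrySpec:
    """Spec with edge lengths scaled by ``factor`` (e.g. 0.5 = one refinement)."""
    if spec.kind == "human":
        h0 = spec.h_cavity or max(0.25 * spec.cavity_radius, 0.08 * spec.breast_radius)
        h1 = spec.h_far or 4.0 * h0
    else:
        h0 = spec.h_cavity or 0.25
        h1 = spec.h_far or 12.0 * h0
    return replace(spec, h_cavity=h0 * factor, h_far=h1 * factor)
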