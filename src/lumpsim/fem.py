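"""Linear tetrahedral finite-element primitives.

Vectorized P1 (linear) tetrahedra: element volumes, shape-function
gradients, mass/stiffness assembly, and L2 projections.  All quantities
live on an unstructured tet mesh given as ``points (N, 3)`` and
``tets (E, 4)``.  Lengths are in cm throughout the package.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of each tetrahedron (positive for correct orientation)."""
    p = points[tets]
    d = p[:, 1:] - p[:, :1]  # (E, 3, 3) edge vectors from node 0
    return np.linalg.det(d) / 6.0


def shape_gradients(points: np.ndarray, tets: np.ndarray):
    """Gradients of the four barycentric shape functions.

    Returns
    -------
    grads : (E, 4, 3) array, constant per element
    vols : (E,) positive volumes
    """
    p = points[tets]
    d = np.swapaxes(p[:, 1:] - p[:, :1], 1, 2)  # (E, 3, 3), columns are edges
    vols = np.linalg.det(d) / 6.0
    dinv = np.linalg.inv(d)  # rows are grad N1..N3
    grads = np.empty((tets.shape[0], 4, 3))
    grads[:, 1:, :] = dinv
    grads[:, 0, :] = -dinv.sum(axis=1)
    return grads, vols


def _scatter(tets: np.ndarray, ke: np.ndarray, n_nodes: int) -> sp.csr_matrix:
    """Assemble (E, 4, 4) element matrices into a global CSR matrix."""
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()


def mass_matrix(points, tets, coeff=None, lumped: bool = False) -> sp.csr_matrix:
    """Consistent (or row-lumped) mass matrix with optional per-element coefficient."""
    vols = np.abs(tet_volumes(points, tets))
    if coeff is not None:
        vols = vols * coeff
    base = (np.ones((4, 4)) + np.eye(4)) / 20.0
    ke = vols[:, None, None] * base
    m = _scatter(tets, ke, points.shape[0])
    if lumped:
        return sp.diags(np.asarray(m.sum(axis=1)).ravel()).tocsr()
    return m


def stiffness_matrix(points, tets, diffusivity) -> sp.csr_matrix:
    """Diffusion stiffness matrix with per-element (or scalar) diffusivity."""
    grads, vols = shape_gradients(points, tets)
    d = np.broadcast_to(np.asarray(diffusivity, dtype=float), vols.shape)
    ke = (vols * d)[:, None, None] * np.einsum("eik,ejk->eij", grads, grads)
    return _scatter(tets, ke, points.shape[0])


class FemOperators:
    """Cached-sparsity assembler for repeated mass/stiffness builds.

    The scatter pattern of P1 element matrices never changes, so the
    element-entry -> CSR-slot mapping is computed once and subsequent
    assemblies are a vectorized reduce.
    """

    def __init__(self, points: np.ndarray, tets: np.ndarray):
        self.points = points
        self.tets = tets
        self.n = points.shape[0]
        self.grads, vols = shape_gradients(points, tets)
        self.vols = np.abs(vols)
        rows = np.repeat(tets, 4, axis=1).ravel()
        cols = np.tile(tets, (1, 4)).ravel()
        keys = rows.astype(np.int64) * self.n + cols
        self.order = np.argsort(keys, kind="stable")
        sorted_keys = keys[self.order]
        starts = np.flatnonzero(np.r_[True, sorted_keys[1:] != sorted_keys[:-1]])
        self.starts = starts
        ukeys = sorted_keys[starts]
        self.indices = (ukeys % self.n).astype(np.int32)
        counts = np.bincount((ukeys // self.n).astype(np.int64), minlength=self.n)
        self.indptr = np.r_[0, np.cumsum(counts)].astype(np.int32)
        self._mass_base = (np.ones((4, 4)) + np.eye(4)) / 20.0

    def _to_csr(self, ke: np.ndarray) -> sp.csr_matrix:
        data = np.add.reduceat(ke.ravel()[self.order], self.starts)
        return sp.csr_matrix((data, self.indices, self.indptr), shape=(self.n, self.n))

    def mass(self, coeff=None, lumped=False) -> sp.csr_matrix:
        v = self.vols if coeff is None else self.vols * coeff
        if lumped:
            diag = np.zeros(self.n)
            for a in range(4):
                np.add.at(diag, self.tets[:, a], 0.25 * v)
            return sp.diags(diag).tocsr()
        return self._to_csr(v[:, None, None] * self._mass_base)

    def stiffness(self, diffusivity) -> sp.csr_matrix:
        d = np.broadcast_to(np.asarray(diffusivity, dtype=float), self.vols.shape)
        ke = (self.vols * d)[:, None, None] * np.einsum(
            "eik,ejk->eij", self.grads, self.grads
        )
        return self._to_csr(ke)

    def elem_to_nodal(self, elem_field) -> np.ndarray:
        """Volume-weighted projection of an element field onto nodes."""
        if not hasattr(self, "_node_vol"):
            den = np.zeros(self.n)
            for a in range(4):
                np.add.at(den, self.tets[:, a], self.vols)
            self._node_vol = np.where(den > 0, den, 1.0)
        num = np.zeros(self.n)
        w = self.vols * np.asarray(elem_field, dtype=float)
        for a in range(4):
            np.add.at(num, self.tets[:, a], w)
        return num / self._node_vol


def element_average(tets: np.ndarray, nodal: np.ndarray) -> np.ndarray:
    """Average of a nodal field over each element's four vertices."""
    return nodal[tets].mean(axis=1)


def nodal_from_elements(points, tets, elem_field) -> np.ndarray:
    """Volume-weighted projection of an element field onto nodes (for output)."""
    vols = np.abs(tet_volumes(points, tets))
    num = np.zeros(points.shape[0])
    den = np.zeros(points.shape[0])
    w = vols * np.asarray(elem_field, dtype=float)
    for a in range(4):
        np.add.at(num, tets[:, a], w)
        np.add.at(den, tets[:, a], vols)
    return num / np.where(den > 0, den, 1.0)


def integrate_nodal(points, tets, nodal: np.ndarray) -> float:
    """Integral of a P1 nodal field over the mesh."""
    vols = np.abs(tet_volumes(points, tets))
    return float((vols * nodal[tets].mean(axis=1)).sum())


def l2_error(points, tets, nodal, exact_fn) -> float:
    """L2-norm error of a nodal field against a callable exact solution.

    Uses the 4-point (degree 2) tetrahedral quadrature rule.
    """
    a = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
    b = (5.0 - np.sqrt(5.0)) / 20.0
    bary = np.full((4, 4), b)
    np.fill_diagonal(bary, a)
    vols = np.abs(tet_volumes(points, tets))
    p = points[tets]  # (E, 4, 3)
    vals = nodal[tets]  # (E, 4)
    err2 = np.zeros(len(tets))
    for q in range(4):
        xq = np.einsum("a,eai->ei", bary[q], p)
        uq = vals @ bary[q]
        err2 += 0.25 * (uq - exact_fn(xq)) ** 2
    return float(np.sqrt((vols * err2).sum()))


def boundary_facets(tets: np.ndarray) -> np.ndarray:
    """Facets (triangles) belonging to exactly one tetrahedron.

    Returns an (F, 3) array of node indices with outward orientation not
    guaranteed; use :func:`facet_normals` for oriented normals.
    """
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def facet_areas_normals(points: np.ndarray, facets: np.ndarray):
    """Areas and unit normals of triangular facets (orientation as stored)."""
    p = points[facets]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = 0.5 * np.linalg.norm(n, axis=1)
    with np.errstate(invalid="ignore"):
        units = n / (2.0 * areas[:, None])
    return areas, units
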