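"""Finite-element solution of the stationary current-conduction problem.

Solves div(sigma grad V) = 0 on a tagged triangular mesh with Dirichlet
electrodes at the left (+U/2) and right (-U/2) domain boundaries and zero
normal current on the insulating walls, then recovers E = -grad V.

Elements are Lagrange triangles: quadratic (P2, default -- needed for field
accuracy inside the 5 nm membrane) or linear (P1) behind a flag.  The system
is symmetric positive definite after Dirichlet elimination and is factorised
with sparse LU (deterministic).  Conductivities are rescaled by the geometric
mean of their extremes before assembly; with Dirichlet-only data this leaves
the solution unchanged and only tames the condition number of the
4.11e7 / 5e-7 S/m contrast.

A strongly conducting NP can optionally be treated as a floating
equipotential body: all of its degrees of freedom are merged into one
unknown, which removes the extreme contrast from the operator entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from matplotlib.tri import Triangulation
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import splu

from .geometry import REGION_ID, REGIONS
from .meshing import Mesh
from .model import MaterialProps

__all__ = ["FieldSolution", "SolverError", "assemble_and_solve",
           "treat_conductor_as_equipotential", "solve_submodel"]

#: barycentric quadrature rule, degree-2 exact (enough for P2 stiffness)
_QP = np.array([[2 / 3, 1 / 6, 1 / 6],
                [1 / 6, 2 / 3, 1 / 6],
                [1 / 6, 1 / 6, 2 / 3]])
_QW = np.array([1 / 3, 1 / 3, 1 / 3])

#: P2 midside nodes sit on local edges opposite each vertex
_EDGES = np.array([[1, 2], [2, 0], [0, 1]])


class SolverError(RuntimeError):
    pass


def _element_sigma(mesh: Mesh, materials: dict[str, MaterialProps]) -> np.ndarray:
    missing = [name for name, rid in REGION_ID.items()
               if (mesh.region == rid).any() and name not in materials]
    if missing:
        raise SolverError(f"regions without a conductivity: {missing}")
    table = np.zeros(len(REGIONS))
    for name, rid in REGION_ID.items():
        if name in materials:
            table[rid] = materials[name].conductivity
    sig = table[mesh.region]
    if not (sig > 0).all():
        raise SolverError("every meshed region needs conductivity > 0 "
                          "(use the equipotential treatment for ideal conductors)")
    return sig


def _grad_lambda(nodes: np.ndarray, tris: np.ndarray):
    """Constant barycentric gradients and areas per element."""
    p = nodes[tris]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    area = 0.5 * det
    g = np.empty((len(tris), 3, 2))
    # grad lambda_i = perpendicular of opposite edge / (2A)
    for i in range(3):
        a, b = p[:, (i + 1) % 3], p[:, (i + 2) % 3]
        e = b - a
        g[:, i, 0] = -e[:, 1] / det
        g[:, i, 1] = e[:, 0] / det
    return g, area


def _p2_connectivity(mesh: Mesh):
    """Vertex+midside connectivity: returns (dof array (ne,6), n_dofs,
    midside coordinates)."""
    tris = mesh.tris
    edges = tris[:, _EDGES].reshape(-1, 2)
    edges_sorted = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges_sorted, axis=0, return_inverse=True)
    nv = len(mesh.nodes)
    dof = np.hstack([tris, nv + inv.reshape(-1, 3)])
    mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    return dof, nv + len(uniq), mid


def _shape_gradients(glam: np.ndarray, lam: np.ndarray, order: int):
    """Gradients of all shape functions at one barycentric point.

    glam: (ne,3,2) gradients of lambda; lam: (3,) point.
    Returns (ne, ndof_local, 2).
    """
    if order == 1:
        return glam
    ne = len(glam)
    G = np.empty((ne, 6, 2))
    for i in range(3):
        G[:, i] = (4 * lam[i] - 1) * glam[:, i]
    for a, (i, j) in enumerate(_EDGES):
        G[:, 3 + a] = 4 * (lam[i] * glam[:, j] + lam[j] * glam[:, i])
    return G


@dataclass
class FieldSolution:
    """Nodal potential plus derived per-element field for one solve."""

    mesh: Mesh
    potentials: np.ndarray        # (n_dofs,) V; vertices first, then midsides
    drive: float                  # applied voltage U
    order: int
    materials: dict[str, MaterialProps]
    dof: np.ndarray               # (ne, 3) or (ne, 6)
    _K_full: csr_matrix = field(repr=False, default=None)

    @cached_property
    def _glam(self):
        return _grad_lambda(self.mesh.nodes, self.mesh.tris)

    @cached_property
    def field_vectors(self) -> np.ndarray:
        """E = -grad V per element, evaluated at the element centroid (V/m)."""
        glam, _ = self._glam
        lam = np.array([1 / 3, 1 / 3, 1 / 3])
        G = _shape_gradients(glam, lam, self.order)
        Ve = self.potentials[self.dof]
        return -np.einsum("ea,eak->ek", Ve, G)

    @cached_property
    def _trifinder(self):
        tri = Triangulation(self.mesh.nodes[:, 0], self.mesh.nodes[:, 1],
                            self.mesh.tris)
        return tri.get_trifinder()

    def _locate(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        idx = self._trifinder(pts[:, 0], pts[:, 1])
        if (idx < 0).any():
            bad = pts[np.asarray(idx) < 0][0]
            raise SolverError(f"query point outside the domain: {bad}")
        return np.asarray(idx)

    def _bary(self, pts: np.ndarray, idx: np.ndarray) -> np.ndarray:
        p = self.mesh.nodes[self.mesh.tris[idx]]
        T = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=-1)
        rhs = pts - p[:, 0]
        det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
        l1 = (rhs[:, 0] * T[:, 1, 1] - rhs[:, 1] * T[:, 0, 1]) / det
        l2 = (-rhs[:, 0] * T[:, 1, 0] + rhs[:, 1] * T[:, 0, 0]) / det
        return np.stack([1 - l1 - l2, l1, l2], axis=1)

    def field_at(self, pts) -> np.ndarray:
        """E vectors (V/m) at arbitrary points via element-wise interpolation;
        a point on an element edge uses the element the point locator
        assigns, deterministically."""
        pts = np.atleast_2d(np.asarray(pts, float))
        idx = self._locate(pts)
        lam = self._bary(pts, idx)
        glam, _ = self._glam
        out = np.empty_like(pts)
        Ve = self.potentials[self.dof[idx]]
        gl = glam[idx]
        if self.order == 1:
            G = gl
        else:
            G = np.empty((len(pts), 6, 2))
            for i in range(3):
                G[:, i] = (4 * lam[:, i, None] - 1) * gl[:, i]
            for a, (i, j) in enumerate(_EDGES):
                G[:, 3 + a] = 4 * (lam[:, i, None] * gl[:, j]
                                   + lam[:, j, None] * gl[:, i])
        out = -np.einsum("pa,pak->pk", Ve, G)
        return out

    def potential_at(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        idx = self._locate(pts)
        lam = self._bary(pts, idx)
        Ve = self.potentials[self.dof[idx]]
        if self.order == 1:
            N = lam
        else:
            N = np.empty((len(pts), 6))
            for i in range(3):
                N[:, i] = lam[:, i] * (2 * lam[:, i] - 1)
            for a, (i, j) in enumerate(_EDGES):
                N[:, 3 + a] = 4 * lam[:, i] * lam[:, j]
        return np.einsum("pa,pa->p", Ve, N)

    def electrode_current(self, side: str) -> float:
        """Net current (A per metre of depth) through an electrode, computed
        with the consistent boundary-residual method r = K V."""
        r = self._K_full @ self.potentials
        nodes = set(self.mesh.boundary_nodes(side).tolist())
        if self.order == 2:
            # midside dofs on the electrode
            xmin, xmax, _, _ = self.mesh.box
            x = {"left": xmin, "right": xmax}[side]
            mids = np.nonzero(np.abs(self._mid_coords[:, 0] - x)
                              < 1e-9 * self.mesh.geom.width)[0]
            nodes |= set((len(self.mesh.nodes) + mids).tolist())
        return float(r[sorted(nodes)].sum())

    def check_max_principle(self, tol_factor: float = 1e-6) -> None:
        lo, hi = -self.drive / 2, self.drive / 2
        tol = tol_factor * max(self.drive, 1e-300)
        vmin, vmax = float(self.potentials.min()), float(self.potentials.max())
        if vmin < lo - tol or vmax > hi + tol:
            raise SolverError(
                f"discrete maximum principle violated: range [{vmin}, {vmax}] "
                f"outside [{lo}, {hi}] +- {tol}")


def _assemble(mesh: Mesh, sig: np.ndarray, order: int):
    glam, area = _grad_lambda(mesh.nodes, mesh.tris)
    if order == 1:
        dof, ndof, mid = mesh.tris, len(mesh.nodes), None
        nl = 3
    else:
        dof, ndof, mid = _p2_connectivity(mesh)
        nl = 6
    Ke = np.zeros((len(mesh.tris), nl, nl))
    for lam, w in zip(_QP, _QW):
        G = _shape_gradients(glam, lam, order)
        Ke += w * np.einsum("eik,ejk->eij", G, G)
    Ke *= (sig * area)[:, None, None]
    rows = np.repeat(dof, nl, axis=1).ravel()
    cols = np.tile(dof, (1, nl)).ravel()
    K = coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K, dof, ndof, mid


def _dirichlet_dofs(mesh: Mesh, order: int, mid: np.ndarray | None,
                    drive: float):
    """Electrode dofs and values.  Full-domain meshes: left/right electrodes
    at +-drive/2.  Window meshes: handled by solve_submodel instead."""
    xmin, xmax, _, _ = mesh.box
    tol = 1e-9 * mesh.geom.width
    fixed, vals = [], []
    for side, x, v in (("left", xmin, drive / 2), ("right", xmax, -drive / 2)):
        idx = mesh.boundary_nodes(side)
        fixed.append(idx)
        vals.append(np.full(len(idx), v))
        if order == 2:
            mids = np.nonzero(np.abs(mid[:, 0] - x) < tol)[0]
            fixed.append(len(mesh.nodes) + mids)
            vals.append(np.full(len(mids), v))
    return np.concatenate(fixed), np.concatenate(vals)


def _solve_dirichlet(K, ndof, fixed_idx, fixed_vals):
    if len(fixed_idx) == 0:
        raise SolverError("singular system: no Dirichlet data")
    fixed = np.zeros(ndof, bool)
    fixed[fixed_idx] = True
    x = np.zeros(ndof)
    x[fixed_idx] = fixed_vals
    free = ~fixed
    Kff = K[free][:, free].tocsc()
    b = -K[free][:, fixed_idx] @ fixed_vals
    try:
        lu = splu(Kff)
    except RuntimeError as exc:  # pragma: no cover
        raise SolverError(f"factorisation failed: {exc}") from exc
    sol = lu.solve(b)
    if not np.isfinite(sol).all():
        raise SolverError("solver produced non-finite values")
    # iterative refinement: the 4.11e7 / 5e-7 S/m contrast costs the direct
    # factorisation several digits, which refinement recovers cheaply.
    # Convergence is judged row-wise (|K||x| + |b| weighting), the proper
    # componentwise backward-error measure for a badly scaled operator.
    absK = Kff.copy()
    absK.data = np.abs(absK.data)
    for _ in range(5):
        rownorm = absK @ np.abs(sol) + np.abs(b) + 1e-300
        res = b - Kff @ sol
        berr = float(np.abs(res / rownorm).max())
        if berr <= 1e-12:
            break
        sol = sol + lu.solve(res)
    rownorm = absK @ np.abs(sol) + np.abs(b) + 1e-300
    berr = float(np.abs((b - Kff @ sol) / rownorm).max())
    if berr > 1e-10:
        raise SolverError(f"poor componentwise backward error {berr:.2e}")
    x[free] = sol
    return x


def assemble_and_solve(mesh: Mesh, materials: dict[str, MaterialProps],
                       drive: float, order: int = 2,
                       equipotential_np: bool = False) -> FieldSolution:
    """Solve the conduction problem on a full-domain mesh.

    ``materials`` maps region names (exterior/membrane/cytoplasm/
    nanoparticle) to properties; only conductivity enters the operator.
    ``equipotential_np=True`` replaces the NP interior by a single floating
    unknown (see :func:`treat_conductor_as_equipotential`).
    """
    sig = _element_sigma(mesh, materials)
    # conditioning: rescale by the geometric mean of the extremes
    scale = float(np.sqrt(sig.min() * sig.max()))
    K, dof, ndof, mid = _assemble(mesh, sig / scale, order)
    fixed_idx, fixed_vals = _dirichlet_dofs(mesh, order, mid, drive)

    if equipotential_np:
        np_dofs = np.unique(dof[mesh.region == REGION_ID["nanoparticle"]])
        if len(np_dofs) == 0:
            raise SolverError("no nanoparticle region to treat as equipotential")
        dofmap = np.arange(ndof)
        dofmap[np_dofs] = np_dofs[0]
        # compress
        uniq, dofmap = np.unique(dofmap, return_inverse=True)
        Kc = coo_matrix((K.tocoo().data,
                         (dofmap[K.tocoo().row], dofmap[K.tocoo().col])),
                        shape=(len(uniq), len(uniq))).tocsr()
        x = _solve_dirichlet(Kc, len(uniq), dofmap[fixed_idx], fixed_vals)
        pot = x[dofmap]
    else:
        pot = _solve_dirichlet(K, ndof, fixed_idx, fixed_vals)

    sol = FieldSolution(mesh=mesh, potentials=pot, drive=drive, order=order,
                        materials=materials, dof=dof, _K_full=K)
    sol._mid_coords = mid
    sol.check_max_principle()
    return sol


def treat_conductor_as_equipotential(mesh: Mesh,
                                     materials: dict[str, MaterialProps],
                                     drive: float, order: int = 2) -> FieldSolution:
    """Floating-potential treatment of a strongly conducting NP.

    Valid only when the NP conductivity dominates every other medium by
    orders of magnitude (gold: 4.11e7 S/m vs 1.5 S/m); flagging a poorly
    conducting NP (silica) this way is a usage error.
    """
    np_mat = materials.get("nanoparticle")
    if np_mat is None:
        raise SolverError("no nanoparticle material bound")
    others = max(m.conductivity for k, m in materials.items()
                 if k != "nanoparticle")
    if np_mat.conductivity < 100 * others:
        raise SolverError(
            f"region '{np_mat.name}' is not strongly conductive "
            f"({np_mat.conductivity} vs {others} S/m); equipotential "
            "treatment would be unphysical")
    return assemble_and_solve(mesh, materials, drive, order=order,
                              equipotential_np=True)


def solve_submodel(sub_mesh: Mesh, global_solution: FieldSolution,
                   materials: dict[str, MaterialProps] | None = None,
                   order: int = 2) -> FieldSolution:
    """Solve a window mesh with Dirichlet data interpolated from a global
    solve on all four window edges (two-stage submodeling)."""
    if not sub_mesh.geom.is_window:
        raise SolverError("solve_submodel expects a window mesh")
    if materials is None:
        materials = global_solution.materials
    sig = _element_sigma(sub_mesh, materials)
    scale = float(np.sqrt(sig.min() * sig.max()))
    K, dof, ndof, mid = _assemble(sub_mesh, sig / scale, order)
    # Dirichlet on the whole submesh boundary (the cut): boundary edges are
    # those incident to exactly one element
    tris = sub_mesh.tris
    edges = np.sort(tris[:, [[0, 1], [1, 2], [2, 0]]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bnd_edges = uniq[counts == 1]
    bidx = np.unique(bnd_edges)
    coords = [sub_mesh.nodes[bidx]]
    fixed = [bidx]
    if order == 2:
        # midside dofs of the boundary edges
        all_edges = np.sort(tris[:, _EDGES].reshape(-1, 2), axis=1)
        euniq, inv = np.unique(all_edges, axis=0, return_inverse=True)
        key = {tuple(e): i for i, e in enumerate(euniq)}
        midx = np.array(sorted(key[tuple(e)] for e in map(tuple, bnd_edges)))
        coords.append(mid[midx])
        fixed.append(len(sub_mesh.nodes) + midx)
    coords = np.vstack(coords)
    fixed = np.concatenate(fixed)
    vals = global_solution.potential_at(coords)
    pot = _solve_dirichlet(K, ndof, fixed, vals)
    sol = FieldSolution(mesh=sub_mesh, potentials=pot,
                        drive=global_solution.drive, order=order,
                        materials=materials, dof=dof, _K_full=K)
    sol._mid_coords = mid
    return sol
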