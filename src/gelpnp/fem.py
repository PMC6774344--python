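"""Small nodal-Lagrange finite-element core on intervals and triangles.

Supports orders 1-3 in 1D and 1-2 on triangles, Gauss quadrature exact for
the bilinear forms of the transport problem (degree 2*order), vectorized
assembly of the mass, stiffness, drift and weighted-stiffness operators into
scipy.sparse matrices, and Dirichlet row constraints.  This is the machinery
behind the Poisson-Nernst-Planck weak forms; it carries no physics itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .errors import DimensionError, OptionError
from .geometry import Mesh

__all__ = ["Discretization", "FunctionSpace", "lumped_mass_matrix"]


@dataclass(frozen=True)
class Discretization:
    """Element family and order of the shared scalar function space.

    All three fields (both concentrations and the potential) use the same
    nodal Lagrange space on the same mesh, stacked as (c+, c-, psi).
    """

    order: int = 2
    element_family: str = "Lagrange"
    lumped_mass: bool = False

    def __post_init__(self):
        if self.element_family != "Lagrange":
            raise OptionError("only nodal Lagrange elements are supported")
        if self.order not in (1, 2, 3):
            raise OptionError("order must be 1, 2 or 3")


# ----------------------------------------------------------------- reference

@lru_cache(maxsize=None)
def _interval_basis(order: int, nq: int):
    """1D Lagrange basis on [0,1]: nodes, quad (pts, wts), N (nq,nd), dN."""
    # local node order: endpoints first (shared vertices), then interior
    interior = [(i + 1) / order for i in range(order - 1)]
    xs = np.array([0.0, 1.0] + interior)
    q, w = np.polynomial.legendre.leggauss(nq)
    q = 0.5 * (q + 1.0)
    w = 0.5 * w
    V = np.vander(xs, increasing=True)
    C = np.linalg.inv(V)  # basis_j(x) = sum_m C[m, j] x^m
    P = np.vander(q, N=order + 1, increasing=True)
    dP = np.zeros_like(P)
    for m in range(1, order + 1):
        dP[:, m] = m * q ** (m - 1)
    N = P @ C
    dN = dP @ C
    return xs, q, w, N, dN[..., None]  # gradient axis last


# Dunavant symmetric triangle rules on the reference triangle (area 1/2),
# given as barycentric points and weights summing to one (scaled by 1/2).
_TRI_RULES = {
    2: (
        np.array([[2 / 3, 1 / 6, 1 / 6],
                  [1 / 6, 2 / 3, 1 / 6],
                  [1 / 6, 1 / 6, 2 / 3]]),
        np.full(3, 1 / 3),
    ),
    4: (
        np.array(
            [
                [0.108103018168070, 0.445948490915965, 0.445948490915965],
                [0.445948490915965, 0.108103018168070, 0.445948490915965],
                [0.445948490915965, 0.445948490915965, 0.108103018168070],
                [0.816847572980459, 0.091576213509771, 0.091576213509771],
                [0.091576213509771, 0.816847572980459, 0.091576213509771],
                [0.091576213509771, 0.091576213509771, 0.816847572980459],
            ]
        ),
        np.array(
            [0.223381589678011] * 3 + [0.109951743655322] * 3
        ),
    ),
}


def _triangle_basis(order: int, degree: int):
    """Triangle Lagrange basis: quad (barycentric pts, wts), N, dN(ref)."""
    lam, w = _TRI_RULES[min(4, max(2, degree))]
    w = 0.5 * w  # reference triangle area
    l0, l1, l2 = lam[:, 0], lam[:, 1], lam[:, 2]
    # gradients of barycentric coords wrt (xi, eta)
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    if order == 1:
        N = lam.copy()
        dN = np.broadcast_to(dlam, (len(w), 3, 2)).copy()
        return w, N, dN
    # P2: vertices then edges (0,1), (1,2), (2,0)
    N = np.column_stack([
        l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
        4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0,
    ])
    dN = np.zeros((len(w), 6, 2))
    ls = [l0, l1, l2]
    for v in range(3):
        dN[:, v, :] = (4 * ls[v] - 1)[:, None] * dlam[v]
    for e, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
        dN[:, 3 + e, :] = 4 * (ls[i][:, None] * dlam[j] + ls[j][:, None] * dlam[i])
    return w, N, dN


# -------------------------------------------------------------------- space

class FunctionSpace:
    """Scalar nodal Lagrange space on a Mesh with precomputed assembly data.

    Attributes
    ----------
    ndof : number of scalar degrees of freedom
    cell_dofs : (n_cells, nd) global dof indices per cell
    dof_coords : (ndof, dim) coordinates of the nodal dofs
    W : (n_cells, nq) quadrature weights times |J|
    N : (nq, nd) basis values at reference quadrature points
    G : (n_cells, nq, nd, dim) physical basis gradients
    Xq : (n_cells, nq, dim) physical quadrature points
    """

    def __init__(self, mesh: Mesh, disc: Discretization | int = 2):
        if isinstance(disc, int):
            disc = Discretization(order=disc)
        if mesh.dim == 2 and disc.order == 3:
            raise OptionError("cubic triangles are not implemented; use order 1 or 2")
        self.mesh = mesh
        self.disc = disc
        self.order = disc.order
        if mesh.dim == 1:
            self._build_1d()
        else:
            self._build_2d()
        nd = self.cell_dofs.shape[1]
        self._rows = np.repeat(self.cell_dofs, nd, axis=1).ravel()
        self._cols = np.tile(self.cell_dofs, (1, nd)).ravel()
        self._compute_quad_coords()

    # -- construction -------------------------------------------------

    def _build_1d(self):
        mesh, p = self.mesh, self.order
        xs_ref, _, wq, N, dN = _interval_basis(p, p + 1)
        nv = mesh.n_nodes
        nc = mesh.n_cells
        n_interior = p - 1
        self.ndof = nv + nc * n_interior
        cd = np.empty((nc, p + 1), dtype=np.int64)
        cd[:, 0] = mesh.cells[:, 0]
        cd[:, 1] = mesh.cells[:, 1]
        for j in range(n_interior):
            cd[:, 2 + j] = nv + np.arange(nc) * n_interior + j
        self.cell_dofs = cd
        x0 = mesh.nodes[mesh.cells[:, 0], 0]
        x1 = mesh.nodes[mesh.cells[:, 1], 0]
        h = (x1 - x0)
        coords = np.empty((self.ndof, 1))
        coords[:nv, 0] = mesh.nodes[:, 0]
        for j in range(n_interior):
            coords[cd[:, 2 + j], 0] = x0 + xs_ref[2 + j] * h
        self.dof_coords = coords
        self.W = wq[None, :] * h[:, None]
        self.N = N
        # physical gradient: dN/dx = dN/dxi / h
        self.G = (dN[None, :, :, :] / h[:, None, None, None])

    def _build_2d(self):
        mesh, p = self.mesh, self.order
        wq, N, dN = _triangle_basis(p, 2 * p)
        nv = mesh.n_nodes
        cells = mesh.cells
        if p == 1:
            self.ndof = nv
            self.cell_dofs = cells.astype(np.int64)
            self.dof_coords = mesh.nodes.copy()
        else:
            edges = {}
            cd = np.empty((mesh.n_cells, 6), dtype=np.int64)
            cd[:, :3] = cells
            for c, tri in enumerate(cells):
                for e, (i, j) in enumerate(((0, 1), (1, 2), (2, 0))):
                    key = (int(min(tri[i], tri[j])), int(max(tri[i], tri[j])))
                    if key not in edges:
                        edges[key] = nv + len(edges)
                    cd[c, 3 + e] = edges[key]
            self.ndof = nv + len(edges)
            self.cell_dofs = cd
            coords = np.empty((self.ndof, 2))
            coords[:nv] = mesh.nodes
            for (a, b), d in edges.items():
                coords[d] = 0.5 * (mesh.nodes[a] + mesh.nodes[b])
            self.dof_coords = coords
            self._edge_dofs = edges
        pcoord = mesh.nodes[cells]
        J = np.stack([pcoord[:, 1] - pcoord[:, 0],
                      pcoord[:, 2] - pcoord[:, 0]], axis=2)  # dx/d(xi,eta)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        invJT = np.empty_like(J)
        invJT[:, 0, 0] = J[:, 1, 1]
        invJT[:, 0, 1] = -J[:, 1, 0]
        invJT[:, 1, 0] = -J[:, 0, 1]
        invJT[:, 1, 1] = J[:, 0, 0]
        invJT /= detJ[:, None, None]
        self.W = wq[None, :] * detJ[:, None]
        self.N = N
        # G[c, q, i, :] = invJT[c] @ dN[q, i, :]
        self.G = np.einsum("cab,qib->cqia", invJT, dN)

    def _compute_quad_coords(self):
        cd_coords = self.dof_coords[self.cell_dofs]  # (nc, nd, dim)
        self.Xq = np.einsum("qi,cid->cqd", self.N, cd_coords)

    # -- queries -------------------------------------------------------

    def boundary_dofs(self, tag: str) -> np.ndarray:
        """Sorted dof indices lying on boundary facets carrying ``tag``."""
        mesh = self.mesh
        sel = mesh.boundary_tags == tag
        facets = np.atleast_2d(mesh.boundary_facets)[sel]
        dofs = set(int(v) for v in facets.ravel())
        if mesh.dim == 2 and self.order == 2:
            for a, b in facets:
                key = (int(min(a, b)), int(max(a, b)))
                dofs.add(self._edge_dofs[key])
        if mesh.dim == 1 and self.order > 1:
            pass  # endpoint facets are vertices; no interior dof on them
        return np.array(sorted(dofs), dtype=np.int64)

    def region_cellmask(self, region: str) -> np.ndarray:
        return self.mesh.cell_regions == region

    def region_indicator_q(self, region: str) -> np.ndarray:
        """(n_cells, nq) indicator of a region at quadrature points."""
        mask = self.region_cellmask(region).astype(float)
        return np.broadcast_to(mask[:, None], self.W.shape).copy()

    def dof_region_mask(self, region: str) -> np.ndarray:
        """Boolean per-dof mask: dof belongs to (the closure of) a region."""
        mask = np.zeros(self.ndof, dtype=bool)
        cells = self.region_cellmask(region)
        mask[np.unique(self.cell_dofs[cells])] = True
        return mask

    # -- evaluation ----------------------------------------------------

    def check_vector(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if u.shape != (self.ndof,):
            raise DimensionError(
                f"expected nodal vector of length {self.ndof}, got {u.shape}"
            )
        return u

    def at_quad(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Values (nc, nq) and gradients (nc, nq, dim) at quadrature points."""
        u = self.check_vector(u)
        uc = u[self.cell_dofs]
        vals = np.einsum("qi,ci->cq", self.N, uc)
        grads = np.einsum("cqid,ci->cqd", self.G, uc)
        return vals, grads

    def integrate(self, fq: np.ndarray) -> float:
        """Integral over the domain of a quantity sampled at quad points."""
        return float((self.W * fq).sum())

    def interpolate(self, f) -> np.ndarray:
        """Nodal interpolant of a callable f(points (n, dim)) -> (n,)."""
        return np.asarray(f(self.dof_coords), dtype=float)

    # -- assembly ------------------------------------------------------

    def _scatter(self, local: np.ndarray) -> sp.csr_matrix:
        mat = sp.coo_matrix(
            (local.ravel(), (self._rows, self._cols)),
            shape=(self.ndof, self.ndof),
        )
        return mat.tocsr()

    def mass_matrix(self, coeff_q: np.ndarray | None = None) -> sp.csr_matrix:
        """M_ij = int coeff N_j N_i dx."""
        W = self.W if coeff_q is None else self.W * coeff_q
        local = np.einsum("cq,qi,qj->cij", W, self.N, self.N)
        return self._scatter(local)

    def stiffness_matrix(self, coeff_q: np.ndarray | None = None) -> sp.csr_matrix:
        """K_ij = int coeff grad(N_j) . grad(N_i) dx."""
        W = self.W if coeff_q is None else self.W * coeff_q
        local = np.einsum("cq,cqid,cqjd->cij", W, self.G, self.G)
        return self._scatter(local)

    def drift_matrix(self, grad_psi_q: np.ndarray) -> sp.csr_matrix:
        """A_ij = int N_j (grad_psi . grad(N_i)) dx  (drift wrt concentration)."""
        gdotG = np.einsum("cqd,cqid->cqi", grad_psi_q, self.G)
        local = np.einsum("cq,cqi,qj->cij", self.W, gdotG, self.N)
        return self._scatter(local)

    def load_vector(self, fq: np.ndarray) -> np.ndarray:
        """b_i = int f N_i dx with f sampled at quadrature points."""
        b = np.zeros(self.ndof)
        local = np.einsum("cq,qi->ci", self.W * fq, self.N)
        np.add.at(b, self.cell_dofs, local)
        return b

    def grad_load_vector(self, flux_q: np.ndarray) -> np.ndarray:
        """b_i = int flux . grad(N_i) dx with flux (nc, nq, dim)."""
        b = np.zeros(self.ndof)
        local = np.einsum("cq,cqd,cqid->ci", self.W, flux_q, self.G)
        np.add.at(b, self.cell_dofs, local)
        return b


def lumped_mass_matrix(space: FunctionSpace) -> sp.csr_matrix:
    """Row-sum lumped mass matrix (diagonal)."""
    m = np.asarray(space.mass_matrix().sum(axis=1)).ravel()
    return sp.diags(m).tocsr()
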