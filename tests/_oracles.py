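"""Independent brute-force oracles used to cross-check the package.

Everything here is derived from the governing equations by a route disjoint
from the package's assembly code: closed-form element integrals, dense numpy
linear algebra, and scipy root finding.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def donnan_anion_root_search(cf: float, csol: float) -> float:
    """Gel anion concentration by 1D root search over c- in (0, csol].

    Solves c+ * c- = csol^2 with c+ = c- + cf (z_f = -1) by bracketing
    f(c-) = (c- + cf) c- - csol^2, which is negative at 0+ and positive at
    csol.
    """

    def f(cm):
        return (cm + cf) * cm - csol * csol

    if cf == 0.0:
        return csol
    return brentq(f, 1e-30, csol, xtol=1e-16, rtol=1e-15)


def hand_stiffness_two_cells(h1: float, h2: float) -> np.ndarray:
    """3x3 P1 stiffness of a two-cell interval mesh, assembled by hand.

    Element matrix of a cell of length h is (1/h) [[1, -1], [-1, 1]].
    """
    K = np.zeros((3, 3))
    K[0:2, 0:2] += np.array([[1, -1], [-1, 1]]) / h1
    K[1:3, 1:3] += np.array([[1, -1], [-1, 1]]) / h2
    return K


def fd_heat_backward_euler(
    x: np.ndarray,
    c0: np.ndarray,
    diffusivity: float,
    dt: float,
    n_steps: int,
    bc_value: float,
) -> np.ndarray:
    """Implicit-Euler finite-difference heat equation on the (possibly
    nonuniform) grid ``x`` with Dirichlet ends.

    Vertex-centered flux form: control volume of node i is
    (x[i+1]-x[i-1])/2; identical to lumped-mass P1 finite elements.
    """
    n = len(x)
    h = np.diff(x)
    A = np.zeros((n, n))
    for i in range(1, n - 1):
        vol = 0.5 * (x[i + 1] - x[i - 1])
        A[i, i - 1] = -diffusivity / (h[i - 1] * vol)
        A[i, i + 1] = -diffusivity / (h[i] * vol)
        A[i, i] = -(A[i, i - 1] + A[i, i + 1])
    M = np.eye(n) + dt * A
    M[0, :] = 0.0
    M[0, 0] = 1.0
    M[-1, :] = 0.0
    M[-1, -1] = 1.0
    c = c0.copy()
    for _ in range(n_steps):
        rhs = c.copy()
        rhs[0] = bc_value
        rhs[-1] = bc_value
        c = np.linalg.solve(M, rhs)
    return c


class DensePnpSteady1D:
    """Dense, closed-form-integral P1 steady PNP solver on a given 1D grid.

    Works in nondimensional variables (c/c_ref, psi in thermal-voltage
    units, x/L) like the package default, but assembles every element matrix
    from the exact integrals of linear shape functions and solves with dense
    numpy Newton.  gel = [x0, x1] in scaled coordinates.
    """

    def __init__(self, xhat, gel_interval, gamma, cf_hat, z=(1.0, -1.0),
                 d=(1.0, 1.0)):
        self.x = np.asarray(xhat)
        self.n = len(self.x)
        self.h = np.diff(self.x)
        self.gel = gel_interval
        self.gamma = gamma
        self.cf = cf_hat
        self.z = z
        self.d = d
        mids = 0.5 * (self.x[:-1] + self.x[1:])
        self.cf_cell = np.where(
            (mids > gel_interval[0]) & (mids < gel_interval[1]), cf_hat, 0.0
        )

    # closed-form element integrals for linear elements on a cell of length h:
    #   mass          [[h/3, h/6], [h/6, h/3]]
    #   stiffness     (1/h) [[1, -1], [-1, 1]]
    #   drift  A_ij = int N_j psi' N_i' = psi' * (+-1/2) (sign of N_i')
    #   B_ij  = int cbar N_i' N_j' = mean(c)/h [[1,-1],[-1,1]]
    def _matrices(self, psi, c):
        n, h = self.n, self.h
        K = np.zeros((n, n))
        M = np.zeros((n, n))
        A = np.zeros((n, n))
        B = np.zeros((n, n))
        for e in range(n - 1):
            i, j = e, e + 1
            ke = np.array([[1, -1], [-1, 1]]) / h[e]
            me = h[e] * np.array([[2, 1], [1, 2]]) / 6.0
            dpsi = (psi[j] - psi[i]) / h[e]
            ae = dpsi * np.array([[-0.5, -0.5], [0.5, 0.5]])
            cbar = 0.5 * (c[i] + c[j])
            be = cbar * np.array([[1, -1], [-1, 1]]) / h[e]
            for a in range(2):
                for b in range(2):
                    K[e + a, e + b] += ke[a, b]
                    M[e + a, e + b] += me[a, b]
                    A[e + a, e + b] += ae[a, b]
                    B[e + a, e + b] += be[a, b]
        return K, M, A, B

    def _cf_load(self):
        b = np.zeros(self.n)
        for e in range(self.n - 1):
            w = 0.5 * self.h[e] * self.cf_cell[e]
            b[e] += w
            b[e + 1] += w
        return b

    def residual(self, u):
        n = self.n
        c1, c2, psi = u[:n], u[n:2 * n], u[2 * n:]
        K, M, A, _ = self._matrices(psi, c1)
        r = np.empty(3 * n)
        r[:n] = self.d[0] * (K @ c1) + self.z[0] * self.d[0] * (A @ c1)
        r[n:2 * n] = self.d[1] * (K @ c2) + self.z[1] * self.d[1] * (A @ c2)
        r[2 * n:] = (
            K @ psi
            - self.gamma * (self.z[0] * (M @ c1) + self.z[1] * (M @ c2))
            + self.gamma * self._cf_load()  # z_f = -1
        )
        for blk in range(3):
            val = 1.0 if blk < 2 else 0.0
            r[blk * n] = u[blk * n] - val
            r[blk * n + n - 1] = u[blk * n + n - 1] - val
        return r

    def jacobian(self, u):
        n = self.n
        c1, c2, psi = u[:n], u[n:2 * n], u[2 * n:]
        K, M, A, B1 = self._matrices(psi, c1)
        _, _, _, B2 = self._matrices(psi, c2)
        J = np.zeros((3 * n, 3 * n))
        J[:n, :n] = self.d[0] * (K + self.z[0] * A)
        J[:n, 2 * n:] = self.z[0] * self.d[0] * B1
        J[n:2 * n, n:2 * n] = self.d[1] * (K + self.z[1] * A)
        J[n:2 * n, 2 * n:] = self.z[1] * self.d[1] * B2
        J[2 * n:, :n] = -self.gamma * self.z[0] * M
        J[2 * n:, n:2 * n] = -self.gamma * self.z[1] * M
        J[2 * n:, 2 * n:] = K
        for blk in range(3):
            for row in (blk * n, blk * n + n - 1):
                J[row, :] = 0.0
                J[row, row] = 1.0
        return J

    def solve(self, tol=1e-11, max_iter=80):
        n = self.n
        u = np.concatenate([np.ones(n), np.ones(n), np.zeros(n)])
        norm = np.max(np.abs(self.residual(u)))
        for _ in range(max_iter):
            r = self.residual(u)
            norm = np.max(np.abs(r))
            if norm < tol:
                return u[:n], u[n:2 * n], u[2 * n:]
            du = np.linalg.solve(self.jacobian(u), -r)
            alpha = 1.0
            for _ in range(25):  # plain backtracking on the residual norm
                trial = np.max(np.abs(self.residual(u + alpha * du)))
                if trial < norm:
                    break
                alpha *= 0.5
            u = u + alpha * du
        raise RuntimeError("dense oracle Newton did not converge")
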