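"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own formulas: section properties come
from brute-force 2D quadrature over a pixel mask, the torsion constant from
a finite-difference Prandtl stress-function solve, and frame accelerations
from finite differences of explicitly composed rotation matrices.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.integrate import cumulative_trapezoid
from scipy.sparse.linalg import spsolve


def _grid(half: float, n: int):
    h = 2.0 * half / n
    x = (np.arange(n) + 0.5) * h - half
    Y, Z = np.meshgrid(x, x, indexing="ij")
    return Y, Z, h


def annulus_mask(r_out: float, r_in: float, n: int = 1200):
    Y, Z, h = _grid(r_out * 1.001, n)
    R2 = Y**2 + Z**2
    return (R2 <= r_out**2) & (R2 >= r_in**2), Y, Z, h


def plus_mask(hgt: float, t: float, m: int = 12):
    """Pixel mask of the plus section on a grid aligned so that the limb
    half-thickness t/2 falls exactly on a pixel face (J ∝ t³ makes the thin
    direction the accuracy-critical one)."""
    p = t / (2.0 * m)
    N = int(np.ceil((hgt / 2.0) / p))
    x = (np.arange(2 * N) + 0.5) * p - N * p
    Y, Z = np.meshgrid(x, x, indexing="ij")
    vert = (np.abs(Y) <= t / 2) & (np.abs(Z) <= hgt / 2)
    horz = (np.abs(Z) <= t / 2) & (np.abs(Y) <= hgt / 2)
    return vert | horz, Y, Z, p


def rect_mask(hgt: float, t: float, m: int = 24):
    """Aligned pixel mask of a single hgt x t rectangle."""
    p = t / m
    nx = int(round(hgt / p))
    mask = np.ones((nx, m), dtype=bool)
    return mask, p


def quad_section_properties(mask, Y, Z, h):
    """Area and second moments by pixel quadrature."""
    dA = h * h
    A = mask.sum() * dA
    I_z = (Z[mask] ** 2).sum() * dA   # bending about y (z arm)
    I_y = (Y[mask] ** 2).sum() * dA
    return A, I_y, I_z


def prandtl_torsion_constant(mask, h: float) -> float:
    """Saint-Venant torsion constant from the Prandtl stress function:
    ∇²ψ = −2 inside the (simply connected) section, ψ = 0 on the boundary,
    J = 2 ∫ψ dA.  Five-point Laplacian on the pixel mask."""
    idx = -np.ones(mask.shape, dtype=int)
    cells = np.argwhere(mask)
    idx[mask] = np.arange(cells.shape[0])
    n = cells.shape[0]
    rows, cols, vals = [], [], []
    b = np.full(n, 2.0 * h * h)
    for k, (i, j) in enumerate(cells):
        diag = 4.0
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < mask.shape[0] and 0 <= jj < mask.shape[1] and mask[ii, jj]:
                rows.append(k)
                cols.append(idx[ii, jj])
                vals.append(-1.0)
            else:
                # mirror ghost (psi_out = -psi_in) puts the Dirichlet
                # boundary on the pixel face, restoring O(h^2) accuracy
                diag += 1.0
        rows.append(k)
        cols.append(k)
        vals.append(diag)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    psi = spsolve(A.tocsc(), b)
    return 2.0 * psi.sum() * h * h


def rot_y(phi):
    c, s = np.cos(phi), np.sin(phi)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(th):
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def fd_local_acceleration(r_local, t_eval, spec, dt=1e-7):
    """Frame acceleration of a point fixed at r_local, via second central
    differences of the global trajectory p(t) = Rz(θ)Ry(φ) r, mapped back to
    the local frame.  θ(t) integrated numerically from the ramped rate."""
    from haltere.kinematics import rotation_state, stroke_state

    ts = np.array([t_eval - dt, t_eval, t_eval + dt])
    # θ via fine cumulative integration from 0
    grid = np.linspace(0.0, t_eval + dt, 200001)
    thd, _ = rotation_state(grid, spec)
    theta_grid = cumulative_trapezoid(thd, grid, initial=0.0)

    def pos(t):
        phi, _, _ = stroke_state(t, spec)
        theta = np.interp(t, grid, theta_grid)
        return rot_z(theta) @ rot_y(phi) @ np.asarray(r_local, float)

    p = np.stack([pos(t) for t in ts])
    acc_global = (p[0] - 2.0 * p[1] + p[2]) / dt**2
    phi, _, _ = stroke_state(t_eval, spec)
    theta = np.interp(t_eval, grid, theta_grid)
    R = rot_z(theta) @ rot_y(phi)
    return R.T @ acc_global
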