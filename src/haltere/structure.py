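"""3D Euler–Bernoulli beam finite-element model of the haltere stalk.

Each of the ``n_el`` equal elements along the spanwise x′ axis carries the
standard 12 DOF (u_x, u_y, u_z, θ_x, θ_y, θ_z at both nodes): linear axial
(EA) and torsion (GJ) interpolation and cubic Hermite bending in both
transverse planes, with consistent mass matrices.  The rigid bulb enters as
a 6x6 rigid-body mass at the distal node, written about the node point so
that a transverse centre-of-mass offset produces the exact
translation–rotation coupling.  The base node is fully clamped; damping is
Rayleigh, C = α_k K + α_m M (stiffness-proportional by default, α_k = 1e−5,
α_m = 0).

Time integration is average-acceleration Newmark (γ = 1/2, β = 1/4),
unconditionally stable and without algorithmic damping, so the physical
Rayleigh value governs decay.

Sign conventions: with bending deflection v(x) in y′ the nodal rotation is
θ_z = +v′; with deflection w(x) in z′ it is θ_y = −w′.  Spanwise normal
strain at a surface point (y, z) = c (sin α, cos α) is
ε_xx = u′ − z w″ − y v″ (α = 0 dorsal, α = π/2 lateral).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import HaltereModel

__all__ = [
    "BeamSystem",
    "SimResult",
    "build_beam",
    "static_solve",
    "newmark_simulate",
    "modal_frequencies",
    "deformation_angles",
    "strain_at",
]

log = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """Raised when the time integration produces non-finite state."""


@dataclass
class BeamSystem:
    """Assembled FE system for one haltere model (SI units)."""

    model: HaltereModel
    n_el: int
    node_x: np.ndarray          # (n_nodes,) spanwise coordinates, m
    M: sp.csc_matrix            # (ndof, ndof)
    K: sp.csc_matrix
    C: sp.csc_matrix
    free: np.ndarray            # bool mask of unconstrained DOFs
    load_basis: dict            # distributed-load basis vectors (ndof,)
    bulb_mass: float
    bulb_offset: np.ndarray     # (3,), m
    bulb_inertia: np.ndarray    # (3,3), kg m²
    alpha_k: float
    alpha_m: float

    @property
    def ndof(self) -> int:
        return 6 * self.node_x.shape[0]

    @property
    def tip_node(self) -> int:
        return self.node_x.shape[0] - 1

    @property
    def length_m(self) -> float:
        return float(self.node_x[-1])


def _bending_matrices(EI: float, rhoA: float, L: float, plane: str):
    """4x4 stiffness and consistent mass for one bending plane.

    DOF order (v1, r1, v2, r2) with r = θ_z for the y-plane (θ_z = +v′) and
    r = θ_y for the z-plane (θ_y = −w′: mirror signs on the rotation DOFs).
    """
    k = EI / L**3 * np.array(
        [
            [12.0, 6.0 * L, -12.0, 6.0 * L],
            [6.0 * L, 4.0 * L**2, -6.0 * L, 2.0 * L**2],
            [-12.0, -6.0 * L, 12.0, -6.0 * L],
            [6.0 * L, 2.0 * L**2, -6.0 * L, 4.0 * L**2],
        ]
    )
    m = rhoA * L / 420.0 * np.array(
        [
            [156.0, 22.0 * L, 54.0, -13.0 * L],
            [22.0 * L, 4.0 * L**2, 13.0 * L, -3.0 * L**2],
            [54.0, 13.0 * L, 156.0, -22.0 * L],
            [-13.0 * L, -3.0 * L**2, -22.0 * L, 4.0 * L**2],
        ]
    )
    if plane == "z":
        D = np.diag([1.0, -1.0, 1.0, -1.0])
        k = D @ k @ D
        m = D @ m @ D
    return k, m


def build_beam(model: HaltereModel, n_el: int | None = None) -> BeamSystem:
    """Assemble mass, stiffness and damping for ``model``.

    ``n_el`` overrides the model's discretisation (mesh-refinement checks).
    """
    n_el = int(n_el or model.n_el)
    if n_el < 4:
        raise ValueError("need at least 4 elements")
    sec, mat = model.section, model.material
    Lm = model.length_m
    A = sec.area * 1e-12
    Iy = sec.I_y * 1e-24
    Iz = sec.I_z * 1e-24
    J = sec.J * 1e-24
    Ip = sec.I_polar * 1e-24
    E, G, rho = mat.E, mat.G, mat.rho

    node_x = np.linspace(0.0, Lm, n_el + 1)
    Le = Lm / n_el
    ndof = 6 * (n_el + 1)
    Kg = np.zeros((ndof, ndof))
    Mg = np.zeros((ndof, ndof))

    k_ax = E * A / Le * np.array([[1.0, -1.0], [-1.0, 1.0]])
    m_ax = rho * A * Le / 6.0 * np.array([[2.0, 1.0], [1.0, 2.0]])
    k_to = G * J / Le * np.array([[1.0, -1.0], [-1.0, 1.0]])
    m_to = rho * Ip * Le / 6.0 * np.array([[2.0, 1.0], [1.0, 2.0]])
    k_by, m_by = _bending_matrices(E * Iz, rho * A, Le, "y")  # v in y, θ_z
    k_bz, m_bz = _bending_matrices(E * Iy, rho * A, Le, "z")  # w in z, θ_y

    for e in range(n_el):
        n1, n2 = 6 * e, 6 * (e + 1)
        ax = [n1 + 0, n2 + 0]
        to = [n1 + 3, n2 + 3]
        by = [n1 + 1, n1 + 5, n2 + 1, n2 + 5]
        bz = [n1 + 2, n1 + 4, n2 + 2, n2 + 4]
        Kg[np.ix_(ax, ax)] += k_ax
        Mg[np.ix_(ax, ax)] += m_ax
        Kg[np.ix_(to, to)] += k_to
        Mg[np.ix_(to, to)] += m_to
        Kg[np.ix_(by, by)] += k_by
        Mg[np.ix_(by, by)] += m_by
        Kg[np.ix_(bz, bz)] += k_bz
        Mg[np.ix_(bz, bz)] += m_bz

    # rigid bulb mass about the distal node: v_com = v + ω×d
    m_b = model.bulb.mass
    d = model.bulb.offset_m
    Ic = model.bulb.inertia_com
    S = np.array([[0.0, -d[2], d[1]], [d[2], 0.0, -d[0]], [-d[1], d[0], 0.0]])
    Mb = np.zeros((6, 6))
    Mb[:3, :3] = m_b * np.eye(3)
    Mb[:3, 3:] = -m_b * S
    Mb[3:, :3] = m_b * S
    Mb[3:, 3:] = Ic + m_b * (S.T @ S)
    i0 = 6 * n_el
    Mg[i0 : i0 + 6, i0 : i0 + 6] += Mb

    free = np.ones(ndof, dtype=bool)
    free[:6] = False  # clamped base

    alpha_k, alpha_m = 1e-5, 0.0
    Cg = alpha_k * Kg + alpha_m * Mg

    # distributed-load basis: consistent nodal loads for q(x) = ρA·x in each
    # translational direction and uniform unit distributed torque × ρI_p.
    basis = {
        "axial": np.zeros(ndof),
        "lateral": np.zeros(ndof),
        "stroke": np.zeros(ndof),
        "torsion": np.zeros(ndof),
    }
    for e in range(n_el):
        x1, x2 = node_x[e], node_x[e + 1]
        n1, n2 = 6 * e, 6 * (e + 1)
        q1, q2 = rho * A * x1, rho * A * x2
        # axial, linear shape functions
        basis["axial"][n1 + 0] += Le * (2.0 * q1 + q2) / 6.0
        basis["axial"][n2 + 0] += Le * (q1 + 2.0 * q2) / 6.0
        # transverse, Hermite consistent loads for linear q
        F1 = Le * (7.0 * q1 + 3.0 * q2) / 20.0
        F2 = Le * (3.0 * q1 + 7.0 * q2) / 20.0
        M1 = Le**2 * (3.0 * q1 + 2.0 * q2) / 60.0
        M2 = -(Le**2) * (2.0 * q1 + 3.0 * q2) / 60.0
        basis["lateral"][n1 + 1] += F1
        basis["lateral"][n2 + 1] += F2
        basis["lateral"][n1 + 5] += M1
        basis["lateral"][n2 + 5] += M2
        basis["stroke"][n1 + 2] += F1
        basis["stroke"][n2 + 2] += F2
        basis["stroke"][n1 + 4] += -M1
        basis["stroke"][n2 + 4] += -M2
        # uniform distributed torque, ρI_p folded in
        basis["torsion"][n1 + 3] += rho * Ip * Le / 2.0
        basis["torsion"][n2 + 3] += rho * Ip * Le / 2.0

    sys_ = BeamSystem(
        model=model,
        n_el=n_el,
        node_x=node_x,
        M=sp.csc_matrix(Mg),
        K=sp.csc_matrix(Kg),
        C=sp.csc_matrix(Cg),
        free=free,
        load_basis=basis,
        bulb_mass=m_b,
        bulb_offset=d,
        bulb_inertia=Ic,
        alpha_k=alpha_k,
        alpha_m=alpha_m,
    )
    # fail fast on a singular constrained system
    Kff = Kg[np.ix_(free, free)]
    try:
        scipy.linalg.cho_factor(Kff)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError("stiffness singular after clamping") from exc
    return sys_


def static_solve(system: BeamSystem, load: np.ndarray) -> np.ndarray:
    """Solve K u = f on the free DOFs; returns the full-length vector."""
    load = np.asarray(load, dtype=float)
    f = system.free
    Kff = system.K.toarray()[np.ix_(f, f)]
    u = np.zeros(system.ndof)
    u[f] = scipy.linalg.solve(Kff, load[f], assume_a="sym")
    return u


@dataclass
class SimResult:
    """Time histories from one simulation.

    ``displ`` holds the full nodal displacement history, shape (ndof, nt).
    Deformation angles and strains are derived on demand.
    """

    system: BeamSystem
    times: np.ndarray
    displ: np.ndarray
    veloc: np.ndarray | None = None
    accel: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def window_mask(self, t_start: float | None = None,
                    t_end: float | None = None) -> np.ndarray:
        if t_start is None:
            t_start = self.meta.get("analysis_start", self.times[0])
        if t_end is None:
            t_end = self.meta.get("analysis_end", self.times[-1])
        return (self.times >= t_start) & (self.times <= t_end)

    # -- deformation angles ------------------------------------------------
    def bulb_point_displacement(self, point_offset: np.ndarray) -> np.ndarray:
        """Displacement history (3, nt) of a rigid-bulb material point at
        ``point_offset`` (m) from the distal node."""
        i0 = 6 * self.system.tip_node
        u = self.displ[i0 : i0 + 3, :]
        th = self.displ[i0 + 3 : i0 + 6, :]
        return u + np.cross(th.T, np.asarray(point_offset, dtype=float)).T

    def deformation_angles(self) -> dict[str, np.ndarray]:
        """Δφ (in-plane), Δθ (out-of-plane) and Δγ (twist) time series.

        Δφ = arctan(δ_z/x_d) and Δθ = arctan(δ_y/x_d) follow the bulb COM;
        Δγ = arctan(Δδ_z / y_d) uses two rigid-bulb points at ± the bulb
        y′ semi-axis from the COM (identical to arctan of the distal twist
        DOF for small rotations).
        """
        sysb = self.system
        xd = sysb.length_m
        d = sysb.bulb_offset
        com = self.bulb_point_displacement(d)
        dphi = np.arctan(com[2] / xd)
        dtheta = np.arctan(com[1] / xd)
        s_y = sysb.model.bulb.semi_axes[1] * 1e-6
        if s_y <= 0:
            raise ValueError("bulb y semi-axis must be positive for twist")
        ey = np.array([0.0, s_y, 0.0])
        p_plus = self.bulb_point_displacement(d + ey)
        p_minus = self.bulb_point_displacement(d - ey)
        dgamma = np.arctan((p_plus[2] - p_minus[2]) / (2.0 * s_y))
        return {"dphi": dphi, "dtheta": dtheta, "dgamma": dgamma}

    # -- strain recovery ---------------------------------------------------
    def strain_at(self, x_s_um: float, alpha: float) -> np.ndarray:
        """Spanwise surface strain ε_xx(α, t) at span position ``x_s_um``
        (μm from the base) and circumferential angle ``alpha`` (rad, 0 =
        dorsal +z′, π/2 = lateral +y′)."""
        sysb = self.system
        x_s = x_s_um * 1e-6
        if not (0.0 < x_s < sysb.length_m):
            raise ValueError("strain sample position outside the stalk")
        node_x = sysb.node_x
        e = min(int(np.searchsorted(node_x, x_s, side="right")) - 1,
                sysb.n_el - 1)
        L = node_x[e + 1] - node_x[e]
        xi = x_s - node_x[e]
        n1, n2 = 6 * e, 6 * (e + 1)
        u = self.displ
        du = (u[n2 + 0] - u[n1 + 0]) / L
        # Hermite second derivatives at xi
        h1 = -6.0 / L**2 + 12.0 * xi / L**3
        h2 = -4.0 / L + 6.0 * xi / L**2
        h3 = 6.0 / L**2 - 12.0 * xi / L**3
        h4 = -2.0 / L + 6.0 * xi / L**2
        vpp = h1 * u[n1 + 1] + h2 * u[n1 + 5] + h3 * u[n2 + 1] + h4 * u[n2 + 5]
        wpp = h1 * u[n1 + 2] - h2 * u[n1 + 4] + h3 * u[n2 + 2] - h4 * u[n2 + 4]
        c = sysb.model.section.c * 1e-6
        return du - c * np.cos(alpha) * wpp - c * np.sin(alpha) * vpp

    # -- serialisation -----------------------------------------------------
    def angles_frame(self):
        """Tidy (t, quantity, value) DataFrame of the deformation angles."""
        import pandas as pd

        ang = self.deformation_angles()
        frames = [
            pd.DataFrame({"t": self.times, "quantity": name, "value": series})
            for name, series in ang.items()
        ]
        return pd.concat(frames, ignore_index=True)

    def save_hdf5(self, path) -> None:
        """Full nodal history in a single hierarchical binary container."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("displ", data=self.displ)
            for k, v in self.meta.items():
                f.attrs[k] = v


def newmark_simulate(
    system: BeamSystem,
    loads: np.ndarray,
    dt: float,
    *,
    times: np.ndarray | None = None,
    store_velocity: bool = False,
    u0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    meta: dict | None = None,
) -> SimResult:
    """Integrate M ü + C u̇ + K u = F(t) with average-acceleration Newmark.

    ``loads`` is the full (ndof, nt) load history on the dense time grid
    with step ``dt``; initial conditions default to rest.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    loads = np.asarray(loads, dtype=float)
    ndof, nt = loads.shape
    if ndof != system.ndof:
        raise ValueError("load vector length does not match system DOFs")
    f = system.free
    Mf = system.M[np.ix_(f, f)].tocsc()
    Kf = system.K[np.ix_(f, f)].tocsc()
    Cf = system.C[np.ix_(f, f)].tocsc()
    Ff = loads[f, :]

    gamma, beta = 0.5, 0.25
    a0 = 1.0 / (beta * dt**2)
    a1 = gamma / (beta * dt)
    a2 = 1.0 / (beta * dt)
    a3 = 1.0 / (2.0 * beta) - 1.0
    a4 = gamma / beta - 1.0
    a5 = dt / 2.0 * (gamma / beta - 2.0)

    Keff = (Kf + a0 * Mf + a1 * Cf).tocsc()
    lu = splu(Keff)

    nfree = Ff.shape[0]
    u = np.zeros(nfree) if u0 is None else np.asarray(u0, float)[f]
    v = np.zeros(nfree) if v0 is None else np.asarray(v0, float)[f]
    # consistent initial acceleration
    a = sp.linalg.spsolve(Mf.tocsc(), Ff[:, 0] - Cf @ v - Kf @ u)

    U = np.zeros((nfree, nt))
    V = np.zeros((nfree, nt)) if store_velocity else None
    U[:, 0] = u
    if store_velocity:
        V[:, 0] = v
    for n in range(1, nt):
        rhs = (
            Ff[:, n]
            + Mf @ (a0 * u + a2 * v + a3 * a)
            + Cf @ (a1 * u + a4 * v + a5 * a)
        )
        u_new = lu.solve(rhs)
        a_new = a0 * (u_new - u) - a2 * v - a3 * a
        v_new = v + dt * ((1.0 - gamma) * a + gamma * a_new)
        u, v, a = u_new, v_new, a_new
        U[:, n] = u
        if store_velocity:
            V[:, n] = v
        if n % 1000 == 0 and not np.all(np.isfinite(u)):
            raise DivergenceError(f"non-finite state at step {n}")
    if not np.all(np.isfinite(U[:, -1])):
        raise DivergenceError("non-finite state at final step")

    displ = np.zeros((system.ndof, nt))
    displ[f, :] = U
    veloc = None
    if store_velocity:
        veloc = np.zeros((system.ndof, nt))
        veloc[f, :] = V
    if times is None:
        times = np.arange(nt) * dt
    return SimResult(
        system=system,
        times=np.asarray(times, dtype=float),
        displ=displ,
        veloc=veloc,
        meta=dict(meta or {}),
    )


def modal_frequencies(system: BeamSystem, n: int = 6) -> np.ndarray:
    """First ``n`` undamped natural frequencies (Hz), ascending."""
    if n < 1:
        raise ValueError("need n >= 1")
    f = system.free
    Kff = system.K.toarray()[np.ix_(f, f)]
    Mff = system.M.toarray()[np.ix_(f, f)]
    w2 = scipy.linalg.eigh(Kff, Mff, eigvals_only=True,
                           subset_by_index=[0, n - 1])
    return np.sqrt(np.clip(w2, 0.0, None)) / (2.0 * np.pi)


def deformation_angles(result: SimResult, x_d: float | None = None,
                       y_d: float | None = None) -> dict[str, np.ndarray]:
    """Module-level convenience wrapper around
    :meth:`SimResult.deformation_angles`."""
    return result.deformation_angles()


def strain_at(result: SimResult, x_s_um: float, alpha: float) -> np.ndarray:
    """Module-level convenience wrapper around :meth:`SimResult.strain_at`."""
    return result.strain_at(x_s_um, alpha)


def mechanical_energy(system: BeamSystem, u: np.ndarray,
                      v: np.ndarray) -> np.ndarray:
    """Total mechanical energy ½u'Ku + ½v'Mv for history columns."""
    return 0.5 * np.einsum("it,it->t", u, system.K @ u) + 0.5 * np.einsum(
        "it,it->t", v, system.M @ v
    )
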