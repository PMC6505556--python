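"""Prescribed flapping / body-rotation motion and rigid-frame inertial loads.

The haltere base is clamped to a plate that flaps about the plate's Y axis
with stroke angle φ(t) = A_f sin(2π f_φ t) while the whole animal yaws about
the global Z axis at rate θ̇ = Ω.  Both motions are ramped from rest with a
C² smoothstep.  Everything downstream works in the haltere-fixed frame
(x′ spanwise, y′ lateral / out-of-plane, z′ dorsal / in-stroke-plane), where
a material point fixed at position r experiences the frame acceleration

    a(r, t) = ω̇ × r + ω × (ω × r),

with the frame angular velocity, in local components,

    ω = (−θ̇ sin φ,  φ̇,  θ̇ cos φ).

The ω×(ω×r) cross terms between θ̇ and φ̇ are the Coriolis-type gyroscopic
loading (out-of-plane, at twice the flapping frequency, linear in Ω); the
pure φ̇² part is the centrifugal tension; ω̇×r is the Euler (tangential)
load that drives the large in-plane bending.

Elastic deflections are small (≲0.01 rad), so loads are evaluated on the
undeformed configuration and Coriolis coupling of *elastic* velocities with
the frame rotation is neglected (second order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structure import BeamSystem

__all__ = [
    "KinematicsSpec",
    "FrameState",
    "ramp_factor",
    "stroke_state",
    "rotation_state",
    "frame_state",
    "rigid_acceleration",
    "distributed_loads",
    "inertial_load_history",
]


@dataclass(frozen=True)
class KinematicsSpec:
    """Flapping law, body rotation and time grid.

    Parameters
    ----------
    amplitude_rad : float
        Stroke amplitude A_f (rad), default π/2.
    frequency_hz : float
        Flapping frequency f_φ (Hz), default 40.
    rotation_rad_s : float
        Body yaw rate Ω about global Z (rad s⁻¹); 0 = flapping only,
        10 = the "with rotation" condition.
    ramp_periods : float
        Start-up ramp duration in flapping periods (amplitude smoothstep).
    total_periods : float
        Total simulated duration in flapping periods.
    analysis_periods : float
        Length of the steady-state window at the end of the run over which
        amplitudes, spectra and spikes are measured.
    dt : float
        Time step (s); must resolve millisecond spike-timing shifts.
    """

    amplitude_rad: float = np.pi / 2.0
    frequency_hz: float = 40.0
    rotation_rad_s: float = 0.0
    ramp_periods: float = 2.0
    total_periods: float = 10.5
    analysis_periods: float = 5.0
    dt: float = 1e-5

    def __post_init__(self) -> None:
        if not (0.0 < self.amplitude_rad <= np.pi):
            raise ValueError("amplitude must be in (0, pi]")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.dt >= 1.0 / (50.0 * self.frequency_hz):
            raise ValueError("dt too coarse: need dt < 1/(50 f_phi)")
        if self.total_periods < self.ramp_periods + 4.0:
            raise ValueError("need at least 4 post-ramp flapping periods")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def omega_flap(self) -> float:
        return 2.0 * np.pi * self.frequency_hz

    @property
    def t_ramp(self) -> float:
        return self.ramp_periods * self.period

    @property
    def duration(self) -> float:
        return self.total_periods * self.period

    @property
    def analysis_start(self) -> float:
        # the window keeps half a period clear of the end of the run so that
        # probability peaks near the window edges are always detectable
        return self.duration - (self.analysis_periods + 0.5) * self.period

    @property
    def analysis_end(self) -> float:
        return self.analysis_start + self.analysis_periods * self.period

    def time_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt))
        return np.arange(n + 1) * self.dt

    def with_rotation(self, omega: float) -> "KinematicsSpec":
        return replace(self, rotation_rad_s=omega)


@dataclass(frozen=True)
class FrameState:
    """Angular velocity / acceleration of the haltere-fixed frame, local
    components.  Arrays have shape (..., 3)."""

    omega: np.ndarray
    alpha: np.ndarray


def _smoothstep(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quintic smoothstep 6x⁵−15x⁴+10x³ with first two derivatives,
    clamped outside [0, 1] (derivatives vanish at both ends: C²)."""
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, 0.0, 1.0)
    s = xc**3 * (10.0 - 15.0 * xc + 6.0 * xc**2)
    ds = 30.0 * xc**2 * (1.0 - xc) ** 2
    dds = 60.0 * xc * (1.0 - xc) * (1.0 - 2.0 * xc)
    return s, ds, dds


def ramp_factor(t, t_ramp: float):
    """Smooth monotone start-up factor: 0 at t = 0, 1 for t ≥ t_ramp."""
    if t_ramp <= 0:
        raise ValueError("t_ramp must be positive")
    return _smoothstep(np.asarray(t, dtype=float) / t_ramp)[0]


def _ramp_derivs(t, t_ramp: float):
    s, ds, dds = _smoothstep(np.asarray(t, dtype=float) / t_ramp)
    return s, ds / t_ramp, dds / t_ramp**2


def stroke_state(t, spec: KinematicsSpec):
    """Stroke angle φ and its first two analytic time derivatives."""
    t = np.asarray(t, dtype=float)
    s, sd, sdd = _ramp_derivs(t, spec.t_ramp)
    w = spec.omega_flap
    base = spec.amplitude_rad * np.sin(w * t)
    based = spec.amplitude_rad * w * np.cos(w * t)
    basedd = -spec.amplitude_rad * w**2 * np.sin(w * t)
    phi = s * base
    dphi = sd * base + s * based
    ddphi = sdd * base + 2.0 * sd * based + s * basedd
    return phi, dphi, ddphi


def rotation_state(t, spec: KinematicsSpec):
    """Body yaw rate θ̇ and acceleration θ̈ (rate ramped like the stroke)."""
    t = np.asarray(t, dtype=float)
    s, sd, _ = _ramp_derivs(t, spec.t_ramp)
    return s * spec.rotation_rad_s, sd * spec.rotation_rad_s


def frame_state(t, spec: KinematicsSpec) -> FrameState:
    """Local-frame angular velocity ω and acceleration ω̇ at time(s) t.

    With R = Rz(θ) · Ry(φ) mapping local to global, the local components
    are ω = (−θ̇ sinφ, φ̇, θ̇ cosφ); the angular acceleration in local
    components is the elementwise time derivative (the ω×ω transport term
    vanishes).
    """
    phi, dphi, _ddphi = stroke_state(t, spec)
    thd, thdd = rotation_state(t, spec)
    sin, cos = np.sin(phi), np.cos(phi)
    omega = np.stack([-thd * sin, dphi, thd * cos], axis=-1)
    alpha = np.stack(
        [-thdd * sin - thd * dphi * cos, _ddphi, thdd * cos - thd * dphi * sin],
        axis=-1,
    )
    return FrameState(omega=omega, alpha=alpha)


def rigid_acceleration(r, t, spec: KinematicsSpec):
    """Frame acceleration of a point fixed at local position r (metres).

    Returns ``(a_total, a_euler, a_centrifugal)`` in local components,
    a_euler = ω̇×r, a_centrifugal = ω×(ω×r), a_total their sum.  The
    gyroscopic (Coriolis-type) part is the Ω·φ̇ cross-term inside
    a_centrifugal plus the matching term of a_euler.
    """
    st = frame_state(t, spec)
    r = np.asarray(r, dtype=float)
    a_e = np.cross(st.alpha, r)
    a_c = np.cross(st.omega, np.cross(st.omega, r))
    return a_e + a_c, a_e, a_c


def _axis_load_coefficients(spec: KinematicsSpec, times: np.ndarray):
    """Coefficient vector c(t) with a(x·e_x) = x·c(t) for axis points, and
    the frame state (needed for bulb terms).  Shape (nt, 3)."""
    st = frame_state(times, spec)
    w, al = st.omega, st.alpha
    wx = w[..., 0]
    w2 = np.sum(w * w, axis=-1)
    c = np.empty_like(w)
    c[..., 0] = wx * wx - w2  # = −(ω_y² + ω_z²): centrifugal tension
    c[..., 1] = al[..., 2] + w[..., 1] * wx
    c[..., 2] = -al[..., 1] + w[..., 2] * wx
    return c, st


def inertial_load_history(beam: "BeamSystem", spec: KinematicsSpec,
                          times: np.ndarray) -> np.ndarray:
    """Consistent nodal load vectors from the prescribed frame motion for
    every time in ``times``.  Returns shape (ndof, nt).

    Stalk: distributed −ρA·a(x) with a linear in x, integrated with the
    beam shape functions, plus distributed torsion −ρI_p·ω̇_x.  Bulb: force
    −m·a(r_com) at the distal node with the rigid-offset moment and the
    rotary couple −(I_c ω̇ + ω × I_c ω).
    """
    times = np.asarray(times, dtype=float)
    c, st = _axis_load_coefficients(spec, times)
    nt = times.shape[0]
    F = np.zeros((beam.ndof, nt))
    # distributed stalk loads: basis vectors already include ρA (or ρ I_p)
    F -= np.outer(beam.load_basis["axial"], c[:, 0])
    F -= np.outer(beam.load_basis["lateral"], c[:, 1])
    F -= np.outer(beam.load_basis["stroke"], c[:, 2])
    F -= np.outer(beam.load_basis["torsion"], st.alpha[:, 0])

    # rigid bulb at the distal node
    m = beam.bulb_mass
    d = beam.bulb_offset  # (3,) metres, = (0, Δy, Δz)
    I_c = beam.bulb_inertia
    r_com = np.array([beam.length_m, 0.0, 0.0]) + d
    a_com = np.cross(st.alpha, r_com) + np.cross(
        st.omega, np.cross(st.omega, r_com)
    )
    Fb = -m * a_com  # (nt, 3)
    couple = -(st.alpha @ I_c.T + np.cross(st.omega, st.omega @ I_c.T))
    Mb = np.cross(d, Fb) + couple
    i0 = 6 * beam.tip_node
    F[i0 : i0 + 3, :] += Fb.T
    F[i0 + 3 : i0 + 6, :] += Mb.T
    return F


def distributed_loads(beam: "BeamSystem", t: float,
                      spec: KinematicsSpec) -> np.ndarray:
    """Nodal force/moment vector at a single time (see
    :func:`inertial_load_history`)."""
    return inertial_load_history(beam, spec, np.atleast_1d(float(t)))[:, 0]
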