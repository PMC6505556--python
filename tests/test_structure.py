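"""Beam assembly, statics, modal analysis, Newmark dynamics and strain
recovery, checked against closed-form cantilever results and full-scale
scenario invariants."""

import numpy as np
import pytest

from haltere import geometry, structure
from haltere.geometry import BulbSpec, HaltereModel
from haltere.kinematics import KinematicsSpec
from haltere.structure import (
    DivergenceError,
    build_beam,
    mechanical_energy,
    modal_frequencies,
    newmark_simulate,
    static_solve,
)


@pytest.fixture(scope="module")
def model():
    return HaltereModel()


@pytest.fixture(scope="module")
def beam(model):
    return build_beam(model)


def _EI(model):
    return model.material.E * model.section.I_y * 1e-24


class TestStatics:
    def test_cantilever_tip_force(self, model, beam):
        # Hermite elements are exact for an end load: δ = F L³ / 3EI
        L = model.length_m
        for dof in (1, 2):  # lateral and stroke-plane directions
            f = np.zeros(beam.ndof)
            f[6 * beam.tip_node + dof] = 1e-4
            u = static_solve(beam, f)
            assert u[6 * beam.tip_node + dof] == pytest.approx(
                1e-4 * L**3 / (3.0 * _EI(model)), rel=1e-9
            )

    def test_uniform_torsion(self, model, beam):
        L = model.length_m
        GJ = model.material.G * model.section.J * 1e-24
        f = np.zeros(beam.ndof)
        f[6 * beam.tip_node + 3] = 1e-8
        u = static_solve(beam, f)
        assert u[6 * beam.tip_node + 3] == pytest.approx(1e-8 * L / GJ, rel=1e-9)

    def test_zero_load(self, beam):
        u = static_solve(beam, np.zeros(beam.ndof))
        assert np.allclose(u, 0.0)
        assert np.allclose(u[:6], 0.0)  # clamped DOFs stay zero


class TestModal:
    def test_first_bending_frequency_far_above_flapping(self, model, beam):
        # Rayleigh estimate with tip mass + 33/140 of the stalk mass brackets f1
        k = 3.0 * _EI(model) / model.length_m**3
        m_eff = model.bulb.mass + 33.0 / 140.0 * model.stalk_mass
        f_rayleigh = np.sqrt(k / m_eff) / (2.0 * np.pi)
        f = modal_frequencies(beam, 4)
        assert np.all(np.diff(f) >= -1e-9)
        assert f[0] == pytest.approx(f_rayleigh, rel=0.10)
        assert f[0] > 10.0 * 40.0  # quasi-static at the flapping frequency

    def test_mesh_convergence(self, model):
        f31 = modal_frequencies(build_beam(model, 31), 1)[0]
        f62 = modal_frequencies(build_beam(model, 62), 1)[0]
        assert abs(f62 - f31) / f31 < 0.01


class TestNewmark:
    def test_zero_load_stays_zero(self, beam):
        res = newmark_simulate(beam, np.zeros((beam.ndof, 50)), 1e-5)
        assert np.allclose(res.displ, 0.0)

    def test_ramped_constant_load_converges_to_static(self, beam):
        # smooth ramp to a constant tip load; the slow (quasi-static) response
        # must match the static solution to 0.1%
        from haltere.kinematics import ramp_factor

        nt = 8000
        dt = 1e-5
        t = np.arange(nt) * dt
        f_tip = np.zeros(beam.ndof)
        f_tip[6 * beam.tip_node + 2] = 2e-4
        loads = np.outer(f_tip, ramp_factor(t, 0.04))
        res = newmark_simulate(beam, loads, dt)
        u_static = static_solve(beam, f_tip)
        i = 6 * beam.tip_node + 2
        assert res.displ[i, -1] == pytest.approx(u_static[i], rel=1e-3)

    def test_free_decay_matches_rayleigh_damping_ratio(self, model):
        # ζ_i = α_k ω_i / 2 for stiffness-proportional damping
        import scipy.linalg

        beam = build_beam(model, 8)
        f = beam.free
        Kff = beam.K.toarray()[np.ix_(f, f)]
        Mff = beam.M.toarray()[np.ix_(f, f)]
        w2, vecs = scipy.linalg.eigh(Kff, Mff)
        w1 = np.sqrt(w2[0])
        u0 = np.zeros(beam.ndof)
        u0[f] = vecs[:, 0]
        dt = 2e-6
        nt = int(6.0 * 2 * np.pi / w1 / dt)
        res = newmark_simulate(
            beam, np.zeros((beam.ndof, nt)), dt, u0=u0, store_velocity=True
        )
        q = vecs[:, 0] @ (Mff @ res.displ[f, :])  # modal coordinate
        peaks = [
            i for i in range(1, nt - 1)
            if q[i] > q[i - 1] and q[i] > q[i + 1] and q[i] > 0
        ]
        ratios = q[peaks[:-1]] / q[peaks[1:]]
        zeta = np.mean(np.log(ratios)) / (2.0 * np.pi)
        assert zeta == pytest.approx(beam.alpha_k * w1 / 2.0, rel=0.05)

    def test_free_vibration_energy_non_increasing(self, model):
        beam = build_beam(model, 8)
        u0 = np.zeros(beam.ndof)
        u0[6 * beam.tip_node + 2] = 1e-5
        u0 = static_solve(beam, beam.K @ u0 * 0.0 + _tip_load(beam, 1e-4))
        res = newmark_simulate(
            beam, np.zeros((beam.ndof, 3000)), 2e-6, u0=u0, store_velocity=True
        )
        E = mechanical_energy(beam, res.displ, res.veloc)
        assert np.all(np.diff(E) <= 1e-9 * E[0])

    def test_divergence_is_reported(self, beam):
        bad = np.zeros((beam.ndof, 40))
        bad[6 * beam.tip_node + 2, 10:] = np.nan
        with pytest.raises(DivergenceError):
            newmark_simulate(beam, bad, 1e-5)


def _tip_load(beam, F, dof=2):
    f = np.zeros(beam.ndof)
    f[6 * beam.tip_node + dof] = F
    return f


class TestStrainRecovery:
    def test_pure_tip_moment_gives_uniform_bending_strain(self, model, beam):
        # M_y at the tip → uniform curvature κ = M/EI, ε(α=0) = ± c κ,
        # anti-symmetric dorsal/ventral, zero on the neutral axis (α=π/2)
        M = 1e-8
        f = np.zeros(beam.ndof)
        f[6 * beam.tip_node + 4] = M
        u = static_solve(beam, f)
        res = structure.SimResult(system=beam, times=np.zeros(1),
                                  displ=u[:, None])
        kappa = M / _EI(model)
        c = model.section.c * 1e-6
        eps_dorsal = res.strain_at(300.0, 0.0)[0]
        eps_ventral = res.strain_at(300.0, np.pi)[0]
        eps_side = res.strain_at(300.0, np.pi / 2.0)[0]
        assert abs(eps_dorsal) == pytest.approx(c * kappa, rel=1e-9)
        assert eps_ventral == pytest.approx(-eps_dorsal, rel=1e-9)
        assert abs(eps_side) < 1e-12 * abs(eps_dorsal) + 1e-18

    def test_axial_load_strains_all_positions_equally(self, model, beam):
        f = _tip_load(beam, 1e-4, dof=0)
        u = static_solve(beam, f)
        res = structure.SimResult(system=beam, times=np.zeros(1),
                                  displ=u[:, None])
        EA = model.material.E * model.section.area * 1e-12
        expected = 1e-4 / EA
        for alpha in (0.0, np.pi / 4, np.pi / 2, np.pi):
            assert res.strain_at(300.0, alpha)[0] == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_position_rejected(self, beam):
        res = structure.SimResult(system=beam, times=np.zeros(1),
                                  displ=np.zeros((beam.ndof, 1)))
        with pytest.raises(ValueError):
            res.strain_at(6000.0, 0.0)

    def test_deformation_angle_matches_static_deflection(self, model, beam):
        f = _tip_load(beam, 1e-4, dof=2)
        u = static_solve(beam, f)
        res = structure.SimResult(system=beam, times=np.zeros(1),
                                  displ=u[:, None])
        ang = res.deformation_angles()
        delta = u[6 * beam.tip_node + 2]
        assert ang["dphi"][0] == pytest.approx(np.arctan(delta / model.length_m))
        assert ang["dtheta"][0] == 0.0


class TestScenarioInvariants:
    """Full-scale simulation properties (shared session fixtures)."""

    def test_symmetric_flapping_has_no_out_of_plane_or_twist(self, scen):
        res = scen("cs_flap")
        assert np.abs(res.angles["dtheta"]).max() < 1e-6
        assert np.abs(res.angles["dgamma"]).max() < 1e-6

    def test_out_of_plane_amplitude_linear_in_rotation_rate(self, scen):
        omegas = np.array([1.0, 5.0, 10.0, 20.0])
        amps = np.array(
            [scen("cs_rot", omega=om).summary["p2p_dtheta"] for om in omegas]
        )
        slope = np.sum(omegas * amps) / np.sum(omegas**2)
        ss_res = np.sum((amps - slope * omegas) ** 2)
        ss_tot = np.sum((amps - amps.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.999

    def test_out_of_plane_flips_sign_with_rotation(self, scen):
        from haltere.scenarios import compare_scenarios

        gain = compare_scenarios(scen("cs_rot", omega=-10.0), scen("cs_rot"),
                                 "signed_dtheta")
        assert gain == pytest.approx(-1.0, abs=1e-6)

    def test_dominant_frequencies(self, scen):
        res = scen("cs_rot")
        f = res.spec.kinematics.frequency_hz
        assert res.summary["f_dom_dtheta"] == pytest.approx(2 * f, abs=1.0)
        assert res.summary["f_dom_dgamma"] == pytest.approx(f, abs=1.0)
        assert res.summary["f_dom_dphi"] == pytest.approx(f, abs=1.0)

    def test_twist_ratio_between_stalk_designs(self, scen):
        ratio = (scen("ps_rot").summary["p2p_dgamma"]
                 / scen("cs_rot").summary["p2p_dgamma"])
        assert ratio >= 20.0

    def test_mesh_convergence_of_in_plane_amplitude(self, scen):
        p31 = scen("cs_flap").summary["p2p_dphi"]
        p62 = scen("cs_flap", n_el=62).summary["p2p_dphi"]
        assert abs(p62 - p31) / p31 < 0.02

    def test_flapping_strain_shares_centrifugal_tension(self, scen):
        # all circumferential positions see the same positive tensile
        # component from centrifugal loading of the flapping stalk
        res = scen("cs_flap")
        mask = res.sim.window_mask()
        means = [res.strain(a)[mask].mean()
                 for a in (0.0, np.pi / 4, np.pi / 2, np.pi)]
        assert np.ptp(means) < 0.02 * abs(np.mean(means))
        assert np.mean(means) > 0.0
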