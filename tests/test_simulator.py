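"""Morphing engine: increments, threshold law, blocking, strategies."""

import math

import numpy as np
import pytest

from kinemorph import (MorphSimulation, SimulationConfig, build_peptide,
                       backbone_rmsd, compute_increments, delta_energy,
                       energy_threshold, simulate_step)
from kinemorph.energy import EnergyModel
from kinemorph.kinematics import rotate_dof, wrap_angle
from kinemorph.simulator import DofState, SimulationError
from kinemorph.structure_io import TopologyError, enumerate_dofs


def uphill_target(model, forcefield, delta=10.0):
    """Target whose every backbone increment raises the energy of ``model``
    — the adversarial landscape in which the control law must block."""
    target = model.copy()
    for dof in enumerate_dofs(model):
        de_p = delta_energy(model, forcefield, dof, delta)
        de_m = delta_energy(model, forcefield, dof, -delta)
        rotate_dof(target, dof, delta if de_p >= de_m else -delta)
    return target


class TestComputeIncrements:
    def test_plain_arithmetic(self):
        assert compute_increments([-60.0], [-100.0], 100)[0] == pytest.approx(-0.4)

    def test_wraps_through_180(self):
        inc = compute_increments([175.0], [-175.0], 10)[0]
        assert inc == pytest.approx(1.0)  # through +-180, not -35 deg/step

    def test_zero_distance(self):
        assert compute_increments([42.0], [42.0], 5)[0] == 0.0

    def test_exact_halfturn_resolves_positive(self):
        assert compute_increments([0.0], [180.0], 10)[0] == pytest.approx(18.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_increments([0.0, 1.0], [0.0], 10)


class TestEnergyThreshold:
    @pytest.mark.parametrize("e0,eps,p,k,expected", [
        (1000.0, 0.10, 100, 100, 1100.0),
        (1000.0, 0.10, 100, 50, 1050.0),
        (1000.0, 0.10, 101, 50, 1000.0 * (1 + 50 * 0.10 / 101)),
    ])
    def test_linear_ramp(self, e0, eps, p, k, expected):
        assert energy_threshold(e0, eps, p, k) == pytest.approx(expected)


class TestSimulateStep:
    def _setup(self, model, target, p=10, **kw):
        cfg = SimulationConfig(p=p, **kw)
        sim = MorphSimulation(model, target, cfg)
        work = model.copy()
        em = EnergyModel(work, sim.forcefield)
        states = [DofState(dof=d, increment=float(i))
                  for d, i in zip(sim.backbone_dofs, sim.increments)]
        return cfg, sim, work, em, states

    def test_generous_threshold_advances_all_dofs_exactly(self):
        a = build_peptide("LAGL", -70, -35)
        b = build_peptide("LAGL", -100, 10)
        cfg, sim, work, em, states = self._setup(a, b, p=10, epsilon=1e6)
        e0 = em.energy(work.coords)
        energy, blocked, p_cur = simulate_step(work, states, cfg, em, e0, 1, 10)
        assert blocked == [] and p_cur == 10
        for d, inc, a0 in zip(sim.backbone_dofs, sim.increments, sim.initial_angles):
            got = work.backbone_dihedral(d.kind, d.residue_index)
            assert wrap_angle(got - a0 - inc) == pytest.approx(0.0, abs=1e-9)

    def test_adversarial_blocks_everything_and_inflates_p(self, forcefield):
        a = build_peptide("LLLLLLLLLL", -57, -47, chi1=75.0)
        b = uphill_target(a, forcefield)
        cfg, sim, work, em, states = self._setup(a, b, p=5, epsilon=1e-9, m=100)
        e0 = em.energy(work.coords)
        before = work.coords.copy()
        energy, blocked, p_cur = simulate_step(work, states, cfg, em, e0, 1, 5)
        assert len(blocked) == len([s for s in states if s.increment != 0.0])
        assert p_cur == 6  # inflated by exactly one despite many blocks
        assert np.array_equal(work.coords, before)  # restored bit-for-bit
        assert all(s.block_count == 1 for s in states if s.increment != 0.0)

    def test_half_increment_acceptance_leaves_block_count_unchanged(self, forcefield):
        """Constructed case: the full increment violates the cap, the half
        does not; the DOF advances by half and is not counted as blocked."""
        a = build_peptide("LLLLLLLLLL", -57, -47, chi1=75.0)
        b = uphill_target(a, forcefield, delta=10.0)
        cfg, sim, work, em, states = self._setup(a, b, p=5, epsilon=1.0)
        # single active DOF: zero every other increment
        keep = max(range(len(states)),
                   key=lambda i: abs(states[i].increment))
        for i, st in enumerate(states):
            if i != keep:
                st.increment = 0.0
        st = states[keep]
        e0 = em.energy(work.coords)
        e_full = e0 + delta_energy(work, sim.forcefield, st.dof, st.increment)
        e_half = e0 + delta_energy(work, sim.forcefield, st.dof, st.increment / 2)
        assert e0 < e_half < e_full  # uphill construction premise
        # choose epsilon so the cap separates half from full at k=1
        thr = (e_half + e_full) / 2
        eps = (thr / e0 - 1.0) * cfg.p / 1
        cfg2 = SimulationConfig(p=cfg.p, epsilon=eps)
        a0 = work.backbone_dihedral(st.dof.kind, st.dof.residue_index)
        energy, blocked, p_cur = simulate_step(work, states, cfg2, em, e0, 1, cfg.p)
        a1 = work.backbone_dihedral(st.dof.kind, st.dof.residue_index)
        assert blocked == [] and st.block_count == 0 and p_cur == cfg.p
        assert wrap_angle(a1 - a0) == pytest.approx(st.increment / 2, abs=1e-9)
        assert energy == pytest.approx(e_half, abs=1e-6)

    def test_nonfinite_reference_energy_aborts(self):
        a = build_peptide("LAG", -70, -35)
        b = build_peptide("LAG", -100, 10)
        cfg, sim, work, em, states = self._setup(a, b)
        with pytest.raises(SimulationError):
            simulate_step(work, states, cfg, em, float("nan"), 1, 10)


class TestRunSimulation:
    def test_identical_endpoints_give_identity_trajectory(self):
        a = build_peptide("LAGL", -70, -35)
        cfg = SimulationConfig(p=5, include_sidechains=False)
        res = MorphSimulation(a, a.copy(), cfg).run()
        assert len(res.trajectory) == 6
        for frame in res.trajectory:
            assert np.abs(frame.coords - a.coords).max() < 1e-12
        assert res.final_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_identical_endpoints_backbone_fixed_with_sidechain_module(self):
        """With the orientation module on, side chains may still relax, but
        the backbone never moves and the energy never rises."""
        a = build_peptide("LAGL", -70, -35)
        res = MorphSimulation(a, a.copy(), SimulationConfig(p=5)).run()
        assert res.final_rmsd == pytest.approx(0.0, abs=1e-9)
        energies = [r.energy for r in res.reports]
        assert all(e1 <= e0 + 1e-9 for e0, e1 in zip([res.e0] + energies, energies))

    def test_topology_mismatch_rejected(self):
        a = build_peptide("LAG", -70, -35)
        b = build_peptide("LAGA", -70, -35)
        with pytest.raises(TopologyError):
            MorphSimulation(a, b)

    def test_unnormalized_input_rejected(self, morph_pair):
        from kinemorph import perturb_geometry

        h, ex = morph_pair
        bad = perturb_geometry(h, plane_twist=3.0, seed=1)
        with pytest.raises(SimulationError, match="omega"):
            MorphSimulation(bad, ex)

    def test_linear_interpolation_limit(self, morph_pair):
        """With an unbounded cap, step-k dihedrals equal linear
        interpolation at fraction k/p."""
        h, ex = morph_pair
        cfg = SimulationConfig(p=10, epsilon=math.inf, strategy="type1",
                               include_sidechains=False)
        sim = MorphSimulation(h, ex, cfg)
        res = sim.run()
        assert len(res.reports) == 10
        for k, frame in enumerate(res.trajectory):
            t = k / 10.0
            for d, a0, a1 in zip(sim.backbone_dofs, sim.initial_angles,
                                 sim.final_angles):
                expect = a0 + t * wrap_angle(a1 - a0)
                got = frame.backbone_dihedral(d.kind, d.residue_index)
                assert abs(wrap_angle(got - expect)) < 1e-6

    def test_control_law_invariant_on_constrained_run(self, morph_pair):
        h, ex = morph_pair
        res = MorphSimulation(h, ex, SimulationConfig(
            p=20, epsilon=0.10, strategy="type1")).run()
        for r in res.reports:
            assert r.energy <= energy_threshold(
                res.e0, 0.10, r.p_current, r.k) + 1e-9

    def test_frozen_dofs_never_move(self, morph_pair):
        h, ex = morph_pair
        cfg = SimulationConfig(p=5, epsilon=0.5, strategy="type2")
        sim = MorphSimulation(h, ex, cfg)
        res = sim.run()
        # all-helix fixture: every residue stable, everything frozen
        assert all(r.n_frozen == len(sim.backbone_dofs) for r in res.reports)
        for d, a0 in zip(sim.backbone_dofs, sim.initial_angles):
            got = res.final_model.backbone_dihedral(d.kind, d.residue_index)
            assert abs(wrap_angle(got - a0)) < 1e-9

    def test_type2_rotates_fewer_dofs_than_type1_when_ss_present(self, morph_pair):
        h, ex = morph_pair
        runs = {}
        for strat in ("type1", "type2"):
            res = MorphSimulation(h, ex, SimulationConfig(
                p=5, epsilon=0.5, strategy=strat)).run()
            runs[strat] = res.reports[0].n_rotated
        assert runs["type2"] < runs["type1"]

    def test_direction_reversal_after_m_blocks(self, forcefield):
        """A DOF blocked m times rotates the other way for the next n steps,
        then its original direction and a fresh block counter return."""
        a = build_peptide("LLLLLLLLLL", -57, -47, chi1=75.0)
        b = uphill_target(a, forcefield)
        cfg = SimulationConfig(p=8, epsilon=1e-9, m=3, n=1, strategy="type1",
                               include_sidechains=False, max_steps=4)
        res = MorphSimulation(a, b, cfg).run()
        blocked_per_step = [r.n_blocked for r in res.reports]
        n_dofs = 18
        # steps 1-3 block everything; step 4 runs reversed (downhill) freely
        assert blocked_per_step[:3] == [n_dofs, n_dofs, n_dofs]
        assert blocked_per_step[3] == 0
        assert np.abs(res.trajectory[3].coords - a.coords).max() < 1e-12
        assert np.abs(res.trajectory[4].coords - a.coords).max() > 0.01

    def test_report_and_summary_surface(self, morph_pair):
        h, ex = morph_pair
        res = MorphSimulation(h, ex, SimulationConfig(p=5, epsilon=0.5)).run()
        df = res.report_frame
        assert list(df.k) == list(range(1, len(df) + 1))
        text = res.summary()
        assert "RMSD" in text and "strategy" in text
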