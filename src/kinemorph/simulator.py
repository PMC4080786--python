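"""The morphing engine: stepwise dihedral interpolation under an energy cap.

Given two normalized conformations of the same chain, each backbone torsion
is assigned a fixed per-step increment — the minimal wrapped angular
distance to its target value divided by the intended step count ``p``, taken
in the shorter direction.  Every step rotates all active torsions in chain
order while recording each rotation's energy increment, then enforces the
control law

    E^k  <=  E^0 * (1 + k * epsilon / p_current)

by a repair loop: while the cap is exceeded, the worst-offending torsion is
rolled back, retried at half its increment, and blocked for the step if the
half also fails.  A torsion blocked ``m`` times rotates in the opposite
direction for the next ``n`` steps (to route around steric obstacles), and
whenever at least one torsion was blocked in a step the planned step count
``p_current`` grows by one, loosening the per-step tolerance.

Strategies: *type1* adds side-chain orientation after each step; *type2*
additionally freezes the phi/psi of residues detected inside secondary
structures; *type3* also freezes the chi1 of those residues.

Rollback is exact: a step keeps a snapshot of its starting coordinates and
repairs by deterministic replay of the surviving rotations, so an undone
rotation leaves no floating-point drift behind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .energy import EnergyModel, ForceFieldParams
from .kinematics import rotate_dof, wrap_angle
from .metrics import backbone_rmsd, ramachandran_fraction
from .sidechain import orient_side_chains
from .ssdetect import detect_secondary_structures
from .structure_io import Dof, ProteinModel, TopologyError, enumerate_dofs

STRATEGIES = ("type1", "type2", "type3")


class SimulationError(RuntimeError):
    """Invalid simulation inputs or a non-finite starting energy."""


@dataclass(frozen=True)
class SimulationConfig:
    """Control parameters of the morphing procedure.

    p: intended number of intermediate conformations.
    epsilon: maximum fractional energy change over the whole run (0.10 =
        10%); the per-step cap ramps linearly with k.
    m: blocks a torsion endures before its rotation direction is reversed.
    n: steps a direction reversal lasts.
    strategy: 'type1' | 'type2' | 'type3' (see module docstring).
    include_sidechains: run the side-chain orientation module.
    retarget: recompute increments toward the target every step instead of
        keeping the start-time values (off, matching the original design).
    max_steps: hard cap on the step count; p inflation can otherwise
        outrun k forever when every step blocks (defaults to 5*p).
    omega_tolerance: allowed deviation of omega from {0, 180} before the
        inputs are rejected as un-normalized (degrees).
    ss_tolerance: candidate window of the secondary-structure detector.
    """

    p: int = 100
    epsilon: float = 0.10
    m: int = 3
    n: int = 1
    strategy: str = "type2"
    include_sidechains: bool = True
    lock_proline_phi: bool = False
    retarget: bool = False
    max_steps: int | None = None
    omega_tolerance: float = 1e-3
    ss_tolerance: float = 30.0

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be >= 1")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")

    @property
    def step_cap(self) -> int:
        return self.max_steps if self.max_steps is not None else 5 * self.p


@dataclass
class DofState:
    """Per-DOF bookkeeping for blocking and direction reversal."""

    dof: Dof
    increment: float  # signed degrees/step, fixed at start
    block_count: int = 0
    reversal_steps_left: int = 0
    frozen: bool = False
    blocked_this_step: bool = False
    last_delta_e: float = 0.0

    @property
    def effective_increment(self) -> float:
        return -self.increment if self.reversal_steps_left > 0 else self.increment


@dataclass(frozen=True)
class StepReport:
    """Diagnostics of one accepted simulation step."""

    k: int
    energy: float
    threshold: float
    n_rotated: int
    n_blocked: int
    n_frozen: int
    rmsd_to_target: float
    ramachandran_pct: float
    p_current: int


def compute_increments(initial, final, p: int) -> np.ndarray:
    """Signed per-step increments (degrees): minimal wrapped distance / p.

    The sign picks the shorter rotation direction; an exact 180-degree
    distance resolves to the positive direction.
    """
    initial = np.asarray(initial, dtype=float)
    final = np.asarray(final, dtype=float)
    if initial.shape != final.shape:
        raise ValueError("initial and final angle lists differ in length")
    if p < 1:
        raise ValueError("p must be >= 1")
    return wrap_angle(final - initial) / p


def energy_threshold(e0: float, epsilon: float, p_current: int, k: int) -> float:
    """Admissible energy bound at step k: E0 * (1 + k*epsilon/p_current)."""
    return e0 * (1.0 + k * epsilon / p_current)


def simulate_step(model: ProteinModel, states: list[DofState],
                  config: SimulationConfig, em: EnergyModel,
                  e0: float, k: int, p_current: int):
    """Advance one step in place; returns (energy, blocked_states, p_current).

    Rotates every active torsion sequentially by its effective increment,
    recording the energy increment of each rotation, then repairs threshold
    violations by halving/blocking the highest-increment offenders.  If any
    torsion was blocked, p_current is inflated by one (once per step).
    """
    if not math.isfinite(e0):
        raise SimulationError("starting energy is not finite")
    snapshot = model.coords.copy()
    threshold = energy_threshold(e0, config.epsilon, p_current, k)

    rotated: list[DofState] = []
    for st in states:
        st.blocked_this_step = False
        if st.frozen or st.increment == 0.0:
            continue
        delta = st.effective_increment
        st.last_delta_e = _incremental_delta(model, em, st.dof, delta)
        rotated.append(st)
    energy = em.energy(model.coords) if rotated else em.energy(snapshot)

    scale: dict[int, float] = {id(st): 1.0 for st in rotated}

    def replay() -> float:
        model.coords[:] = snapshot
        for st in rotated:
            s = scale[id(st)]
            if s:
                rotate_dof(model, st.dof, st.effective_increment * s)
        return em.energy(model.coords)

    if energy > threshold:
        # worst recorded increment first; ties -> earliest in chain order
        order = sorted(rotated, key=lambda st: -st.last_delta_e)
        for st in order:
            if energy <= threshold:
                break
            scale[id(st)] = 0.5
            energy = replay()
            if energy <= threshold:
                break
            scale[id(st)] = 0.0
            energy = replay()
            st.blocked_this_step = True
            st.block_count += 1

    blocked = [st for st in rotated if st.blocked_this_step]
    if blocked:
        p_current += 1
    return energy, blocked, p_current


def _incremental_delta(model: ProteinModel, em: EnergyModel, dof: Dof,
                       delta: float) -> float:
    """Rotate and return the energy increment (rotation is kept)."""
    before = em.cross_energy(model.coords, dof.moving)
    rotate_dof(model, dof, delta)
    return em.cross_energy(model.coords, dof.moving) - before


class MorphSimulation:
    """Morph between two conformations of one chain.

    Parameters
    ----------
    initial, final : ProteinModel
        Normalized, topology-identical endpoints of the motion.
    config : SimulationConfig, optional
    forcefield : ForceFieldParams, optional
    """

    def __init__(self, initial: ProteinModel, final: ProteinModel,
                 config: SimulationConfig | None = None,
                 forcefield: ForceFieldParams | None = None):
        self.config = config or SimulationConfig()
        self.forcefield = forcefield or ForceFieldParams()
        _check_topology(initial, final)
        for name, m in (("initial", initial), ("final", final)):
            _check_normalized(m, self.config.omega_tolerance, name)
        self.initial = initial
        self.final = final
        self.backbone_dofs = enumerate_dofs(
            initial, include_sidechains=False,
            lock_proline_phi=self.config.lock_proline_phi)
        all_dofs = enumerate_dofs(
            initial, include_sidechains=True,
            lock_proline_phi=self.config.lock_proline_phi)
        self.chi_dofs = [d for d in all_dofs if d.kind == "chi1"]
        self.initial_angles = np.array(
            [initial.backbone_dihedral(d.kind, d.residue_index)
             for d in self.backbone_dofs])
        self.final_angles = np.array(
            [final.backbone_dihedral(d.kind, d.residue_index)
             for d in self.backbone_dofs])
        self.increments = compute_increments(
            self.initial_angles, self.final_angles, self.config.p)

    def run(self) -> "MorphResult":
        cfg = self.config
        model = self.initial.copy()
        em = EnergyModel(model, self.forcefield)
        e0 = em.energy(model.coords)
        if not math.isfinite(e0):
            raise SimulationError("initial conformation has non-finite energy")
        states = [DofState(dof=d, increment=float(inc))
                  for d, inc in zip(self.backbone_dofs, self.increments)]

        frames = [self.initial.copy()]
        reports: list[StepReport] = []
        p_current = cfg.p
        k = 0
        while k < p_current and k < cfg.step_cap:
            k += 1
            frozen_chi: set[int] = set()
            n_frozen = 0
            if cfg.strategy in ("type2", "type3"):
                ann = detect_secondary_structures(
                    model, tolerance=cfg.ss_tolerance)
                stable = set(ann.stable_residues)
                for st in states:
                    st.frozen = st.dof.residue_index in stable
                n_frozen = sum(st.frozen for st in states)
                if cfg.strategy == "type3":
                    frozen_chi = {i for i, d in enumerate(self.chi_dofs)
                                  if d.residue_index in stable}
            if cfg.retarget and k > 1:
                remaining = p_current - k + 1
                current = np.array(
                    [model.backbone_dihedral(d.kind, d.residue_index)
                     for d in self.backbone_dofs])
                new_inc = wrap_angle(self.final_angles - current) / remaining
                for st, inc in zip(states, new_inc):
                    st.increment = float(inc)

            reversing = [st for st in states if st.reversal_steps_left > 0]
            energy, blocked, p_current = simulate_step(
                model, states, cfg, em, e0, k, p_current)

            if cfg.include_sidechains and self.chi_dofs:
                energy = orient_side_chains(
                    model, em, energy, self.chi_dofs, frozen=frozen_chi)

            for st in states:
                if st.block_count >= cfg.m:
                    st.reversal_steps_left = cfg.n
                    st.block_count = 0
            for st in reversing:
                st.reversal_steps_left -= 1

            reports.append(StepReport(
                k=k,
                energy=energy,
                threshold=energy_threshold(e0, cfg.epsilon, p_current, k),
                n_rotated=sum(1 for st in states
                              if not st.frozen and st.increment != 0.0),
                n_blocked=len(blocked),
                n_frozen=n_frozen,
                rmsd_to_target=backbone_rmsd(model, self.final, superpose=True),
                ramachandran_pct=ramachandran_fraction(model),
                p_current=p_current,
            ))
            frames.append(model.copy())
        return MorphResult(simulation=self, trajectory=frames,
                           reports=reports, e0=e0)


@dataclass
class MorphResult:
    """Trajectory plus per-step diagnostics of a finished morph."""

    simulation: MorphSimulation
    trajectory: list[ProteinModel]
    reports: list[StepReport]
    e0: float

    @property
    def report_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.reports])

    @property
    def final_model(self) -> ProteinModel:
        return self.trajectory[-1]

    @property
    def final_rmsd(self) -> float:
        return backbone_rmsd(self.final_model, self.simulation.final,
                             superpose=True)

    @property
    def energy_change_pct(self) -> float:
        from .metrics import energy_change_pct

        if not self.reports:
            return 0.0
        return energy_change_pct(self.e0, self.reports[-1].energy)

    def write_trajectory(self, path) -> None:
        from .structure_io import write_trajectory

        write_trajectory(self.trajectory, path)

    def write_report(self, path) -> None:
        self.report_frame.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        cfg = self.simulation.config
        initial_rmsd = backbone_rmsd(self.simulation.initial,
                                     self.simulation.final, superpose=True)
        lines = [
            "Kinematic morph summary",
            "=======================",
            f"strategy            {cfg.strategy}",
            f"steps run           {len(self.reports)} "
            f"(p={cfg.p}, final p_current="
            f"{self.reports[-1].p_current if self.reports else cfg.p})",
            f"epsilon / m / n     {cfg.epsilon} / {cfg.m} / {cfg.n}",
            f"E0 (kcal/mol)       {self.e0:.3f}",
            f"final energy        "
            f"{self.reports[-1].energy if self.reports else self.e0:.3f} "
            f"({self.energy_change_pct:+.2f}%)",
            f"initial->target RMSD {initial_rmsd:.3f} A",
            f"final->target RMSD   {self.final_rmsd:.3f} A",
            f"final Ramachandran   "
            f"{self.reports[-1].ramachandran_pct if self.reports else float('nan'):.1f}%"
            " in preferred regions",
        ]
        return "\n".join(lines)


def run_simulation(model_initial: ProteinModel, model_final: ProteinModel,
                   config: SimulationConfig | None = None,
                   params: ForceFieldParams | None = None):
    """Functional entry point; returns (trajectory, StepReport list)."""
    result = MorphSimulation(model_initial, model_final, config, params).run()
    return result.trajectory, result.reports


def _check_topology(a: ProteinModel, b: ProteinModel) -> None:
    if a.n_atoms != b.n_atoms or a.n_residues != b.n_residues:
        raise TopologyError("models differ in atom or residue count")
    for x, y in zip(a.atoms, b.atoms):
        if x.name != y.name or x.residue_index != y.residue_index:
            raise TopologyError(
                f"atom mismatch: {x.name}/{x.residue_index} vs "
                f"{y.name}/{y.residue_index}")


def _check_normalized(model: ProteinModel, tol: float, label: str) -> None:
    for i in range(model.n_residues - 1):
        omega = model.backbone_dihedral("omega", i)
        dev = min(abs(wrap_angle(omega)), abs(wrap_angle(omega - 180.0)))
        if dev > tol:
            raise SimulationError(
                f"{label} model is not normalized: omega of peptide bond {i} "
                f"deviates {dev:.4f} deg from 0/180 (tolerance {tol})")
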