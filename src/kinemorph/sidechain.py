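"""Side-chain orientation about Calpha-Cbeta to relieve potential energy.

A deliberately minimizer-free heuristic run once after each simulation step:
first each side chain's preferred rotation direction is found from two small
trial rotations, then a four-stage cascade tries (1) a 2-degree rotation of
every side chain in its preferred direction, (2) a 1-degree rotation, (3) a
1-degree rotation of only the chains whose individual trial produced an
energy decrement, and (4) full rollback.  The structure is returned modified
only if its total energy strictly decreased, so the procedure can never
degrade the morph; trial rotations are always fully undone (coordinates
restored bit-for-bit from saved arrays, not by inverse rotation).
"""

from __future__ import annotations

from .energy import EnergyModel
from .kinematics import rotate_dof
from .structure_io import Dof, ProteinModel

TRIAL_ANGLE = 2.0  # degrees; also the stage-1 rotation magnitude


def choose_directions(model: ProteinModel, em: EnergyModel,
                      chi_dofs: list[Dof],
                      trial_angle: float = TRIAL_ANGLE):
    """Per-side-chain preferred rotation sign from two trial rotations.

    For each chi1 DOF the energy increments of a +trial and a -trial
    rotation are measured (and fully undone).  The sign with the larger
    decrement wins; if both directions raise the energy, the one raising it
    less wins; an exact tie goes to +.  Returns ``(signs, trial_dE)`` where
    ``trial_dE[i]`` is the increment of the chosen direction — stage 3 of
    the cascade uses its sign.
    """
    signs: dict[int, float] = {}
    trial_de: dict[int, float] = {}
    for idx, dof in enumerate(chi_dofs):
        saved = model.coords[dof.moving].copy()
        before = em.cross_energy(model.coords, dof.moving)
        rotate_dof(model, dof, trial_angle)
        de_plus = em.cross_energy(model.coords, dof.moving) - before
        model.coords[dof.moving] = saved
        rotate_dof(model, dof, -trial_angle)
        de_minus = em.cross_energy(model.coords, dof.moving) - before
        model.coords[dof.moving] = saved
        if de_plus <= de_minus:
            signs[idx], trial_de[idx] = 1.0, de_plus
        else:
            signs[idx], trial_de[idx] = -1.0, de_minus
    return signs, trial_de


def orient_side_chains(model: ProteinModel, em: EnergyModel, e_k: float,
                       chi_dofs: list[Dof],
                       frozen: frozenset | set = frozenset(),
                       trial_angle: float = TRIAL_ANGLE) -> float:
    """Run the orientation cascade in place; returns the resulting energy.

    ``e_k`` is the current total energy of ``model``.  Side chains whose
    DOF index is in ``frozen`` are untouched.  The returned energy is
    strictly lower than ``e_k``, or equal to it with the model restored
    bit-for-bit.
    """
    active = [(i, d) for i, d in enumerate(chi_dofs) if i not in frozen]
    if not active:
        return e_k
    signs, trial_de = choose_directions(
        model, em, [d for _, d in active], trial_angle)
    snapshot = model.coords.copy()

    def try_stage(selected, magnitude: float) -> float | None:
        for local_idx, dof in selected:
            rotate_dof(model, dof, magnitude * signs[local_idx])
        e_new = em.energy(model.coords)
        if e_new < e_k:
            return e_new
        model.coords[:] = snapshot
        return None

    indexed = list(enumerate(d for _, d in active))
    # stage 1: everything at the trial magnitude
    e_new = try_stage(indexed, trial_angle)
    if e_new is not None:
        return e_new
    # stage 2: everything at half the magnitude
    e_new = try_stage(indexed, 1.0)
    if e_new is not None:
        return e_new
    # stage 3: only the chains whose own trial lowered the energy
    winners = [(i, d) for i, d in indexed if trial_de[i] < 0.0]
    if winners:
        e_new = try_stage(winners, 1.0)
        if e_new is not None:
            return e_new
    # stage 4: full rollback already performed by the failed try_stage
    return e_k
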