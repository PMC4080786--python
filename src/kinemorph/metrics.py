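"""Validation indicators: backbone RMSD, Ramachandran fraction, energy drift.

Three independent views of morph quality: global structural similarity
(backbone RMSD, optionally after least-squares superposition), biological
plausibility (fraction of residues inside preferred Ramachandran regions)
and steric health (percentage energy change relative to a reference).
"""

from __future__ import annotations

import numpy as np

from .structure_io import BACKBONE_ATOMS, ProteinModel, StructureError

#: Generous preferred-region boxes of the Ramachandran plane, degrees.
#: Each region lists phi intervals and psi intervals; a residue is inside a
#: region when phi falls in any phi interval and psi in any psi interval.
DEFAULT_REGIONS: list[dict] = [
    {"name": "alpha", "phi": [(-180.0, 0.0)], "psi": [(-120.0, 50.0)]},
    {"name": "beta", "phi": [(-180.0, -20.0)],
     "psi": [(50.0, 180.0), (-180.0, -170.0)]},
    {"name": "left-alpha", "phi": [(20.0, 100.0)], "psi": [(-20.0, 90.0)]},
]


def _backbone_coords(model: ProteinModel) -> np.ndarray:
    idx = []
    for res in model.residues:
        for name in BACKBONE_ATOMS:
            if res.has_atom(name):
                idx.append(res.atom_index(name))
    return model.coords[idx]


def kabsch_rotation(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix aligning centred ``moving`` onto ``fixed``."""
    h = moving.T @ fixed
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def backbone_rmsd(model_a: ProteinModel, model_b: ProteinModel,
                  superpose: bool = True) -> float:
    """Root-mean-square deviation over N, Calpha, C, O atoms (Angstrom).

    With ``superpose`` the optimal least-squares rigid alignment (Kabsch) is
    applied first; the result is then invariant to any rigid-body motion of
    either model and symmetric in its arguments.
    """
    if model_a.n_residues != model_b.n_residues:
        raise StructureError(
            f"residue count mismatch: {model_a.n_residues} vs {model_b.n_residues}")
    a = _backbone_coords(model_a)
    b = _backbone_coords(model_b)
    if a.shape != b.shape:
        raise StructureError("backbone atom sets differ between the models")
    if superpose:
        ca, cb = a.mean(axis=0), b.mean(axis=0)
        a0, b0 = a - ca, b - cb
        rot = kabsch_rotation(a0, b0)
        diff = a0 @ rot.T - b0
    else:
        diff = a - b
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def in_preferred_region(phi: float, psi: float,
                        regions: list[dict] | None = None) -> bool:
    """Membership test against the configured preferred-region boxes.

    Intervals are half-open [lo, hi) except that an upper bound of 180
    is inclusive (the angle wrap point).
    """
    regions = DEFAULT_REGIONS if regions is None else regions

    def inside(x: float, intervals) -> bool:
        return any(lo <= x < hi or (hi == 180.0 and x == 180.0)
                   for lo, hi in intervals)

    return any(inside(phi, reg["phi"]) and inside(psi, reg["psi"])
               for reg in regions)


def ramachandran_fraction(model, regions: list[dict] | None = None) -> float:
    """Percentage of residues with (phi, psi) inside a preferred region.

    Terminal residues missing one of the angles are excluded from the
    denominator.  ``model`` may also be an iterable of (phi, psi) pairs.
    """
    if hasattr(model, "phi_psi"):
        angles = [model.phi_psi(i) for i in range(model.n_residues)]
    else:
        angles = list(model)
    defined = [(p, s) for p, s in angles if p is not None and s is not None]
    if not defined:
        raise StructureError("no residue has both phi and psi defined")
    n_in = sum(1 for p, s in defined if in_preferred_region(p, s, regions))
    return 100.0 * n_in / len(defined)


def energy_change_pct(e_ref: float, e: float) -> float:
    """Percentage energy change relative to |e_ref| (signed)."""
    if e_ref == 0:
        raise ValueError("reference energy is zero; percentage undefined")
    return 100.0 * (e - e_ref) / abs(e_ref)
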