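"""Geometric normalization of experimental structures to the kinematic model.

X-ray structures violate the rigid-model hypotheses slightly: peptide groups
are not exactly planar and equivalent bonds differ in length.  Two passes
homogenize them:

* **peptide-plane normalization** — per peptide bond, a least-squares middle
  plane through the Calpha_i -> Calpha_{i+1} axis is fitted to the local
  coordinates of C_i, O_i, N_{i+1}, and those three atoms are orthogonally
  projected onto it.  Both Calpha positions are fixed, so normalizing plane
  *i* never disturbs plane *i-1* and the backbone stays continuous.  After
  projection the five plane atoms are exactly coplanar, hence omega is
  exactly 0 or 180 degrees (up to floating-point roundoff) and the peptide
  bond angle stops being a degree of freedom.

* **bond-length normalization** — every covalent bond is set to a reference
  equilibrium length (AMBER-style values), sequentially from the first atom
  of the chain to the last.  Repositioning atom *i* along the existing j->i
  bond direction and rigidly translating its covalent-tree descendants
  leaves every torsion angle unchanged and never disturbs a bond fixed
  earlier.

The sequential strategy applies planes first, then lengths, so the length
pass repairs the small bond stretches the projection introduces.
"""

from __future__ import annotations

import numpy as np

from .kinematics import GeometryError, local_frame
from .structure_io import ProteinModel, StructureError

#: Reference equilibrium bond lengths (Angstrom).  Keys are either named
#: backbone atom pairs (order as bonded, j then i) or element pairs used as a
#: fallback for side-chain bonds.  Override via the ``reference_lengths``
#: argument of the normalization functions.
DEFAULT_BOND_LENGTHS: dict[tuple[str, str], float] = {
    # backbone, by atom name
    ("N", "CA"): 1.449,
    ("CA", "C"): 1.522,
    ("C", "O"): 1.229,
    ("C", "OXT"): 1.229,
    ("C", "N"): 1.335,   # peptide bond
    ("CA", "CB"): 1.526,
    # side chains, by element pair (sorted)
    ("C", "C"): 1.526,
    ("C", "S"): 1.810,
    ("N", "N"): 1.350,
    ("O", "O"): 1.480,
    ("S", "S"): 2.040,
    ("ELEM_C", "ELEM_N"): 1.471,
    ("ELEM_C", "ELEM_O"): 1.410,
}


def reference_length(model: ProteinModel, j: int, i: int,
                     table: dict[tuple[str, str], float]) -> float:
    """Look up the reference length of the j-i bond.

    Named backbone pairs take precedence; unnamed bonds fall back to the
    element pair.  A missing entry is a hard error naming the bond.
    """
    nj, ni = model.atoms[j].name, model.atoms[i].name
    if (nj, ni) in table:
        return table[(nj, ni)]
    if (ni, nj) in table:
        return table[(ni, nj)]
    ej, ei = sorted((model.atoms[j].element, model.atoms[i].element))
    if ej != ei and (f"ELEM_{ej}", f"ELEM_{ei}") in table:
        return table[(f"ELEM_{ej}", f"ELEM_{ei}")]
    if (ej, ei) in table:
        return table[(ej, ei)]
    raise StructureError(
        f"no reference length for bond {nj}-{ni} "
        f"(residue {model.atoms[j].residue_index}-{model.atoms[i].residue_index})")


def fit_plane_slope(pairs) -> float:
    """Least-squares slope *a* of the middle plane ``w = a v``.

    ``pairs`` are the (v, w) local coordinates of C_i, O_i, N_{i+1}; the
    plane always contains the u axis, so the fit reduces to one slope:
    ``a = (sum w_j v_j) / (sum v_j^2)``.
    """
    pairs = np.asarray(pairs, dtype=float).reshape(-1, 2)
    v, w = pairs[:, 0], pairs[:, 1]
    denom = float(np.dot(v, v))
    if denom < 1e-300:
        raise GeometryError("plane slope undefined: all v coordinates are zero")
    return float(np.dot(w, v) / denom)


def normalize_peptide_plane(model: ProteinModel, i: int) -> ProteinModel:
    """Flatten peptide plane *i* in place; both Calpha atoms are fixed."""
    frame = local_frame(model, i)
    res_i, res_j = model.residues[i], model.residues[i + 1]
    idx = [res_i.atom_index("C"), res_j.atom_index("N")]
    if res_i.has_atom("O"):
        idx.insert(1, res_i.atom_index("O"))
    local = frame.to_local(model.coords[idx])
    a = fit_plane_slope(local[:, 1:3])
    v, w = local[:, 1], local[:, 2]
    shift = (w - a * v) / (1.0 + a * a)
    local[:, 1] = v + a * shift
    local[:, 2] = w - shift
    model.coords[idx] = frame.to_world(local)
    return model


def normalize_planes(model: ProteinModel) -> ProteinModel:
    """Flatten every peptide plane, sequentially along the chain."""
    for i in range(model.n_residues - 1):
        normalize_peptide_plane(model, i)
    return model


def apply_distance_constraint(model: ProteinModel, j: int, i: int,
                              d_ji: float) -> ProteinModel:
    """Set |r_i - r_j| = d_ji, keeping atom *i* on the original j->i line.

    The sphere constraint fixes the distance and the line constraint makes
    the solution unique; the covalent-tree descendants of *i* (not crossing
    back through *j*) are rigidly translated by the same shift, which keeps
    all downstream bond lengths and every torsion angle unchanged.
    """
    rj = model.coords[j]
    ri = model.coords[i]
    diff = ri - rj
    norm = np.linalg.norm(diff)
    if norm < 1e-9:
        raise GeometryError(
            f"atoms {j} and {i} coincide; bond direction undefined")
    new_ri = rj + d_ji * diff / norm
    shift = new_ri - ri
    model.coords[i] = new_ri
    downstream = model.descendants(i, j)
    if downstream.size:
        model.coords[downstream] += shift
    return model


def normalize_lengths(model: ProteinModel,
                      reference_lengths: dict | None = None) -> ProteinModel:
    """Impose reference lengths on every covalent bond, in chain order."""
    table = DEFAULT_BOND_LENGTHS if reference_lengths is None else reference_lengths
    for j, i in model.bonds:  # bonds are stored parent->child in chain order
        apply_distance_constraint(model, j, i, reference_length(model, j, i, table))
    return model


def normalize_sequential(model: ProteinModel,
                         reference_lengths: dict | None = None) -> ProteinModel:
    """Planes first, lengths second: after this both model hypotheses hold
    simultaneously (omega in {0, 180} and all bonds at reference length)."""
    normalize_planes(model)
    normalize_lengths(model, reference_lengths)
    return model
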