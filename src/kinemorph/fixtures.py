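"""Synthetic polypeptide generator with exact ideal geometry.

Builds single-chain models from a sequence and requested (phi, psi, omega)
lists by sequential internal-to-Cartesian placement: every bond length sits
exactly on the reference table, bond angles at ideal peptide values, and
peptide planes are exactly planar, so generator output is already normalized
and satisfies every hypothesis of the kinematic model.  Side chains are
built through Cbeta plus a single pseudo carbon ("CG") for residues other
than glycine and alanine — enough surface to exercise the chi1 degree of
freedom and the side-chain orientation procedure without a rotamer library.
These are synthetic stand-ins for experimental structures, not predictions
of real side-chain geometry.

:func:`perturb_geometry` adds seeded Gaussian noise to bond lengths and
peptide-plane twist, emulating the imperfection of deposited X-ray
coordinates that the normalization module exists to repair.
"""

from __future__ import annotations

import numpy as np

from .kinematics import place_atom
from .normalization import DEFAULT_BOND_LENGTHS, apply_distance_constraint
from .structure_io import Atom, ProteinModel, Residue

AA_3LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: ideal backbone bond angles, degrees
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.4
ANGLE_C_CA_CB = 111.1
ANGLE_CA_CB_CG = 114.0
TORSION_N_C_CA_CB = 122.6  # improper placing Cbeta off the backbone plane (L)
DEFAULT_CHI1 = -60.0

# preset (phi, psi) used by helpers and the CLI.  The extended preset keeps
# psi below +133 so that, starting from the helix, the minimal wrapped
# rotation direction leaves through the allowed upper corridor of the
# Ramachandran plane instead of wrapping psi through the self-intersecting
# tight-spiral region around (-75, -80).
CONFORMATIONS = {
    "helix": (-57.0, -47.0),
    "sheet": (-120.0, 120.0),
    "extended": (-130.0, 130.0),
}


def _as_list(value, n: int, name: str) -> list[float]:
    if np.ndim(value) == 0:
        return [float(value)] * n
    out = [float(x) for x in value]
    if len(out) != n:
        raise ValueError(f"{name} list has length {len(out)}, expected {n}")
    return out


def build_peptide(sequence: str, phi, psi, omega=180.0,
                  chi1=DEFAULT_CHI1) -> ProteinModel:
    """Build an ideal-geometry polypeptide.

    ``phi``/``psi`` are scalars or per-residue lists (degrees); ``phi[0]``
    and the torsional use of ``psi[-1]`` only orient terminal groups.
    ``omega`` covers the n-1 peptide bonds (scalar or list, 180 = trans).
    The measured dihedrals of the result equal the request to ~1e-6 degree.
    """
    sequence = sequence.strip().upper()
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    resnames = []
    for letter in sequence:
        if letter not in AA_3LETTER:
            raise ValueError(f"unknown residue letter {letter!r}")
        resnames.append(AA_3LETTER[letter])
    phi = _as_list(phi, n, "phi")
    psi = _as_list(psi, n, "psi")
    omega = _as_list(omega, max(n - 1, 1), "omega")
    chi1 = _as_list(chi1, n, "chi1")

    b = DEFAULT_BOND_LENGTHS
    d_n_ca, d_ca_c = b[("N", "CA")], b[("CA", "C")]
    d_c_o, d_c_n = b[("C", "O")], b[("C", "N")]
    d_ca_cb, d_cb_cg = b[("CA", "CB")], b[("C", "C")]

    # backbone N/CA/C positions first
    pos_n = [np.zeros(3)]
    pos_ca = [np.array([d_n_ca, 0.0, 0.0])]
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    pos_c = [pos_ca[0] + d_ca_c * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(n - 1):
        pos_n.append(place_atom(pos_n[i], pos_ca[i], pos_c[i],
                                d_c_n, ANGLE_CA_C_N, psi[i]))
        pos_ca.append(place_atom(pos_ca[i], pos_c[i], pos_n[i + 1],
                                 d_n_ca, ANGLE_C_N_CA, omega[i]))
        pos_c.append(place_atom(pos_c[i], pos_n[i + 1], pos_ca[i + 1],
                                d_ca_c, ANGLE_N_CA_C, phi[i + 1]))

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    residues: list[Residue] = []
    serial = 1

    def add_atom(res: Residue, name: str, element: str, xyz) -> None:
        nonlocal serial
        res.atom_indices[name] = len(atoms)
        atoms.append(Atom(serial=serial, name=name, element=element,
                          residue_index=len(residues)))
        coords.append(np.asarray(xyz, dtype=float))
        serial += 1

    for i, resname in enumerate(resnames):
        res = Residue(name=resname, resseq=i + 1)
        add_atom(res, "N", "N", pos_n[i])
        add_atom(res, "CA", "C", pos_ca[i])
        add_atom(res, "C", "C", pos_c[i])
        # carbonyl O in the peptide plane, anti to the next N
        o = place_atom(pos_n[i], pos_ca[i], pos_c[i],
                       d_c_o, ANGLE_CA_C_O, psi[i] + 180.0)
        add_atom(res, "O", "O", o)
        if resname != "GLY":
            cb = place_atom(pos_n[i], pos_c[i], pos_ca[i],
                            d_ca_cb, ANGLE_C_CA_CB, TORSION_N_C_CA_CB)
            add_atom(res, "CB", "C", cb)
            if resname not in ("ALA", "PRO"):
                cg = place_atom(pos_n[i], pos_ca[i], cb,
                                d_cb_cg, ANGLE_CA_CB_CG, chi1[i])
                add_atom(res, "CG", "C", cg)
        residues.append(res)

    return ProteinModel(atoms, np.array(coords), residues)


def helix_extended_pair(sequence: str = "LLLLLLLLLL", chi1: float = 75.0):
    """Desk-scale morph endpoints: an alpha-helix and an extended chain.

    The default chi1 of +75 degrees presses the pseudo side chains against
    the backbone carbonyls of the helix, giving it the mildly strained,
    positive potential energy characteristic of unrefined experimental
    coordinates — the regime the percentage-based energy control law
    presumes — while the extended target is relaxed, so the morph relieves
    the strain as it unwinds.
    """
    h_phi, h_psi = CONFORMATIONS["helix"]
    e_phi, e_psi = CONFORMATIONS["extended"]
    return (build_peptide(sequence, h_phi, h_psi, chi1=chi1),
            build_peptide(sequence, e_phi, e_psi, chi1=chi1))


def perturb_geometry(model: ProteinModel, bond_noise: float = 0.0,
                     plane_twist: float = 0.0, seed: int = 0) -> ProteinModel:
    """Seeded Gaussian perturbation of bond lengths and peptide planarity.

    ``bond_noise`` (Angstrom s.d.) jitters every covalent bond length via
    the same downstream-translation mechanics the normalizer uses, so
    connectivity and torsions are preserved.  ``plane_twist`` (degree s.d.)
    twists each peptide bond (omega) and tips each carbonyl O out of plane.
    Deterministic for a fixed seed; the input model is not modified.
    """
    if bond_noise < 0 or plane_twist < 0:
        raise ValueError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    out = model.copy()

    if bond_noise > 0:
        for j, i in out.bonds:
            d = float(np.linalg.norm(out.coords[i] - out.coords[j]))
            apply_distance_constraint(out, j, i,
                                      d + rng.normal(0.0, bond_noise))
    if plane_twist > 0:
        from .kinematics import rotate_about_axis

        for i in range(out.n_residues - 1):
            c = out.residues[i].atom_index("C")
            nn = out.residues[i + 1].atom_index("N")
            # twist omega: rotate everything past the peptide bond
            downstream = out.descendants(nn, c)
            if downstream.size:
                out.coords[downstream] = rotate_about_axis(
                    out.coords[downstream], out.coords[nn],
                    out.coords[nn] - out.coords[c],
                    rng.normal(0.0, plane_twist))
            # tip the carbonyl O out of the plane
            if out.residues[i].has_atom("O"):
                o = out.residues[i].atom_index("O")
                ca = out.residues[i].atom_index("CA")
                out.coords[[o]] = rotate_about_axis(
                    out.coords[[o]], out.coords[c],
                    out.coords[c] - out.coords[ca],
                    rng.normal(0.0, plane_twist))
    return out
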