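"""PDB reading/writing and construction of the kinematic protein model.

A :class:`ProteinModel` is an all-atom, ball-and-rods representation of a
single chain: coordinates live in one ``(n_atoms, 3)`` array, residues index
into it, and a covalent-bond tree supplies the moving set of every degree of
freedom.  Degrees of freedom are backbone phi (residues 2..N), psi
(residues 1..N-1) and, optionally, the side-chain Calpha-Cbeta torsion
(chi1) of every residue with at least one atom beyond Cbeta.  Rotating a
phi/psi DOF carries the entire downstream chain (all atoms reachable from
the second axis atom without crossing the bond), so peptide planes stay
internally rigid.

PDB I/O is delegated to gemmi; only the first MODEL of a file is used, the
highest-occupancy altloc is kept (ties resolved toward 'A'), and
HETATM/water records are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: maximum covalent-bond distance by element pair (Angstrom), used when the
#: side-chain connectivity beyond Cbeta must be inferred from geometry
_BOND_CUTOFF_DEFAULT = 1.95
_BOND_CUTOFF_S = 2.2


class StructureError(ValueError):
    """Malformed or unsupported input structure."""


class TopologyError(ValueError):
    """Inconsistent topology between models that must share it."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0


@dataclass
class Residue:
    name: str
    resseq: int
    atom_indices: dict[str, int] = field(default_factory=dict)

    def atom_index(self, name: str) -> int:
        try:
            return self.atom_indices[name]
        except KeyError:
            raise StructureError(
                f"residue {self.name}{self.resseq} has no atom {name!r}"
            ) from None

    def has_atom(self, name: str) -> bool:
        return name in self.atom_indices

    @property
    def sidechain_atoms(self) -> list[int]:
        """Indices of atoms beyond Cbeta (i.e. neither backbone nor CB)."""
        skip = set(BACKBONE_ATOMS) | {"CB", "OXT", "H"}
        return [i for n, i in self.atom_indices.items() if n not in skip]


@dataclass(frozen=True)
class Dof:
    """One rotational degree of freedom: a bond axis plus its moving set."""

    kind: str  # 'phi' | 'psi' | 'chi1'
    residue_index: int
    axis: tuple[int, int]  # rotation about axis[0] -> axis[1]
    moving: np.ndarray  # atom indices displaced by this rotation

    def __repr__(self) -> str:  # moving set too noisy for repr
        return f"Dof({self.kind}, res={self.residue_index}, axis={self.axis})"


class ProteinModel:
    """Single-chain all-atom model with covalent topology."""

    def __init__(self, atoms: list[Atom], coords: np.ndarray,
                 residues: list[Residue], chain_id: str = "A"):
        if len(residues) == 0:
            raise StructureError("model has zero residues")
        self.atoms = atoms
        self.coords = np.asarray(coords, dtype=float).reshape(len(atoms), 3)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        self.residues = residues
        self.chain_id = chain_id
        self._validate_backbone()
        self.bonds = self._build_bonds()
        self._adjacency = self._build_adjacency()

    # -- construction -------------------------------------------------

    def _validate_backbone(self) -> None:
        last = len(self.residues) - 1
        for i, res in enumerate(self.residues):
            required = ("N", "CA", "C") if i == last else BACKBONE_ATOMS
            for name in required:
                if not res.has_atom(name):
                    raise StructureError(
                        f"missing backbone atom {name} in residue "
                        f"{res.name}{res.resseq} (chain position {i})"
                    )

    def _build_bonds(self) -> list[tuple[int, int]]:
        bonds: list[tuple[int, int]] = []
        for i, res in enumerate(self.residues):
            n, ca, c = (res.atom_index(x) for x in ("N", "CA", "C"))
            bonds.append((n, ca))
            bonds.append((ca, c))
            if res.has_atom("O"):
                bonds.append((c, res.atom_index("O")))
            if res.has_atom("OXT"):
                bonds.append((c, res.atom_index("OXT")))
            if res.has_atom("CB"):
                bonds.append((ca, res.atom_index("CB")))
            side = res.sidechain_atoms
            if side:
                bonds.extend(self._sidechain_bonds(res, side))
            if i + 1 < len(self.residues):
                bonds.append((c, self.residues[i + 1].atom_index("N")))
        return bonds

    def _sidechain_bonds(self, res: Residue, side: list[int]) -> list[tuple[int, int]]:
        """Greedy distance-based connectivity for atoms beyond Cbeta.

        Each side-chain atom is attached to its nearest already-connected
        atom of the residue within the covalent cutoff; this recovers the
        tree topology of standard side chains (rings gain no extra DOFs
        because only chi1 is ever rotated).
        """
        connected = [res.atom_index("CB")] if res.has_atom("CB") else [res.atom_index("CA")]
        bonds = []
        remaining = sorted(side, key=lambda i: np.linalg.norm(
            self.coords[i] - self.coords[connected[0]]))
        for i in remaining:
            dists = [np.linalg.norm(self.coords[i] - self.coords[j]) for j in connected]
            j = connected[int(np.argmin(dists))]
            cutoff = _BOND_CUTOFF_S if "S" in (
                self.atoms[i].element, self.atoms[j].element) else _BOND_CUTOFF_DEFAULT
            d = np.linalg.norm(self.coords[i] - self.coords[j])
            if d > cutoff:
                # distant ring/branch atom: attach to nearest regardless, the
                # side chain is rotated only rigidly about Calpha-Cbeta
                pass
            bonds.append((j, i))
            connected.append(i)
        return bonds

    def _build_adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    # -- queries ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atom_index(self, residue_index: int, name: str) -> int:
        return self.residues[residue_index].atom_index(name)

    def copy(self) -> "ProteinModel":
        m = ProteinModel.__new__(ProteinModel)
        m.atoms = self.atoms
        m.coords = self.coords.copy()
        m.residues = self.residues
        m.chain_id = self.chain_id
        m.bonds = self.bonds
        m._adjacency = self._adjacency
        return m

    def descendants(self, start: int, blocked: int) -> np.ndarray:
        """Atoms reachable from ``start`` without crossing atom ``blocked``.

        ``start`` itself is excluded.  This is the moving set of a rotation
        about the blocked->start bond and the propagation set of a distance
        constraint repositioning ``start``.
        """
        seen = {start, blocked}
        stack = [start]
        out = []
        while stack:
            a = stack.pop()
            for b in self._adjacency[a]:
                if b not in seen:
                    seen.add(b)
                    out.append(b)
                    stack.append(b)
        return np.array(sorted(out), dtype=int)

    def peptide_planes(self) -> list[list[int]]:
        """Atom-index sets {CA_i, C_i, O_i, N_{i+1}, CA_{i+1}} per bond i."""
        planes = []
        for i in range(self.n_residues - 1):
            ri, rj = self.residues[i], self.residues[i + 1]
            plane = [ri.atom_index("CA"), ri.atom_index("C")]
            if ri.has_atom("O"):
                plane.append(ri.atom_index("O"))
            plane.extend([rj.atom_index("N"), rj.atom_index("CA")])
            planes.append(plane)
        return planes

    # -- dihedral bookkeeping -----------------------------------------

    def backbone_dihedral(self, kind: str, i: int) -> float:
        """Measured phi/psi/omega (degrees) of residue ``i``."""
        from .kinematics import dihedral

        res = self.residues[i]
        if kind == "phi":
            prev = self.residues[i - 1]
            return dihedral(self.coords[prev.atom_index("C")],
                            self.coords[res.atom_index("N")],
                            self.coords[res.atom_index("CA")],
                            self.coords[res.atom_index("C")])
        if kind == "psi":
            nxt = self.residues[i + 1]
            return dihedral(self.coords[res.atom_index("N")],
                            self.coords[res.atom_index("CA")],
                            self.coords[res.atom_index("C")],
                            self.coords[nxt.atom_index("N")])
        if kind == "omega":
            nxt = self.residues[i + 1]
            return dihedral(self.coords[res.atom_index("CA")],
                            self.coords[res.atom_index("C")],
                            self.coords[nxt.atom_index("N")],
                            self.coords[nxt.atom_index("CA")])
        raise ValueError(f"unknown dihedral kind {kind!r}")

    def phi_psi(self, i: int) -> tuple[float | None, float | None]:
        phi = self.backbone_dihedral("phi", i) if i > 0 else None
        psi = self.backbone_dihedral("psi", i) if i < self.n_residues - 1 else None
        return phi, psi


def enumerate_dofs(model: ProteinModel, include_sidechains: bool = False,
                   lock_proline_phi: bool = False) -> list[Dof]:
    """Ordered DOF list: per residue phi then psi (2N-2 backbone DOFs),
    chi1 torsions appended for residues with atoms beyond Cbeta.

    Proline phi can be locked out (ring closure makes it nearly immobile in
    real proteins); proline chi1 is always locked.
    """
    dofs: list[Dof] = []
    n = model.n_residues
    for i, res in enumerate(model.residues):
        if i > 0 and not (lock_proline_phi and res.name == "PRO"):
            nn, ca = res.atom_index("N"), res.atom_index("CA")
            dofs.append(Dof("phi", i, (nn, ca), model.descendants(ca, nn)))
        if i < n - 1:
            ca, c = res.atom_index("CA"), res.atom_index("C")
            dofs.append(Dof("psi", i, (ca, c), model.descendants(c, ca)))
    if include_sidechains:
        for i, res in enumerate(model.residues):
            if res.name == "PRO" or not res.has_atom("CB"):
                continue
            if not res.sidechain_atoms:
                continue  # GLY/ALA: nothing beyond Cbeta to move
            ca, cb = res.atom_index("CA"), res.atom_index("CB")
            moving = model.descendants(cb, ca)
            if moving.size:
                dofs.append(Dof("chi1", i, (ca, cb), moving))
    return dofs


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties -> altloc 'A', then
    first encountered."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        if atom.occ > prev.occ or (
                atom.occ == prev.occ and atom.altloc == "A" and prev.altloc != "A"):
            by_name[atom.name] = atom
    return list(by_name.values())


def read_pdb(path, chain_id: str | None = None) -> ProteinModel:
    """Read one chain of a PDB file into a :class:`ProteinModel`.

    First MODEL only; HETATM groups and waters dropped; altlocs resolved to
    the highest-occupancy conformer.  ``chain_id=None`` selects the first
    chain containing amino-acid residues.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    return _from_gemmi_model(st[0], chain_id, str(path))


def _from_gemmi_model(gmodel: gemmi.Model, chain_id: str | None,
                      source: str) -> ProteinModel:
    chain = None
    for ch in gmodel:
        if chain_id is not None and ch.name != chain_id:
            continue
        if any(_is_amino(r) for r in ch):
            chain = ch
            break
    if chain is None:
        raise StructureError(
            f"no amino-acid chain {chain_id or ''!s} found in {source}")

    atoms: list[Atom] = []
    coords: list[list[float]] = []
    residues: list[Residue] = []
    for gres in chain:
        if not _is_amino(gres):
            continue
        res = Residue(name=gres.name, resseq=gres.seqid.num)
        for gatom in _resolve_altlocs(gres):
            idx = len(atoms)
            res.atom_indices[gatom.name] = idx
            atoms.append(Atom(serial=gatom.serial, name=gatom.name,
                              element=gatom.element.name,
                              residue_index=len(residues),
                              occupancy=gatom.occ, altloc=gatom.altloc,
                              bfactor=gatom.b_iso))
            coords.append([gatom.pos.x, gatom.pos.y, gatom.pos.z])
        residues.append(res)
    if not residues:
        raise StructureError(f"no amino-acid residues in {source}")
    return ProteinModel(atoms, np.array(coords), residues, chain_id=chain.name)


def _is_amino(gres: gemmi.Residue) -> bool:
    if gres.name in ("HOH", "WAT"):
        return False
    info = gemmi.find_tabulated_residue(gres.name)
    if info is not None and info.is_amino_acid():
        return True
    # unknown residue: accept if it carries a protein backbone
    names = {a.name for a in gres}
    return {"N", "CA", "C"} <= names


def _to_gemmi_model(model: ProteinModel, number: int) -> gemmi.Model:
    gm = gemmi.Model(number)
    chain = gemmi.Chain(model.chain_id)
    for ri, res in enumerate(model.residues):
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.resseq, " ")
        for name, idx in res.atom_indices.items():
            ga = gemmi.Atom()
            ga.name = name
            ga.element = gemmi.Element(model.atoms[idx].element)
            ga.occ = model.atoms[idx].occupancy
            ga.b_iso = model.atoms[idx].bfactor
            x, y, z = model.coords[idx]
            ga.pos = gemmi.Position(round(x, 3), round(y, 3), round(z, 3))
            gres.add_atom(ga)
        chain.add_residue(gres)
    gm.add_chain(chain)
    return gm


def write_pdb(model: ProteinModel, path) -> None:
    """Write a single-model PDB file (fixed columns, 3-decimal Angstrom)."""
    write_trajectory([model], path)


def write_trajectory(models, path) -> None:
    """Write a multi-MODEL PDB trajectory readable by standard viewers.

    All frames must share topology (same residues/atom names in order).
    """
    models = list(models)
    if not models:
        raise ValueError("empty trajectory")
    ref = models[0]
    for m in models[1:]:
        if m.n_atoms != ref.n_atoms or any(
                a.name != b.name or a.residue_index != b.residue_index
                for a, b in zip(m.atoms, ref.atoms)):
            raise TopologyError("trajectory frames do not share topology")
    st = gemmi.Structure()
    st.name = "kinemorph"
    for k, m in enumerate(models, start=1):
        st.add_model(_to_gemmi_model(m, k))
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def read_trajectory(path, chain_id: str | None = None) -> list[ProteinModel]:
    """Read every MODEL block of a PDB file as a list of ProteinModels."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return [_from_gemmi_model(gm, chain_id, str(path)) for gm in st]
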