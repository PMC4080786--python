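"""AMBER-style nonbonded potential for steric-clash screening.

Under the rigid kinematic model, bond and angle terms are constants, so the
potential used to police the morph is the nonbonded sum only: 12-6
Lennard-Jones plus Coulomb over all atom pairs separated by three or more
bonds, with the customary 1-4 scaling (electrostatics divided by 1.2, van
der Waals by 2.0) and 1-2/1-3 pairs excluded.  Parameters are a heavy-atom
(united-atom-style) set shipped with the package: element-based LJ
radii/depths and a per-residue-neutral backbone charge template; deposited
X-ray inputs lack hydrogens and the simulation only consumes energy
*changes*, which this level of parameterization resolves well.

Absolute energies are in kcal/mol but are not comparable to MD-grade AMBER
values; only relative and percentage behaviour is meaningful.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import yaml

from .structure_io import ProteinModel


class EnergyError(ValueError):
    """Unphysical configuration (coincident atoms) or missing parameters."""


class ForceFieldParams:
    """Per-element LJ parameters, charge templates and scaling factors.

    ``overrides`` (a nested dict with the same shape as the packaged YAML)
    replaces individual entries; ``path`` loads a full replacement file.
    """

    def __init__(self, path=None, overrides: dict | None = None):
        if path is None:
            text = resources.files("kinemorph.data").joinpath(
                "forcefield.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        data = yaml.safe_load(text)
        if overrides:
            for key, val in overrides.items():
                if isinstance(val, dict) and isinstance(data.get(key), dict):
                    data[key].update(val)
                else:
                    data[key] = val
        self.elements: dict[str, dict] = data["elements"]
        self.backbone_charges: dict[str, float] = data["charges"]["backbone"]
        self.default_charge: float = float(data["charges"]["default"])
        self.elec14: float = float(data["scaling"]["elec14"])
        self.vdw14: float = float(data["scaling"]["vdw14"])
        self.coulomb_constant: float = float(data["coulomb_constant"])
        self.dielectric: float = float(data["dielectric"])
        self.cutoff: float | None = data.get("cutoff")
        for el, p in self.elements.items():
            if p["epsilon"] < 0:
                raise EnergyError(f"negative LJ well depth for element {el}")

    def lj(self, element: str) -> tuple[float, float]:
        try:
            p = self.elements[element]
        except KeyError:
            raise EnergyError(f"no LJ parameters for element {element!r}") from None
        return float(p["rmin2"]), float(p["epsilon"])

    def charge(self, atom_name: str) -> float:
        return float(self.backbone_charges.get(atom_name, self.default_charge))


class EnergyModel:
    """Pair list + parameters for one topology; evaluates E(coords).

    Pair exclusions and 1-4 scaling are derived from the model's covalent
    bond graph once at construction; the same instance serves every frame of
    a simulation because topology never changes.
    """

    def __init__(self, model: ProteinModel, params: ForceFieldParams | None = None):
        self.params = params or ForceFieldParams()
        n = model.n_atoms
        rmin2 = np.empty(n)
        eps = np.empty(n)
        q = np.empty(n)
        for i, atom in enumerate(model.atoms):
            rmin2[i], eps[i] = self.params.lj(atom.element)
            q[i] = self.params.charge(atom.name)

        sep = _bond_separations(model, max_sep=3)
        ii, jj = np.triu_indices(n, k=1)
        s = sep[ii, jj]
        keep = (s == 0) | (s >= 3)  # 0 encodes "farther than 3 bonds"
        self.pi = ii[keep]
        self.pj = jj[keep]
        is14 = s[keep] == 3
        self.eps_ij = np.sqrt(eps[self.pi] * eps[self.pj])
        self.rmin_ij = rmin2[self.pi] + rmin2[self.pj]
        ke = self.params.coulomb_constant / self.params.dielectric
        self.qq_ij = ke * q[self.pi] * q[self.pj]
        self.lj_scale = np.where(is14, 1.0 / self.params.vdw14, 1.0)
        self.elec_scale = np.where(is14, 1.0 / self.params.elec14, 1.0)

    def _pair_energy(self, coords: np.ndarray, mask=None) -> float:
        pi, pj = self.pi, self.pj
        eps, rmin = self.eps_ij, self.rmin_ij
        qq, ljs, els = self.qq_ij, self.lj_scale, self.elec_scale
        if mask is not None:
            pi, pj = pi[mask], pj[mask]
            eps, rmin, qq = eps[mask], rmin[mask], qq[mask]
            ljs, els = ljs[mask], els[mask]
        d = coords[pi] - coords[pj]
        r2 = np.einsum("ij,ij->i", d, d)
        if r2.size and r2.min() < 1e-12:
            k = int(np.argmin(r2))
            raise EnergyError(
                f"coincident atoms {pi[k]} and {pj[k]}: infinite energy")
        if self.params.cutoff is not None:
            within = r2 <= self.params.cutoff ** 2
            r2 = r2[within]
            eps, rmin, qq = eps[within], rmin[within], qq[within]
            ljs, els = ljs[within], els[within]
        inv_r2 = 1.0 / r2
        sr2 = rmin * rmin * inv_r2
        sr6 = sr2 * sr2 * sr2
        e_lj = np.sum(ljs * eps * (sr6 * sr6 - 2.0 * sr6))
        e_el = np.sum(els * qq * np.sqrt(inv_r2))
        return float(e_lj + e_el)

    def energy(self, coords: np.ndarray) -> float:
        """Total nonbonded energy (kcal/mol)."""
        return self._pair_energy(coords)

    def cross_energy(self, coords: np.ndarray, moving: np.ndarray) -> float:
        """Energy of pairs straddling the moving/static partition.

        Under a rigid rotation of ``moving``, the total energy change equals
        the change of this cross term, which is what makes incremental
        evaluation exact.
        """
        flag = np.zeros(coords.shape[0], dtype=bool)
        flag[moving] = True
        mask = flag[self.pi] != flag[self.pj]
        return self._pair_energy(coords, mask)


def _bond_separations(model: ProteinModel, max_sep: int = 3) -> np.ndarray:
    """Matrix of bond-path lengths up to ``max_sep`` (0 = farther)."""
    n = model.n_atoms
    sep = np.zeros((n, n), dtype=np.int8)
    adj = model._adjacency
    for start in range(n):
        dist = {start: 0}
        frontier = [start]
        for d in range(1, max_sep + 1):
            nxt = []
            for a in frontier:
                for b in adj[a]:
                    if b not in dist:
                        dist[b] = d
                        nxt.append(b)
                        sep[start, b] = d
            frontier = nxt
    return sep


def total_energy(model: ProteinModel, params: ForceFieldParams | None = None) -> float:
    """Total nonbonded potential energy of the model (kcal/mol)."""
    return _cached_energy_model(model, params).energy(model.coords)


def delta_energy(model: ProteinModel, params, dof, delta_deg: float) -> float:
    """Energy increment a DOF rotation would produce (model unchanged).

    Computed incrementally over the pairs that straddle the moving set;
    exactly equals total_energy(after) - total_energy(before).
    """
    from .kinematics import rotate_dof

    em = _cached_energy_model(model, params)
    before = em.cross_energy(model.coords, dof.moving)
    saved = model.coords[dof.moving].copy()
    rotate_dof(model, dof, delta_deg)
    after = em.cross_energy(model.coords, dof.moving)
    model.coords[dof.moving] = saved
    return after - before


def _cached_energy_model(model: ProteinModel, params) -> EnergyModel:
    cache = getattr(model, "_energy_model_cache", None)
    key = id(params)
    if cache is None:
        cache = {}
        model._energy_model_cache = cache
    if key not in cache:
        cache[key] = EnergyModel(model, params)
    return cache[key]
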