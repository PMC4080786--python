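"""Secondary-structure detection from backbone dihedral angles.

A residue is a *candidate* of a secondary-structure type when its (phi, psi)
pair lies within a square tolerance window around that type's canonical
Ramachandran zone centre (alpha-helix or beta-sheet; 30 degrees per angle by
default).  A candidate becomes *stable* only as part of a run of at least
three consecutive candidates of the same type — the three-residue rule that
keeps isolated coil residues from being labelled as structure even with a
generous tolerance.  Everything else is *unstable*.

The detector needs nothing but dihedral values, so it costs microseconds per
residue and can run every simulation step to decide which degrees of
freedom to freeze.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kinematics import wrap_angle

#: Canonical zone centres (phi0, psi0) in degrees.  The tolerance window is
#: applied per angle.  Overridable through every public function.
DEFAULT_CENTERS: dict[str, tuple[float, float]] = {
    "alpha": (-57.0, -47.0),
    "beta": (-120.0, 120.0),
}

DEFAULT_TOLERANCE = 30.0

CANDIDATE = "candidate"
STABLE = "stable"
UNSTABLE = "unstable"


@dataclass
class SsAnnotation:
    """Per-residue classification produced by the detector."""

    status: list[str] = field(default_factory=list)
    ss_type: list[str] = field(default_factory=list)  # 'alpha' | 'beta' | 'none'

    def __len__(self) -> int:
        return len(self.status)

    @property
    def stable_residues(self) -> list[int]:
        return [i for i, s in enumerate(self.status) if s == STABLE]

    def fraction(self, ss_type: str) -> float:
        """Percentage of residues detected as stable of the given type."""
        if not self.status:
            return 0.0
        n = sum(1 for s, t in zip(self.status, self.ss_type)
                if s == STABLE and t == ss_type)
        return 100.0 * n / len(self.status)


def classify_residue(phi, psi, tolerance: float = DEFAULT_TOLERANCE,
                     centers: dict | None = None) -> tuple[bool, str]:
    """Candidate test for a single residue.

    Returns ``(is_candidate, ss_type)``; a residue matching both zones is
    assigned alpha (the narrower, more stereotyped zone).  Terminal residues
    pass ``None`` for the undefined angle, and membership is then decided on
    the defined angle alone.
    """
    centers = centers or DEFAULT_CENTERS
    for ss_type in ("alpha", "beta"):
        if ss_type not in centers:
            continue
        phi0, psi0 = centers[ss_type]
        ok_phi = phi is None or abs(wrap_angle(phi - phi0)) <= tolerance
        ok_psi = psi is None or abs(wrap_angle(psi - psi0)) <= tolerance
        if ok_phi and ok_psi:
            return True, ss_type
    return False, "none"


def detect_secondary_structures(source, tolerance: float = DEFAULT_TOLERANCE,
                                centers: dict | None = None) -> SsAnnotation:
    """Annotate a chain: candidate runs of length >= 3 become stable.

    ``source`` is either a :class:`~kinemorph.structure_io.ProteinModel` or
    an iterable of (phi, psi) pairs in degrees (``None`` for undefined
    terminal angles).  The scan walks the chain once, left to right,
    extending each candidate run until a non-matching residue ends it.
    """
    if hasattr(source, "phi_psi"):
        angles = [source.phi_psi(i) for i in range(source.n_residues)]
    else:
        angles = list(source)

    ann = SsAnnotation()
    for phi, psi in angles:
        is_cand, ss_type = classify_residue(phi, psi, tolerance, centers)
        ann.status.append(CANDIDATE if is_cand else UNSTABLE)
        ann.ss_type.append(ss_type)

    # promote runs of >=3 same-type candidates to stable
    i = 0
    n = len(ann.status)
    while i < n:
        if ann.status[i] != CANDIDATE:
            i += 1
            continue
        j = i
        while j < n and ann.status[j] == CANDIDATE and ann.ss_type[j] == ann.ss_type[i]:
            j += 1
        if j - i >= 3:
            for k in range(i, j):
                ann.status[k] = STABLE
        i = j

    # unstable residues carry no type
    for k in range(n):
        if ann.status[k] == UNSTABLE:
            ann.ss_type[k] = "none"
    return ann
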