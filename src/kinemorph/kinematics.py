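"""Dihedral-angle geometry for the rigid peptide-plane kinematic model.

The protein is treated as a serial linkage whose only degrees of freedom are
rotations about backbone phi/psi bonds and the side-chain Calpha-Cbeta bond.
This module provides the primitives everything else is built on: torsion
measurement, rotation of a degree of freedom's moving set about its bond
axis, the per-residue local reference frame used by peptide-plane
normalization, and internal-to-Cartesian atom placement.

Angle conventions: degrees everywhere, wrapped to (-180, 180], IUPAC sign
(cis = 0, trans = 180).  All angular arithmetic passes through
:func:`wrap_angle`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Degenerate geometry (collinear torsion axis, coincident atoms...)."""


def wrap_angle(angle):
    """Wrap an angle or array of angles in degrees to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    w = a - 360.0 * np.floor((a + 180.0) / 360.0)
    w = np.where(w <= -180.0, w + 360.0, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle (degrees) of four points, IUPAC sign convention.

    Looking down the p2->p3 axis, the angle from the p1 half-plane to the
    p4 half-plane; 0 for cis (eclipsed), 180 for trans.  Raises
    :class:`GeometryError` when three consecutive points are collinear, in
    which case the half-planes are undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise GeometryError("coincident axis points in dihedral")
    b1u = b1 / nb1
    # components of b0/b2 perpendicular to the axis
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-9 or np.linalg.norm(w) < 1e-9:
        raise GeometryError("collinear points in dihedral")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def rotate_about_axis(coords: np.ndarray, origin, axis, delta_deg: float) -> np.ndarray:
    """Rotate points right-handedly by ``delta_deg`` about the line through
    ``origin`` with direction ``axis``."""
    origin = np.asarray(origin, dtype=float)
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise GeometryError("zero-length rotation axis")
    rot = Rotation.from_rotvec(np.radians(delta_deg) * axis / n)
    return rot.apply(coords - origin) + origin


def rotate_dof(model, dof, delta_deg: float):
    """Rotate a degree of freedom's moving set in place.

    Positive ``delta_deg`` increases the measured torsion about the bond
    (right-hand rule looking from axis atom *a* toward *b*).  Atoms outside
    the moving set are untouched; every bond length and all intra-plane
    distances are invariant because the moving set is rotated rigidly.
    Returns ``model`` for chaining.
    """
    if delta_deg == 0.0:
        return model
    ia, ib = dof.axis
    a = model.coords[ia]
    b = model.coords[ib]
    model.coords[dof.moving] = rotate_about_axis(
        model.coords[dof.moving], b, b - a, delta_deg
    )
    return model


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal frame anchored at Calpha_i.

    ``u`` points along Calpha_i -> Calpha_{i+1}; ``w`` is perpendicular to
    the plane spanned by ``u`` and the Calpha_i -> C_i direction, so C_i has
    a zero w-coordinate by construction; ``v = w x u`` completes the frame.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Coordinates of ``points`` in this frame (columns u, v, w)."""
        d = np.atleast_2d(points) - self.origin
        out = np.column_stack((d @ self.u, d @ self.v, d @ self.w))
        return out if np.ndim(points) == 2 else out[0]

    def to_world(self, local: np.ndarray) -> np.ndarray:
        local = np.atleast_2d(local)
        out = self.origin + np.outer(local[:, 0], self.u) \
            + np.outer(local[:, 1], self.v) + np.outer(local[:, 2], self.w)
        return out if out.shape[0] > 1 else out[0]


def local_frame(model, i: int) -> LocalFrame:
    """Peptide-plane reference frame of residue ``i`` (needs residue i+1)."""
    if i >= len(model.residues) - 1:
        raise GeometryError(f"residue {i} has no successor; no frame defined")
    ca_i = model.coords[model.residues[i].atom_index("CA")]
    ca_j = model.coords[model.residues[i + 1].atom_index("CA")]
    c_i = model.coords[model.residues[i].atom_index("C")]
    u = ca_j - ca_i
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise GeometryError(f"coincident Calpha atoms at residues {i}, {i + 1}")
    u = u / nu
    w = np.cross(u, c_i - ca_i)
    nw = np.linalg.norm(w)
    if nw < 1e-9:
        raise GeometryError(f"C atom of residue {i} collinear with the Calpha axis")
    w = w / nw
    v = np.cross(w, u)
    return LocalFrame(origin=ca_i, u=u, v=v, w=w)


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position a new atom D from three placed atoms by internal coordinates.

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D angle and ``torsion_deg`` the
    A-B-C-D torsion (natural extension reference / NeRF construction).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bcu = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bcu)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise GeometryError("collinear reference atoms in place_atom")
    n = n / nn
    m = np.cross(n, bcu)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bcu + d_local[1] * m + d_local[2] * n
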