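"""Geometric kernels: centers of mass, group COM distances, Kabsch
superposition and the radius of gyration used as the capture radius.

All routines accept plain (n, 3) coordinate arrays plus (n,) mass arrays
so they serve both all-atom structures and coarse-grained bead systems.
Mass weighting conventions:

* center of mass and radius of gyration are mass-weighted,
  r_COM = sum(m_i r_i) / sum(m_i),
  Rg = sqrt( sum(m_i |r_i - r_COM|^2) / sum(m_i) );
* least-squares superposition is mass-unweighted over the fitted atoms
  (the standard Cα least-squares convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, SelectionError
from .structure_io import Selection, Structure, resolve_selection

__all__ = [
    "RigidTransform",
    "center_of_mass",
    "com_distance",
    "kabsch_superpose",
    "radius_of_gyration",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation det(R) = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid transforms here")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _validate(coords, masses):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    if len(coords) == 0:
        raise SelectionError("point set is empty")
    if np.any(masses <= 0):
        raise ValueError("all masses must be > 0")
    if len(masses) != len(coords):
        raise ValueError("masses/coords length mismatch")
    return coords, masses


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position (Å)."""
    coords, masses = _validate(coords, masses)
    return masses @ coords / masses.sum()


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration about the group COM (Å).

    This is the capture-radius metric: sqrt(sum m_i |r_i - r_COM|^2 / sum m_i).
    """
    coords, masses = _validate(coords, masses)
    com = masses @ coords / masses.sum()
    d2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(masses @ d2 / masses.sum()))


def com_distance(structure: Structure, sel_a: Selection, sel_b: Selection,
                 atom_policy: str = "all") -> float:
    """Distance between the mass-weighted COMs of two selections (Å).

    ``atom_policy`` "all" uses every selected atom (heavy atoms in crystal
    inputs); "calpha" restricts both groups to Cα atoms.
    """
    out = []
    for name, sel in (("A", sel_a), ("B", sel_b)):
        if atom_policy == "calpha" and sel.atoms == "all":
            sel = Selection(sel.chain, sel.residues, "calpha")
        idx = resolve_selection(structure, sel)
        if len(idx) == 0:
            raise SelectionError(
                f"selection {name} ({sel.describe()}) resolved empty")
        out.append(center_of_mass(structure.coord[idx], structure.mass[idx]))
    return float(np.linalg.norm(out[0] - out[1]))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_indices=None) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimizing the unweighted sum of
    squared deviations over ``fit_indices`` (all points if None) and the
    post-fit RMSD over those points.  The reflection branch of the SVD is
    excluded by sign-correcting the smallest singular vector, so the
    result is always a rotation (det +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(len(mobile))
    idx = np.asarray(fit_indices, dtype=int)
    x = mobile[idx]
    y = reference[idx]
    if len(x) < 3:
        raise DegenerateFitError("need at least 3 fit points")
    if len(x) != len(y):
        raise DegenerateFitError("fit indices must pair mobile/reference 1:1")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(xc, tol=1e-10) < 2:
        raise DegenerateFitError("fit points are collinear")
    H = xc.T @ yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = y.mean(axis=0) - R @ x.mean(axis=0)
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(
        np.sum((transform.apply(x) - y) ** 2, axis=1))))
    return transform, rmsd
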