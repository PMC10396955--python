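"""Exit-vector-plot (EVP) parameters of a disubstituted scaffold.

Two substituents on a rigid scaffold are reduced to two exit vectors:
n1 points from attachment atom C1 toward the first substituent atom X1,
n2 from C2 toward X2.  Their relative arrangement is summarised by five
numbers:

* ``r``   — distance C1–C2 (Å), the length of the scaffold edge;
* ``d``   — distance X1–X2 (Å), how far apart the substituents start;
* ``phi1``/``phi2`` — the plane angles between each exit vector and the
  C1–C2 internuclear axis (degrees; 120° for an ideal aromatic ring);
* ``theta`` — the torsion of n1 and n2 about the C1–C2 axis (signed
  degrees, IUPAC convention), whose magnitude separates flat scaffolds
  (|theta| near 0) from three-dimensional ones.

Nothing is rounded here; presentation layers round to 0.01 Å and 1°.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateGeometryError, ValidationError
from .structio import MolecularStructure

_EPS = 1e-12


@dataclass(frozen=True)
class AttachmentSpec:
    """The four atoms defining the two exit vectors (0-based indices):
    scaffold attachment atoms c1/c2 and first substituent atoms x1/x2."""

    c1_index: int
    c2_index: int
    x1_index: int
    x2_index: int

    def __post_init__(self) -> None:
        idx = (self.c1_index, self.c2_index, self.x1_index, self.x2_index)
        if len(set(idx)) != 4:
            raise ValidationError(
                "attachment atoms must be four distinct indices, got "
                + ", ".join(str(i + 1) for i in idx)
            )

    def swapped(self) -> "AttachmentSpec":
        """Exchange the roles of (C1, X1) and (C2, X2)."""
        return AttachmentSpec(
            self.c2_index, self.c1_index, self.x2_index, self.x1_index
        )


@dataclass(frozen=True)
class ExitVector:
    """Origin (attachment atom, Å) and unit direction toward the first
    substituent atom."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(np.linalg.norm(self.direction)) - 1.0) > 1e-9:
            raise ValidationError("exit vector direction must be a unit vector")


@dataclass(frozen=True)
class EVPParameters:
    """The five-parameter geometric record of one disubstituted scaffold."""

    r: float
    d: float
    phi1: float
    phi2: float
    theta: float

    def __post_init__(self) -> None:
        if self.r < 0 or self.d < 0:
            raise ValidationError("distances r and d must be >= 0")
        for name in ("phi1", "phi2"):
            val = getattr(self, name)
            if not (0.0 <= val <= 180.0):
                raise ValidationError(f"{name} must lie in [0, 180], got {val}")
        if not (-180.0 < self.theta <= 180.0):
            raise ValidationError("theta must lie in (-180, 180]")

    @property
    def abs_theta(self) -> float:
        return abs(self.theta)

    def as_dict(self) -> dict[str, float]:
        return {
            "r": self.r,
            "d": self.d,
            "phi1": self.phi1,
            "phi2": self.phi2,
            "theta": self.theta,
            "abs_theta": self.abs_theta,
        }

    def rounded(self) -> dict[str, float]:
        """Presentation rounding: 0.01 Å for distances, 1° for angles."""
        return {
            "r": round(self.r, 2),
            "d": round(self.d, 2),
            "phi1": round(self.phi1),
            "phi2": round(self.phi2),
            "theta": round(self.theta),
            "abs_theta": round(self.abs_theta),
        }


def plane_angle(v, axis) -> float:
    """Unsigned angle in degrees, in [0, 180], between two vectors.

    Uses atan2(|v x axis|, v . axis), which stays accurate near 0 and
    180 where the arccos form loses precision.
    """
    v = np.asarray(v, dtype=float)
    axis = np.asarray(axis, dtype=float)
    nv, na = np.linalg.norm(v), np.linalg.norm(axis)
    if nv < _EPS or na < _EPS:
        raise ValidationError("plane_angle requires two nonzero vectors")
    cross = np.linalg.norm(np.cross(v, axis))
    dot = float(np.dot(v, axis))
    return float(np.degrees(np.arctan2(cross, dot)))


def torsion_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1–p2–p3–p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p2 toward p3, the far bond
    rotated clockwise from the near bond gives a positive angle.
    Computed with the atan2 cross-product formula, which is stable for
    all geometries except genuinely collinear frames.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < _EPS:
        raise DegenerateGeometryError("torsion axis atoms p2 and p3 coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS:
        raise DegenerateGeometryError("collinear triple (p1, p2, p3)")
    if np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear triple (p2, p3, p4)")
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    x = float(np.dot(n1, n2))
    angle = float(np.degrees(np.arctan2(y, x)))
    # map -180 exactly onto +180 so the range is (-180, 180]
    return 180.0 if angle <= -180.0 + 1e-13 else angle


def exit_vectors(
    structure: MolecularStructure, spec: AttachmentSpec
) -> tuple[ExitVector, ExitVector]:
    """The two exit vectors n1 (C1 toward X1) and n2 (C2 toward X2)."""
    c1 = structure.atoms[spec.c1_index].coords
    c2 = structure.atoms[spec.c2_index].coords
    x1 = structure.atoms[spec.x1_index].coords
    x2 = structure.atoms[spec.x2_index].coords
    v1, v2 = x1 - c1, x2 - c2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise DegenerateGeometryError("attachment and substituent atoms coincide")
    return ExitVector(c1, v1 / n1), ExitVector(c2, v2 / n2)


def compute_evp(structure: MolecularStructure, spec: AttachmentSpec) -> EVPParameters:
    """Compute (r, d, phi1, phi2, theta) for one structure.

    ``spec`` names the four defining atoms; hydrogen substituent atoms
    are allowed.  Raises DegenerateGeometryError when any two of the
    four atoms coincide or the torsion frame is collinear.
    """
    n = len(structure.atoms)
    for idx in (spec.c1_index, spec.c2_index, spec.x1_index, spec.x2_index):
        if not (0 <= idx < n):
            raise ValidationError(
                f"atom index {idx + 1} outside structure of {n} atoms"
            )
    c1 = structure.atoms[spec.c1_index].coords
    c2 = structure.atoms[spec.c2_index].coords
    x1 = structure.atoms[spec.x1_index].coords
    x2 = structure.atoms[spec.x2_index].coords

    axis = c2 - c1
    if np.linalg.norm(axis) < _EPS:
        raise DegenerateGeometryError("attachment atoms C1 and C2 coincide")
    ev1, ev2 = exit_vectors(structure, spec)

    r = float(np.linalg.norm(axis))
    d = float(np.linalg.norm(x2 - x1))
    phi1 = plane_angle(ev1.direction, axis)
    phi2 = plane_angle(ev2.direction, -axis)
    theta = torsion_angle(x1, c1, c2, x2)
    return EVPParameters(r=r, d=d, phi1=phi1, phi2=phi2, theta=theta)
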