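"""Dihedral-angle and sugar-pucker pseudorotation math.

This module is the numerical kernel of the package.  Everything downstream
(pseudo-torsion pipelines, worm databases, motif scoring) consumes the two
primitives defined here:

* :func:`dihedral` -- the four-point torsion angle, IUPAC sign convention,
  reported in the [0, 360) degree range used on NARama axes and in worm CSVs.
* :func:`pseudorotation_phase` / :func:`classify_pucker` -- the
  Altona--Sundaralingam pseudorotation phase of the furanose ring and its
  binary North/South classification (C3'-endo vs C2'-endo).

Degenerate geometry (zero-length bonds, collinear triples, flat rings) yields
*undefined* angles rather than exceptions, so one malformed residue can never
abort a whole-database build.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TorsionAngle",
    "UNDEFINED",
    "dihedral",
    "pseudorotation_phase",
    "classify_pucker",
    "C3_ENDO",
    "C2_ENDO",
    "UNKNOWN_PUCKER",
]

# Pucker labels (module-level constants so string typos cannot creep in).
C3_ENDO = "C3'-endo"
C2_ENDO = "C2'-endo"
UNKNOWN_PUCKER = "unknown"

# Below this (in Angstrom or in cross-product norm) geometry is degenerate.
_DEGENERACY_EPS = 1e-9


@dataclass(frozen=True)
class TorsionAngle:
    """A torsion angle in degrees, possibly undefined.

    ``value`` is ``None`` when the angle is undefined (missing atoms, chain
    break, degenerate geometry).  A defined value always lies in [0, 360).
    Undefined angles never compare equal to any number, including another
    undefined angle's ``float('nan')``-like behaviour: equality with a number
    is simply ``False``.
    """

    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.value is not None:
            if not math.isfinite(self.value):
                raise ValueError("TorsionAngle value must be finite or None")
            if not (0.0 <= self.value < 360.0):
                raise ValueError(
                    f"TorsionAngle value {self.value!r} outside [0, 360)"
                )

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __eq__(self, other: object) -> bool:
        if isinstance(other, TorsionAngle):
            if self.value is None or other.value is None:
                return self.value is None and other.value is None
            return self.value == other.value
        if isinstance(other, (int, float)):
            if self.value is None:
                return False
            return self.value == float(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.value)

    def __float__(self) -> float:
        if self.value is None:
            raise ValueError("undefined torsion angle has no float value")
        return self.value

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        if self.value is None:
            return "TorsionAngle(undefined)"
        return f"TorsionAngle({self.value:.3f})"


#: Shared undefined-angle singleton (TorsionAngle is frozen, so sharing is safe).
UNDEFINED = TorsionAngle(None)


def wrap360(angle_deg: float) -> float:
    """Map an angle in degrees onto [0, 360).

    The single place the package's angle-range convention lives.
    """
    wrapped = math.fmod(angle_deg, 360.0)
    if wrapped < 0.0:
        wrapped += 360.0
    # fmod can return 360.0 - epsilon artifacts exactly equal to 360 after +=
    if wrapped >= 360.0:
        wrapped -= 360.0
    return wrapped


def dihedral(
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
    p4: Sequence[float],
) -> TorsionAngle:
    """Torsion angle of four points, in degrees on [0, 360).

    Sign convention (IUPAC): looking down the p2->p3 axis, a clockwise
    rotation carrying the projection of p1 onto the projection of p4 is
    positive; negative torsions have 360 added.  cis is 0, trans is 180.

    Degenerate input (zero-length bond vector, collinear p1-p2-p3 or
    p2-p3-p4) returns an undefined :class:`TorsionAngle`.
    """
    a = np.asarray(p1, dtype=float)
    b = np.asarray(p2, dtype=float)
    c = np.asarray(p3, dtype=float)
    d = np.asarray(p4, dtype=float)

    b0 = a - b
    b1 = c - b
    b2 = d - c

    nb1 = np.linalg.norm(b1)
    if (
        np.linalg.norm(b0) < _DEGENERACY_EPS
        or nb1 < _DEGENERACY_EPS
        or np.linalg.norm(b2) < _DEGENERACY_EPS
    ):
        logger.debug("degenerate dihedral: zero-length bond vector")
        return UNDEFINED

    b1u = b1 / nb1
    # Components of b0 and b2 perpendicular to the central bond.
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < _DEGENERACY_EPS or np.linalg.norm(w) < _DEGENERACY_EPS:
        logger.debug("degenerate dihedral: collinear atom triple")
        return UNDEFINED

    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1u, v), w))
    return TorsionAngle(wrap360(math.degrees(math.atan2(y, x))))


# sin(36 deg) + sin(72 deg), the Altona--Sundaralingam denominator weight.
_AS_WEIGHT = math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))


def pseudorotation_phase(
    nus: Sequence["TorsionAngle | float | None"],
) -> Optional[float]:
    """Altona--Sundaralingam pseudorotation phase P, degrees on [0, 360).

    ``nus`` are the five endocyclic furanose torsions (nu0..nu4):

    ====  =====================
    nu0   C4'-O4'-C1'-C2'
    nu1   O4'-C1'-C2'-C3'
    nu2   C1'-C2'-C3'-C4'
    nu3   C2'-C3'-C4'-O4'
    nu4   C3'-C4'-O4'-C1'
    ====  =====================

    P satisfies tan(P) = (nu4 + nu1 - nu3 - nu0) / (2 nu2 (sin36 + sin72)),
    evaluated with atan2 so nu2 = 0 needs no special case and the quadrant is
    fixed by the sign of nu2.  Returns ``None`` when any torsion is undefined
    or the ring is (unphysically) flat, i.e. the pucker amplitude vanishes.
    """
    if len(nus) != 5:
        raise ValueError("pseudorotation_phase expects exactly five torsions")
    values: list[Optional[float]] = []
    for nu in nus:
        if isinstance(nu, TorsionAngle):
            values.append(nu.value)
        elif nu is None:
            values.append(None)
        else:
            values.append(wrap360(float(nu)))
    if any(v is None for v in values):
        return None

    # Signed values: torsions are stored on [0, 360) but the pseudorotation
    # combination needs the (-180, 180] signed representation.
    signed = [v - 360.0 if v > 180.0 else v for v in values]
    nu0, nu1, nu2, nu3, nu4 = signed

    if max(abs(s) for s in signed) < _DEGENERACY_EPS:
        # Flat ring: zero amplitude, phase meaningless.
        return None

    numerator = nu4 + nu1 - nu3 - nu0
    denominator = 2.0 * nu2 * _AS_WEIGHT
    return wrap360(math.degrees(math.atan2(numerator, denominator)))


def classify_pucker(phase: Optional[float]) -> str:
    """Binary North/South sugar-pucker classification.

    North half-circle P in [270, 360) or [0, 90) -> C3'-endo; South half
    P in [90, 270) -> C2'-endo; undefined phase -> unknown.  Total: every
    input maps to exactly one label.  Twist states on the boundary fall to
    whichever half-open interval contains them.
    """
    if phase is None:
        return UNKNOWN_PUCKER
    p = wrap360(phase)
    if p < 90.0 or p >= 270.0:
        return C3_ENDO
    return C2_ENDO
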