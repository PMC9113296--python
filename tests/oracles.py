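"""Independent reference implementations used only to check the package.

These deliberately use different formulas/code paths than the library:

* ``oracle_dihedral`` computes the torsion from the two plane normals with
  atan2 (the library projects bond vectors instead).
* ``nus_from_phase`` generates the five endocyclic torsions analytically
  from a pseudorotation phase/amplitude (the inverse of what the library
  computes).
* ``brute_force_search`` rescoring is plain Python loops over windows (the
  library vectorizes with stride tricks).
"""

from __future__ import annotations

import math
from typing import List, Optional, Tuple

import numpy as np


def oracle_dihedral(p1, p2, p3, p4) -> float:
    """Torsion in degrees on [0, 360), via normal-vector cross/dot products."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    # IUPAC sign: positive when p4 is rotated clockwise from p1 looking
    # down p2->p3 (cross-checked against biotite/MDAnalysis conventions).
    m1 = np.cross(b2 / np.linalg.norm(b2), n1)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    return ang % 360.0


def nus_from_phase(phase_deg: float, amplitude_deg: float = 38.0) -> List[float]:
    """Endocyclic torsions nu0..nu4 for a given pseudorotation phase:
    nu_j = nu_max * cos(P + 4*pi*(j-2)/5), in degrees on [0, 360)."""
    out = []
    for j in range(5):
        nu = amplitude_deg * math.cos(
            math.radians(phase_deg) + 4.0 * math.pi * (j - 2) / 5.0
        )
        out.append(nu % 360.0)
    return out


def circ_delta(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def brute_force_search(
    probe: List[Tuple[Optional[float], Optional[float]]],
    worms: List[Tuple[str, List[Tuple[Optional[float], Optional[float]]]]],
    aggregator: str = "mean",
    max_incomparable_fraction: float = 0.0,
) -> List[Tuple[float, str, int]]:
    """Rescore every window by straightforward loops.

    ``probe`` and each worm are lists of (eta, theta) with None for
    undefined.  Returns the complete ranked list of (score, source_id,
    window_start) with the library's tie-break order.
    """
    L = len(probe)
    results = []
    for source_id, angles in worms:
        for start in range(0, len(angles) - L + 1):
            deltas = []
            incomparable = 0
            for k in range(L):
                pe, pt = probe[k]
                we, wt = angles[start + k]
                if None in (pe, pt, we, wt):
                    incomparable += 1
                    continue
                deltas.append(
                    math.sqrt(circ_delta(pe, we) ** 2 + circ_delta(pt, wt) ** 2)
                )
            if incomparable / L > max_incomparable_fraction or not deltas:
                continue
            score = sum(deltas) / len(deltas) if aggregator == "mean" else sum(deltas)
            results.append((score, source_id, start + 1))
    results.sort()
    return results


def worm_angle_list(worm) -> List[Tuple[Optional[float], Optional[float]]]:
    """Extract (eta, theta) pairs (None when undefined) from a Worm."""
    return [
        (
            e.eta.value if e.eta.defined else None,
            e.theta.value if e.theta.defined else None,
        )
        for e in worm.entries
    ]
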