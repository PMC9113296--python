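"""Per-nucleotide pseudo-torsion angles and pucker/helicity annotation.

Each nucleotide *i* of a chain is reduced to two pairs of pseudo-torsions:

* eta(i)  = dihedral(C4'(i-1), P(i), C4'(i), P(i+1))
* theta(i) = dihedral(P(i), C4'(i), P(i+1), C4'(i+1))

and the primed variants eta'(i)/theta'(i) with C1' substituted for C4'
(C1' positions are typically better resolved in experimental density).
An angle is undefined whenever a required atom is missing, a neighbouring
residue does not exist (chain terminals), or a chain break interrupts the
atom quadruple.  Records are emitted for *every* nucleotide, terminals
included, so worm positions map 1:1 onto sequence positions.

The sugar pucker (C3'-endo / C2'-endo / unknown) is attached from the five
endocyclic ring torsions when the ring atoms are present, and each residue
gets a helical/non-helical/unknown flag from a rectangular (eta, theta)
window characteristic of regular double helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .geometry import (
    C2_ENDO,
    C3_ENDO,
    UNDEFINED,
    UNKNOWN_PUCKER,
    TorsionAngle,
    classify_pucker,
    dihedral,
    pseudorotation_phase,
)
from .structure_io import NucleicChain, Nucleotide, residues_bonded

__all__ = [
    "HelicalWindow",
    "DEFAULT_HELICAL_WINDOW",
    "PseudoTorsionRecord",
    "compute_pseudotorsions",
    "classify_helical",
    "HELICAL",
    "NON_HELICAL",
    "UNKNOWN_HELICITY",
]

HELICAL = "helical"
NON_HELICAL = "non-helical"
UNKNOWN_HELICITY = "unknown"

MODE_C4 = "c4"
MODE_C1 = "c1"
MODE_BOTH = "both"

# Endocyclic ring torsion atom quadruples, in nu0..nu4 order.
_RING_TORSIONS = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)


def _periodic_inside(value: float, center: float, halfwidth: float) -> bool:
    """Containment in a periodic interval [center - hw, center + hw] mod 360."""
    delta = abs(value - center) % 360.0
    if delta > 180.0:
        delta = 360.0 - delta
    return delta <= halfwidth


@dataclass(frozen=True)
class HelicalWindow:
    """Rectangular window in (eta, theta) space defining 'helical'.

    The factory default is centered on the mean (eta, theta) of the package's
    ideal A-form helix fixture with +/-25 degree half-widths; both the center
    and the half-widths are plain config values, since the helical/non-helical
    boundary is a reporting convention, not a physical constant.  Edges may
    wrap through 0/360 (containment is periodic).
    """

    eta_center: float
    theta_center: float
    eta_halfwidth: float = 25.0
    theta_halfwidth: float = 25.0

    def __post_init__(self) -> None:
        for c in (self.eta_center, self.theta_center):
            if not (0.0 <= c < 360.0):
                raise ValueError("helical window centers must lie in [0, 360)")
        for hw in (self.eta_halfwidth, self.theta_halfwidth):
            if not (0.0 < hw <= 180.0):
                raise ValueError("helical window half-widths must lie in (0, 180]")

    def contains(self, eta: float, theta: float) -> bool:
        return _periodic_inside(
            eta, self.eta_center, self.eta_halfwidth
        ) and _periodic_inside(theta, self.theta_center, self.theta_halfwidth)


# Mean interior (eta, theta) of the package's ideal A-form fixture helix
# (see naworm.fixtures; recomputed by the test suite from the fixture itself).
DEFAULT_HELICAL_WINDOW = HelicalWindow(
    eta_center=89.42, theta_center=286.29, eta_halfwidth=25.0, theta_halfwidth=25.0
)


@dataclass
class PseudoTorsionRecord:
    """Pseudo-torsion state of one nucleotide."""

    chain_id: str
    seq_id: int
    insertion_code: str
    residue_name: str
    eta: TorsionAngle = UNDEFINED
    theta: TorsionAngle = UNDEFINED
    eta_prime: TorsionAngle = UNDEFINED
    theta_prime: TorsionAngle = UNDEFINED
    pucker: str = UNKNOWN_PUCKER
    helical: str = UNKNOWN_HELICITY
    pseudorotation: Optional[float] = None


def classify_helical(
    eta: TorsionAngle,
    theta: TorsionAngle,
    window: HelicalWindow = DEFAULT_HELICAL_WINDOW,
) -> str:
    """helical / non-helical / unknown for one (eta, theta) pair."""
    if not (eta.defined and theta.defined):
        return UNKNOWN_HELICITY
    return HELICAL if window.contains(eta.value, theta.value) else NON_HELICAL


def _quad(
    residues: Sequence[Optional[Nucleotide]],
    quad: Sequence[Tuple[int, str]],
) -> TorsionAngle:
    """Dihedral over (residue offset, atom name) quadruple; undefined if any
    atom is missing."""
    points = []
    for idx, atom in quad:
        res = residues[idx]
        if res is None:
            return UNDEFINED
        pos = res.atom_pos(atom)
        if pos is None:
            return UNDEFINED
        points.append(pos)
    return dihedral(*points)


def _ring_phase(res: Nucleotide) -> Optional[float]:
    nus = []
    for quad in _RING_TORSIONS:
        if not res.has_atoms(*quad):
            return None
        nus.append(dihedral(*(res.atom_pos(a) for a in quad)))
    return pseudorotation_phase(nus)


def compute_pseudotorsions(
    chain: NucleicChain,
    mode: str = MODE_BOTH,
    helical_window: HelicalWindow = DEFAULT_HELICAL_WINDOW,
) -> List[PseudoTorsionRecord]:
    """Compute eta/theta (and/or eta'/theta') for every nucleotide of a chain.

    Parameters
    ----------
    chain:
        Parsed nucleic chain (length >= 1).
    mode:
        ``"c4"`` for eta/theta, ``"c1"`` for eta'/theta', ``"both"`` for all
        four.  Single-mode output agrees exactly with the corresponding half
        of a ``"both"`` run.
    helical_window:
        Rectangle in (eta, theta) space used for the helical flag.  In
        ``"c1"`` mode the flag is derived from (eta', theta') instead.

    Returns one record per nucleotide, in chain order.  Terminal residues
    (and residues adjacent to chain breaks or missing atoms) carry undefined
    angles rather than being dropped.
    """
    if mode not in (MODE_C4, MODE_C1, MODE_BOTH):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(chain.nucleotides)
    if n == 0:
        return []

    # bonded[i] is True when nucleotides i and i+1 are backbone-connected.
    bonded = [
        residues_bonded(chain.nucleotides[i], chain.nucleotides[i + 1])
        for i in range(n - 1)
    ]

    records: List[PseudoTorsionRecord] = []
    for i, res in enumerate(chain.nucleotides):
        prev_res = chain.nucleotides[i - 1] if i > 0 and bonded[i - 1] else None
        next_res = chain.nucleotides[i + 1] if i < n - 1 and bonded[i] else None
        window = (prev_res, res, next_res)

        rec = PseudoTorsionRecord(
            chain_id=res.chain_id,
            seq_id=res.seq_id,
            insertion_code=res.insertion_code,
            residue_name=res.residue_name,
        )

        if mode in (MODE_C4, MODE_BOTH):
            # eta(i): C4'(i-1) - P(i) - C4'(i) - P(i+1)
            rec.eta = _quad(window, ((0, "C4'"), (1, "P"), (1, "C4'"), (2, "P")))
            # theta(i): P(i) - C4'(i) - P(i+1) - C4'(i+1)
            rec.theta = _quad(window, ((1, "P"), (1, "C4'"), (2, "P"), (2, "C4'")))
        if mode in (MODE_C1, MODE_BOTH):
            rec.eta_prime = _quad(window, ((0, "C1'"), (1, "P"), (1, "C1'"), (2, "P")))
            rec.theta_prime = _quad(
                window, ((1, "P"), (1, "C1'"), (2, "P"), (2, "C1'"))
            )

        rec.pseudorotation = _ring_phase(res)
        rec.pucker = classify_pucker(rec.pseudorotation)

        if mode == MODE_C1:
            rec.helical = classify_helical(
                rec.eta_prime, rec.theta_prime, helical_window
            )
        else:
            rec.helical = classify_helical(rec.eta, rec.theta, helical_window)
        records.append(rec)
    return records
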