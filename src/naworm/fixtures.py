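"""Deterministic synthetic structures and worms for testing and demos.

Real crystallographic inputs are deliberately not bundled: everything the
package needs to exercise itself is generated here, bit-reproducibly.

:func:`make_helix` builds an idealized single-chain helix by applying one
fixed rise/twist step to a template nucleotide.  The template is constructed
geometrically, not copied from any force field:

* the furanose ring (O4', C1', C2', C3', C4') is a regular pentagon with an
  out-of-plane displacement pattern calibrated so the Altona--Sundaralingam
  pseudorotation phase hits a target (North ~18 deg for the A-form/RNA
  template, South ~162 deg for the B-form/DNA template);
* the phosphate is placed so that the O3'(i)-P(i+1) distance is exactly
  1.60 Angstrom across every step, well inside the 2.0 Angstrom backbone
  connectivity rule, making the chain unbroken by construction.

Because every residue is a rigid copy of its predecessor, all interior
pseudo-torsions of one helix are *identical* up to coordinate rounding --
the property the test suite leans on.  The helix parameters (rise, twist,
template placement) are frozen constants; their precise values are
unimportant, only self-consistency and the pucker targets matter, so angle
expectations elsewhere are always expressed relative to the fixture's own
recomputed values, never to literature values.

:func:`make_decoy_worms` produces seeded random-angle worms, optionally with
a probe motif planted at a seeded location, for motif-search recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gemmi
import numpy as np

from .geometry import TorsionAngle, dihedral, pseudorotation_phase, wrap360
from .wormdb import Worm, WormEntry

__all__ = [
    "AFORM",
    "BFORM",
    "HelixParams",
    "make_helix",
    "write_helix",
    "make_decoy_worms",
    "DecoySet",
    "perturb_worm",
    "coarse_grain",
    "delete_residue",
    "write_fixture_set",
]

AFORM = "A-form"
BFORM = "B-form"


@dataclass(frozen=True)
class HelixParams:
    """Frozen parameters of one idealized helix family."""

    twist_deg: float  # rotation about the helix (z) axis per residue
    rise: float  # translation along z per residue, Angstrom
    target_phase_deg: float  # pseudorotation phase of the sugar template
    residue_names: Tuple[str, ...]
    with_o2prime: bool


# A-form-like: 11 nt/turn, shallow rise, North sugars, ribose (O2' present).
_AFORM_PARAMS = HelixParams(
    twist_deg=32.7,
    rise=2.81,
    target_phase_deg=18.0,
    residue_names=("A", "U", "G", "C"),
    with_o2prime=True,
)
# B-form-like: 10 nt/turn, taller rise, South sugars, deoxyribose.
_BFORM_PARAMS = HelixParams(
    twist_deg=36.0,
    rise=3.38,
    target_phase_deg=162.0,
    residue_names=("DA", "DT", "DG", "DC"),
    with_o2prime=False,
)

_PARAMS = {AFORM: _AFORM_PARAMS, BFORM: _BFORM_PARAMS}

# Ring construction constants.
_RING_CYCLE = ("O4'", "C1'", "C2'", "C3'", "C4'")  # pentagon vertex order
_RING_RADIUS = 1.205  # gives ~1.42 A ring bonds
_RING_AMPLITUDE = 0.38  # out-of-plane displacement, A (nu_max ~ 38 deg)
_RING_CENTER = np.array([8.2, 0.0, 0.0])  # distance from helix axis
# O3'(i)->P(i+1) bond length and the derived C3'->P(i+1) separation.
_O3P_BOND = 1.60
_C3O3_BOND = 1.42
_C3_PNEXT_DIST = _O3P_BOND + _C3O3_BOND


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _step(points: np.ndarray, params: HelixParams, n: int = 1) -> np.ndarray:
    """Apply the helical symmetry operation n times (n may be negative)."""
    rot = _rot_z(params.twist_deg * n)
    return points @ rot.T + np.array([0.0, 0.0, params.rise * n])


def _ring_coords(phase_offset_deg: float) -> Dict[str, np.ndarray]:
    """Pentagon ring with z-displacements z_j = A*cos(4*pi*j/5 + offset)."""
    coords = {}
    for j, name in enumerate(_RING_CYCLE):
        ang = 2.0 * math.pi * j / 5.0
        z = _RING_AMPLITUDE * math.cos(2.0 * ang + math.radians(phase_offset_deg))
        coords[name] = np.array(
            [_RING_RADIUS * math.cos(ang), _RING_RADIUS * math.sin(ang), z]
        )
    return coords


def _ring_phase(coords: Dict[str, np.ndarray]) -> Optional[float]:
    quads = (
        ("C4'", "O4'", "C1'", "C2'"),
        ("O4'", "C1'", "C2'", "C3'"),
        ("C1'", "C2'", "C3'", "C4'"),
        ("C2'", "C3'", "C4'", "O4'"),
        ("C3'", "C4'", "O4'", "C1'"),
    )
    nus = [dihedral(*(coords[a] for a in quad)) for quad in quads]
    return pseudorotation_phase(nus)


def _calibrated_ring(target_phase_deg: float) -> Dict[str, np.ndarray]:
    """Find the displacement-pattern offset whose ring hits the target
    pseudorotation phase (coarse scan + fine scan; deterministic)."""

    def phase_error(offset: float) -> float:
        p = _ring_phase(_ring_coords(offset))
        assert p is not None
        d = abs(p - target_phase_deg) % 360.0
        return min(d, 360.0 - d)

    best = min(np.arange(0.0, 360.0, 2.0), key=phase_error)
    fine = np.arange(best - 2.0, best + 2.0, 0.01)
    best = min(fine, key=phase_error)
    return _ring_coords(float(best))


def _template_atoms(params: HelixParams) -> Dict[str, np.ndarray]:
    """Build one template nucleotide in the global frame."""
    ring_local = _calibrated_ring(params.target_phase_deg)
    # Tilt the ring plane and push it out to the helix radius.
    tilt = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(math.radians(65.0)), -math.sin(math.radians(65.0))],
            [0.0, math.sin(math.radians(65.0)), math.cos(math.radians(65.0))],
        ]
    )
    atoms = {name: tilt @ pos + _RING_CENTER for name, pos in ring_local.items()}
    centroid = np.mean([atoms[n] for n in _RING_CYCLE], axis=0)
    normal_ = np.cross(
        atoms["C1'"] - atoms["O4'"], atoms["C4'"] - atoms["O4'"]
    )
    normal = normal_ / np.linalg.norm(normal_)

    # Exocyclic atoms at plausible bond lengths; directions chosen away from
    # the ring so nothing overlaps (no energetics implied).
    def away(anchor: np.ndarray, bias: np.ndarray, length: float) -> np.ndarray:
        d = (anchor - centroid) + bias
        return anchor + length * d / np.linalg.norm(d)

    atoms["C5'"] = away(atoms["C4'"], 0.9 * normal + np.array([0, 0, 0.5]), 1.51)
    if params.with_o2prime:
        atoms["O2'"] = away(atoms["C2'"], -0.9 * normal, 1.41)

    # Phosphate placement: P must sit 1.60 A (via O3') upstream of the next
    # residue's P image.  The locus |step(P) - C3'| = d is the sphere of
    # radius d around step^-1(C3'); take the point on it nearest C5'.
    c3 = atoms["C3'"]
    q = _step(c3[np.newaxis, :], params, n=-1)[0]
    to_c5 = atoms["C5'"] - q
    atoms["P"] = q + _C3_PNEXT_DIST * to_c5 / np.linalg.norm(to_c5)

    p_next = _step(atoms["P"][np.newaxis, :], params, n=1)[0]
    atoms["O3'"] = c3 + _C3O3_BOND * (p_next - c3) / np.linalg.norm(p_next - c3)
    return atoms


_ELEMENT = {"P": "P", "O": "O", "C": "C", "N": "N"}


def make_helix(
    kind: str,
    length: int,
    chain_id: str = "A",
    structure_id: str = "helix",
) -> gemmi.Structure:
    """Build an idealized single-chain helix as a gemmi Structure.

    ``kind`` is ``"A-form"`` (RNA, North sugars) or ``"B-form"`` (DNA, South
    sugars).  Coordinates are rounded to 3 decimals so PDB and mmCIF
    serializations carry identical values.
    """
    if kind not in _PARAMS:
        raise ValueError(f"kind must be {AFORM!r} or {BFORM!r}, got {kind!r}")
    if length < 2:
        raise ValueError("helix length must be >= 2")
    params = _PARAMS[kind]
    template = _template_atoms(params)

    st = gemmi.Structure()
    st.name = structure_id
    model = gemmi.Model(1)
    chain = gemmi.Chain(chain_id)
    for i in range(length):
        res = gemmi.Residue()
        res.name = params.residue_names[i % len(params.residue_names)]
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "A"
        for atom_name, pos in template.items():
            moved = _step(pos[np.newaxis, :], params, n=i)[0]
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(_ELEMENT[atom_name[0]])
            atom.occ = 1.0
            atom.b_iso = 10.0
            atom.pos = gemmi.Position(
                round(moved[0], 3), round(moved[1], 3), round(moved[2], 3)
            )
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_helix(
    kind: str,
    length: int,
    path: str | Path,
    chain_id: str = "A",
) -> Path:
    """Write an idealized helix to PDB or mmCIF (chosen by extension)."""
    path = Path(path)
    st = make_helix(kind, length, chain_id=chain_id, structure_id=path.stem)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
    return path


def delete_residue(st: gemmi.Structure, seq_id: int) -> gemmi.Structure:
    """Return a copy of the structure with one residue removed (creates a
    numbering gap and a backbone break; survivors keep their seq_ids)."""
    out = st.clone()
    for model in out:
        for chain in model:
            for i, res in enumerate(chain):
                if res.seqid.num == seq_id:
                    del chain[i]
                    return out
    raise ValueError(f"seq_id {seq_id} not found")


def coarse_grain(st: gemmi.Structure, keep: Tuple[str, ...] = ("P", "C4'")) -> gemmi.Structure:
    """Strip a structure down to the given backbone atoms (coarse-grained
    model emulation)."""
    out = st.clone()
    for model in out:
        for chain in model:
            for res in chain:
                for i in range(len(res) - 1, -1, -1):
                    if res[i].name not in keep:
                        del res[i]
    return out


@dataclass(frozen=True)
class DecoySet:
    """Decoy worms plus, when a motif was planted, where it went."""

    worms: Tuple[Worm, ...]
    planted_source_id: Optional[str] = None
    planted_start: Optional[int] = None  # 1-based position in that worm


def _random_entries(rng: np.random.Generator, length: int) -> List[WormEntry]:
    angles = np.round(rng.uniform(0.0, 360.0, size=(length, 2)), 3)
    # round() can land exactly on 360.0; fold back into the domain
    angles[angles >= 360.0] = 0.0
    return [
        WormEntry(
            position=i + 1,
            seq_id=i + 1,
            residue_name="N",
            eta=TorsionAngle(float(angles[i, 0])),
            theta=TorsionAngle(float(angles[i, 1])),
            pucker="unknown",
        )
        for i in range(length)
    ]


def make_decoy_worms(
    n_worms: int,
    length: int,
    seed: int,
    planted_motif: Optional[Worm] = None,
    mode: str = "c4",
) -> DecoySet:
    """Seeded random-angle decoy worms, optionally with a planted motif.

    Angles are uniform on [0, 360).  When ``planted_motif`` is given, its
    (eta, theta) values overwrite a seeded random window of one seeded-chosen
    worm; the plant location is returned so tests can assert recovery.
    Identical arguments always produce identical worms.
    """
    rng = np.random.default_rng(seed)
    worms: List[Worm] = []
    for w in range(n_worms):
        worms.append(
            Worm(
                source_id=f"decoy{w:03d}",
                entries=_random_entries(rng, length),
                mode=mode,
            )
        )
    planted_id: Optional[str] = None
    planted_start: Optional[int] = None
    if planted_motif is not None and n_worms > 0:
        m = len(planted_motif)
        if m > length:
            raise ValueError("planted motif longer than decoy worms")
        target = int(rng.integers(0, n_worms))
        start = int(rng.integers(0, length - m + 1))  # 0-based
        host = worms[target]
        new_entries = list(host.entries)
        for k, src in enumerate(planted_motif.entries):
            pos = start + k
            old = new_entries[pos]
            new_entries[pos] = WormEntry(
                position=old.position,
                seq_id=old.seq_id,
                residue_name=src.residue_name,
                eta=src.eta,
                theta=src.theta,
                pucker=src.pucker,
            )
        worms[target] = Worm(
            source_id=host.source_id, entries=new_entries, mode=host.mode
        )
        planted_id = host.source_id
        planted_start = start + 1
    return DecoySet(
        worms=tuple(worms),
        planted_source_id=planted_id,
        planted_start=planted_start,
    )


def perturb_worm(
    worm: Worm,
    position: int,
    delta_eta: float = 0.0,
    delta_theta: float = 0.0,
) -> Worm:
    """Shift the angles of one worm position by (delta_eta, delta_theta),
    wrapping into [0, 360).  Undefined angles stay undefined."""
    entries = []
    for e in worm.entries:
        if e.position == position:
            eta = (
                TorsionAngle(wrap360(e.eta.value + delta_eta))
                if e.eta.defined
                else e.eta
            )
            theta = (
                TorsionAngle(wrap360(e.theta.value + delta_theta))
                if e.theta.defined
                else e.theta
            )
            e = WormEntry(
                position=e.position,
                seq_id=e.seq_id,
                residue_name=e.residue_name,
                eta=eta,
                theta=theta,
                pucker=e.pucker,
            )
        entries.append(e)
    return Worm(source_id=worm.source_id, entries=entries, mode=worm.mode)


def write_fixture_set(out_dir: str | Path) -> List[Path]:
    """Write the standard fixture files used throughout the documentation:
    a 12-nt A-form RNA helix (PDB + mmCIF) and a 10-nt B-form DNA duplex
    (two identical-geometry strands as separate chains)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    written.append(write_helix(AFORM, 12, out_dir / "aform12.pdb"))
    written.append(write_helix(AFORM, 12, out_dir / "aform12.cif"))

    # Two-chain DNA "duplex": second strand is a rigidly displaced copy
    # (base pairing is irrelevant to backbone math).
    st = make_helix(BFORM, 10, chain_id="A", structure_id="bduplex10")
    st2 = make_helix(BFORM, 10, chain_id="B", structure_id="bduplex10")
    shift = gemmi.Position(12.0, 0.0, 0.0)
    for model in st2:
        for chain in model:
            for res in chain:
                for atom in res:
                    atom.pos = gemmi.Position(
                        round(atom.pos.x + shift.x, 3),
                        round(atom.pos.y + shift.y, 3),
                        round(atom.pos.z + shift.z, 3),
                    )
            st[0].add_chain(chain.clone())
    st.setup_entities()
    path = out_dir / "bduplex10.pdb"
    st.write_pdb(str(path))
    written.append(path)
    return written
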