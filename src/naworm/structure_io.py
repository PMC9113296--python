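"""Parse PDB/mmCIF structures into nucleic-acid chain models.

Built on :mod:`gemmi` for format handling.  The model kept here is
deliberately minimal: ordered chains of nucleotides, each nucleotide a
mapping from normalized atom label to coordinates.  Only the atoms that
pseudo-torsion and pucker math need are ever consulted downstream (P, O3',
C1'..C5', O4', O2'), so protein chains, waters, ligands, hydrogens and
anisotropic records are dropped at parse time.

Tolerances built in:

* coarse-grained structures (P + C4' only, or P + C1' only) are accepted;
* modified nucleotides (HETATM within a polymer) are kept whenever the
  backbone atoms exist -- base identity is irrelevant to the math;
* both primed (``C4'``) and starred (``C4*``) atom-name dialects are read,
  normalized internally to primed;
* alternate locations are resolved to the highest-occupancy conformer
  (tie -> alphabetically first altloc ID).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomCoord",
    "Nucleotide",
    "NucleicChain",
    "StructureParseError",
    "read_structure",
    "classify_polymer",
    "residues_bonded",
]

RNA = "RNA"
DNA = "DNA"
UNKNOWN = "unknown"

_RNA_NAMES = {"A", "U", "G", "C", "I"}
_DNA_NAMES = {"DA", "DT", "DG", "DC", "DU", "DI"}

# Backbone / sugar atoms the pipeline may consult.
BACKBONE_ATOMS = ("P", "O3'", "O5'", "C5'", "C4'", "C3'", "C2'", "C1'", "O4'", "O2'")


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass(frozen=True)
class AtomCoord:
    """One atom: normalized label, Cartesian position (Angstrom), occupancy."""

    name: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name!r}: occupancy outside [0, 1]")


@dataclass
class Nucleotide:
    """One nucleotide with its (altloc-resolved) named atoms."""

    chain_id: str
    seq_id: int
    insertion_code: str
    residue_name: str
    atoms: Dict[str, AtomCoord] = field(default_factory=dict)
    polymer_kind: str = UNKNOWN
    is_hetatm: bool = False

    def atom_pos(self, name: str) -> Optional[np.ndarray]:
        atom = self.atoms.get(name)
        return None if atom is None else atom.position

    def has_atoms(self, *names: str) -> bool:
        return all(name in self.atoms for name in names)


@dataclass
class NucleicChain:
    """Ordered nucleotides of one polymer chain from one model."""

    structure_id: str
    chain_id: str
    nucleotides: List[Nucleotide]
    model_number: int = 1

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def source_id(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"

    @property
    def polymer_kind(self) -> str:
        return self.nucleotides[0].polymer_kind if self.nucleotides else UNKNOWN


def normalize_atom_name(name: str) -> str:
    """Map starred dialect (``C4*``) to primed (``C4'``)."""
    return name.strip().replace("*", "'")


def classify_polymer(
    residue_names: Sequence[str],
    atoms_present: Sequence[set] | None = None,
) -> str:
    """Label a chain RNA, DNA or unknown.

    Majority vote over residues: a residue counts as DNA when it matches
    deoxy naming (DA/DC/DG/DT/...) or lacks O2' while having C2'; as RNA when
    it carries O2' or matches A/C/G/U naming.  The label affects only
    reporting -- unknown chains are still processed.
    """
    if not residue_names:
        raise ValueError("classify_polymer requires a nonempty residue list")
    rna_votes = 0
    dna_votes = 0
    for i, name in enumerate(residue_names):
        atoms = atoms_present[i] if atoms_present is not None else set()
        name = name.strip().upper()
        if name in _DNA_NAMES or ("C2'" in atoms and "O2'" not in atoms):
            dna_votes += 1
        elif name in _RNA_NAMES or "O2'" in atoms:
            rna_votes += 1
    n = len(residue_names)
    if dna_votes * 2 > n:
        return DNA
    if rna_votes * 2 > n:
        return RNA
    return UNKNOWN


def _looks_nucleic(res: gemmi.Residue, atom_names: set) -> bool:
    """Heuristic nucleotide test: tabulated chemistry first, atoms second."""
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.found():
        if info.is_water() or info.is_amino_acid():
            return False
        if info.is_nucleic_acid():
            return True
    # Untabulated (or ambiguous ligand): require sugar/backbone signature and
    # no protein alpha-carbon.
    if "CA" in atom_names and "C4'" not in atom_names:
        return False
    sugar = atom_names & {"C4'", "C1'", "O4'"}
    return bool(sugar) or "P" in atom_names


def _resolve_altlocs(res: gemmi.Residue) -> Dict[str, AtomCoord]:
    """Pick one conformer per atom label: highest occupancy, then altloc ID."""
    candidates: Dict[str, List[gemmi.Atom]] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        name = normalize_atom_name(atom.name)
        candidates.setdefault(name, []).append(atom)
    out: Dict[str, AtomCoord] = {}
    for name, atoms in candidates.items():
        best = min(atoms, key=lambda a: (-a.occ, a.altloc or ""))
        occ = best.occ if best.occ is not None else 1.0
        out[name] = AtomCoord(
            name=name,
            position=np.array([best.pos.x, best.pos.y, best.pos.z]),
            occupancy=min(max(float(occ), 0.0), 1.0),
            altloc=best.altloc or "",
        )
    return out


def read_structure(
    path: str | Path,
    model_policy: int | str = "first",
) -> List[NucleicChain]:
    """Read a PDB or mmCIF file and return its nucleic-acid chains.

    Parameters
    ----------
    path:
        Structure file.  Dialect chosen by extension with content sniffing
        as fallback (gemmi's ``Detect``).
    model_policy:
        ``"first"`` (default) keeps the first model; an integer selects an
        explicit model number (e.g. an NMR conformer).

    Returns only chains containing at least one nucleotide; protein, ligand
    and water chains are excluded.  Residues lacking all of P/C4'/C1' are
    dropped with a logged warning; surviving residues keep their file seq_ids.
    A file with zero nucleic chains yields an empty list (logged), not an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: file does not exist")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    if len(st) == 0:
        logger.warning("%s: no models found", path)
        return []

    if model_policy == "first":
        model = st[0]
    else:
        wanted = int(model_policy)
        model = None
        for m in st:
            if m.num == wanted:
                model = m
                break
        if model is None:
            raise StructureParseError(f"{path}: model {wanted} not present")

    # Use the file stem, not any header title, so the same structure gets the
    # same id regardless of serialization dialect.
    structure_id = path.stem
    chains: List[NucleicChain] = []
    for chain in model:
        nucleotides: List[Nucleotide] = []
        for res in chain:
            atoms = _resolve_altlocs(res)
            if not _looks_nucleic(res, set(atoms)):
                continue
            if not (set(atoms) & {"P", "C4'", "C1'"}):
                logger.warning(
                    "%s: dropping residue %s %s%d%s (no P/C4'/C1' atom)",
                    path,
                    res.name,
                    chain.name,
                    res.seqid.num,
                    res.seqid.icode.strip(),
                )
                continue
            nucleotides.append(
                Nucleotide(
                    chain_id=chain.name,
                    seq_id=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    residue_name=res.name.strip(),
                    atoms=atoms,
                    is_hetatm=res.het_flag == "H",
                )
            )
        if not nucleotides:
            continue
        kind = classify_polymer(
            [n.residue_name for n in nucleotides],
            [set(n.atoms) for n in nucleotides],
        )
        for n in nucleotides:
            n.polymer_kind = kind
        chains.append(
            NucleicChain(
                structure_id=structure_id,
                chain_id=chain.name,
                nucleotides=nucleotides,
                model_number=model.num,
            )
        )
    if not chains:
        logger.warning("%s: no nucleic-acid chains found", path)
    return chains


def residues_bonded(prev: Nucleotide, curr: Nucleotide) -> bool:
    """Backbone connectivity between consecutive residues.

    Bonded when the O3'(prev)-P(curr) distance is <= 2.0 Angstrom if both
    atoms exist; otherwise fall back to P(prev)-P(curr) <= 10.0 Angstrom
    (coarse-grained structures lack O3').  A break makes any pseudo-torsion
    spanning it undefined.
    """
    o3 = prev.atom_pos("O3'")
    p_next = curr.atom_pos("P")
    if o3 is not None and p_next is not None:
        return float(np.linalg.norm(o3 - p_next)) <= 2.0
    p_prev = prev.atom_pos("P")
    if p_prev is not None and p_next is not None:
        return float(np.linalg.norm(p_prev - p_next)) <= 10.0
    # Without phosphates we cannot gate on distance; assume bonded so that
    # C1'-only coarse models still yield primed angles.
    return True
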