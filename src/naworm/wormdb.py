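"""Worms, worm CSV serialization, and worm-database construction.

A *worm* is a chain distilled to its ordered sequence of (position, eta,
theta) triples -- a linearized, searchable fingerprint of 3-D structure.  A
*worm database* is a directory holding one worm CSV per nucleic-acid chain
of an input structure directory, plus a small index CSV.

File formats (all plain text):

* worm CSV: one comment line ``# source_id=<id> mode=<c4|c1>``, a header
  ``position,seq_id,residue,eta,theta,pucker``, then one row per nucleotide.
  Angles are printed with 3 decimals; undefined angles carry the explicit
  sentinel ``NA`` (never an empty field).
* index CSV at the database root (``index.csv``):
  ``file,source_id,length,mode``.

One database stores one angle mode (eta/theta from C4', or eta'/theta' from
C1'); probe and database modes must match at search time.  Builds are
deterministic: fixed column order, fixed 3-decimal formatting, files
processed in sorted-filename order, so rebuilding over the same inputs is
byte-identical.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

from .geometry import UNDEFINED, UNKNOWN_PUCKER, TorsionAngle
from .pseudotorsion import MODE_C1, MODE_C4, PseudoTorsionRecord, compute_pseudotorsions
from .structure_io import NucleicChain, StructureParseError, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "WormEntry",
    "Worm",
    "WormDatabase",
    "WormFormatError",
    "worm_from_records",
    "worm_from_chain",
    "write_worm_csv",
    "read_worm_csv",
    "build_database",
    "load_database",
    "INDEX_FILENAME",
]

INDEX_FILENAME = "index.csv"
SENTINEL = "NA"

WORM_HEADER = ["position", "seq_id", "residue", "eta", "theta", "pucker"]
INDEX_HEADER = ["file", "source_id", "length", "mode"]

STRUCTURE_SUFFIXES = {".pdb", ".ent", ".cif", ".mmcif"}


class WormFormatError(ValueError):
    """Raised on malformed worm or index CSV content."""


@dataclass(frozen=True)
class WormEntry:
    """One worm vertex: sequence position plus its (eta, theta) pair."""

    position: int  # 1-based, consecutive
    seq_id: int  # author residue number
    residue_name: str
    eta: TorsionAngle = UNDEFINED
    theta: TorsionAngle = UNDEFINED
    pucker: str = UNKNOWN_PUCKER


@dataclass
class Worm:
    """A chain reduced to a position-indexed sequence of (eta, theta) pairs."""

    source_id: str
    entries: List[WormEntry] = field(default_factory=list)
    mode: Optional[str] = None  # "c4" or "c1"; None when unknown

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries, start=1):
            if e.position != i:
                raise ValueError(
                    f"worm {self.source_id!r}: positions must be consecutive "
                    f"from 1 (entry {i} has position {e.position})"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def subworm(self, start: int, end: int, source_id: Optional[str] = None) -> "Worm":
        """Extract positions start..end (1-based, inclusive) as a new worm,
        renumbered from 1."""
        if not (1 <= start <= end <= len(self.entries)):
            raise ValueError(
                f"subworm range {start}-{end} outside worm of length {len(self)}"
            )
        entries = [
            WormEntry(
                position=i,
                seq_id=e.seq_id,
                residue_name=e.residue_name,
                eta=e.eta,
                theta=e.theta,
                pucker=e.pucker,
            )
            for i, e in enumerate(self.entries[start - 1 : end], start=1)
        ]
        return Worm(
            source_id=source_id or f"{self.source_id}:{start}-{end}",
            entries=entries,
            mode=self.mode,
        )


def worm_from_records(
    records: Sequence[PseudoTorsionRecord],
    source_id: str,
    mode: str = MODE_C4,
) -> Worm:
    """Distill pseudo-torsion records into a worm.

    In ``"c1"`` mode the worm's (eta, theta) columns hold the primed angles;
    the mode tag on the worm (and database index) keeps the two families from
    ever being compared against each other.
    """
    if mode not in (MODE_C4, MODE_C1):
        raise ValueError(f"worm mode must be 'c4' or 'c1', got {mode!r}")
    entries = []
    for i, rec in enumerate(records, start=1):
        eta = rec.eta if mode == MODE_C4 else rec.eta_prime
        theta = rec.theta if mode == MODE_C4 else rec.theta_prime
        entries.append(
            WormEntry(
                position=i,
                seq_id=rec.seq_id,
                residue_name=rec.residue_name,
                eta=eta,
                theta=theta,
                pucker=rec.pucker,
            )
        )
    return Worm(source_id=source_id, entries=entries, mode=mode)


def worm_from_chain(chain: NucleicChain, mode: str = MODE_C4) -> Worm:
    records = compute_pseudotorsions(chain, mode=mode)
    return worm_from_records(records, source_id=chain.source_id, mode=mode)


def _format_angle(angle: TorsionAngle) -> str:
    return SENTINEL if not angle.defined else f"{angle.value:.3f}"


def _parse_angle(text: str, path: Path, row_num: int, column: str) -> TorsionAngle:
    text = text.strip()
    if text == SENTINEL:
        return UNDEFINED
    try:
        value = float(text)
    except ValueError as exc:
        raise WormFormatError(
            f"{path}, row {row_num}: {column} value {text!r} is neither a "
            f"number nor the {SENTINEL!r} sentinel"
        ) from exc
    if not (0.0 <= value < 360.0):
        raise WormFormatError(
            f"{path}, row {row_num}: {column} value {value} outside [0, 360)"
        )
    return TorsionAngle(value)


def write_worm_csv(worm: Worm, path: str | Path) -> None:
    """Write one worm to CSV (see module docstring for the schema)."""
    path = Path(path)
    mode = worm.mode or ""
    with path.open("w", newline="") as fh:
        fh.write(f"# source_id={worm.source_id} mode={mode}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(WORM_HEADER)
        for e in worm.entries:
            writer.writerow(
                [
                    e.position,
                    e.seq_id,
                    e.residue_name,
                    _format_angle(e.eta),
                    _format_angle(e.theta),
                    e.pucker,
                ]
            )


def read_worm_csv(path: str | Path) -> Worm:
    """Read a worm CSV written by :func:`write_worm_csv`.

    Angles are validated against the [0, 360) domain; malformed rows raise
    :class:`WormFormatError` naming the row.
    """
    path = Path(path)
    source_id = path.stem
    mode: Optional[str] = None
    entries: List[WormEntry] = []
    with path.open(newline="") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].strip().split():
                key, _, value = token.partition("=")
                if key == "source_id" and value:
                    source_id = value
                elif key == "mode" and value:
                    if value not in (MODE_C4, MODE_C1):
                        raise WormFormatError(
                            f"{path}: unknown mode {value!r} in worm header"
                        )
                    mode = value
            header_line = fh.readline()
        else:
            header_line = first
        header = [h.strip() for h in header_line.strip().split(",")]
        if header != WORM_HEADER:
            raise WormFormatError(
                f"{path}: unexpected header {header!r}; expected {WORM_HEADER!r}"
            )
        reader = csv.reader(fh)
        row_num = 2 if first.startswith("#") else 1
        for row in reader:
            row_num += 1
            if not row:
                continue
            if len(row) != len(WORM_HEADER):
                raise WormFormatError(
                    f"{path}, row {row_num}: expected {len(WORM_HEADER)} "
                    f"columns, got {len(row)}"
                )
            try:
                position = int(row[0])
                seq_id = int(row[1])
            except ValueError as exc:
                raise WormFormatError(
                    f"{path}, row {row_num}: non-integer position/seq_id"
                ) from exc
            entries.append(
                WormEntry(
                    position=position,
                    seq_id=seq_id,
                    residue_name=row[2],
                    eta=_parse_angle(row[3], path, row_num, "eta"),
                    theta=_parse_angle(row[4], path, row_num, "theta"),
                    pucker=row[5],
                )
            )
    try:
        return Worm(source_id=source_id, entries=entries, mode=mode)
    except ValueError as exc:
        raise WormFormatError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class WormIndexEntry:
    filename: str
    source_id: str
    length: int


@dataclass
class WormDatabase:
    """Handle to a directory of worm CSVs plus its index."""

    root: Path
    mode: str
    index: List[WormIndexEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.index)

    def worm_path(self, entry: WormIndexEntry) -> Path:
        return self.root / entry.filename

    def load_worm(self, entry: WormIndexEntry) -> Worm:
        return read_worm_csv(self.worm_path(entry))

    def worms(self):
        for entry in self.index:
            yield self.load_worm(entry)


def _write_index(db: WormDatabase) -> None:
    with (db.root / INDEX_FILENAME).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(INDEX_HEADER)
        for e in db.index:
            writer.writerow([e.filename, e.source_id, e.length, db.mode])


def build_database(
    input_dir: str | Path,
    out_dir: str | Path,
    mode: str = MODE_C4,
    model_policy: int | str = "first",
) -> WormDatabase:
    """Build a worm database from every structure file in a directory.

    One CSV is written per nucleic chain across all parseable PDB/mmCIF
    files (sorted by filename, for deterministic output).  Unparseable files
    are skipped with a logged warning; they never abort the build.  An empty
    input directory yields an empty (but valid) database.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory {input_dir} does not exist")
    out_dir.mkdir(parents=True, exist_ok=True)

    db = WormDatabase(root=out_dir, mode=mode)
    seen_ids = set()
    for path in sorted(input_dir.iterdir()):
        if not path.is_file() or path.suffix.lower() not in STRUCTURE_SUFFIXES:
            continue
        try:
            chains = read_structure(path, model_policy=model_policy)
        except StructureParseError as exc:
            logger.warning("skipping unparseable structure file: %s", exc)
            continue
        for chain in chains:
            worm = worm_from_chain(chain, mode=mode)
            if worm.source_id in seen_ids:
                logger.warning(
                    "duplicate source_id %s; keeping first occurrence",
                    worm.source_id,
                )
                continue
            seen_ids.add(worm.source_id)
            filename = f"{worm.source_id}.csv"
            write_worm_csv(worm, out_dir / filename)
            db.index.append(
                WormIndexEntry(
                    filename=filename,
                    source_id=worm.source_id,
                    length=len(worm),
                )
            )
    if not db.index:
        logger.warning("no parseable nucleic chains found under %s", input_dir)
    _write_index(db)
    return db


def load_database(root: str | Path) -> WormDatabase:
    """Open an existing worm database directory via its index file."""
    root = Path(root)
    index_path = root / INDEX_FILENAME
    if not index_path.exists():
        raise WormFormatError(f"{root}: no {INDEX_FILENAME} found")
    entries: List[WormIndexEntry] = []
    mode: Optional[str] = None
    with index_path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != INDEX_HEADER:
            raise WormFormatError(
                f"{index_path}: unexpected header {header!r}"
            )
        for row_num, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(INDEX_HEADER):
                raise WormFormatError(
                    f"{index_path}, row {row_num}: expected "
                    f"{len(INDEX_HEADER)} columns"
                )
            filename, source_id, length, row_mode = row
            if mode is None:
                mode = row_mode
            elif row_mode != mode:
                raise WormFormatError(
                    f"{index_path}, row {row_num}: mixed modes in one database"
                )
            if not (root / filename).exists():
                raise WormFormatError(
                    f"{index_path}, row {row_num}: indexed file "
                    f"{filename!r} missing"
                )
            entries.append(
                WormIndexEntry(
                    filename=filename, source_id=source_id, length=int(length)
                )
            )
    if mode is None:
        mode = MODE_C4  # empty database: mode is moot but must be concrete
    db = WormDatabase(root=root, mode=mode, index=entries)
    ids = [e.source_id for e in entries]
    if len(ids) != len(set(ids)):
        raise WormFormatError(f"{index_path}: duplicate source_ids")
    return db
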