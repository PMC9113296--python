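"""NARama plots, 3-D worm plots and the per-nucleotide spreadsheet.

Every image gets a machine-readable sidecar table (CSV) listing exactly what
was drawn; tests and downstream tooling consume the tables, never image
bytes, because rendered output is backend-dependent while the plotted data
is the actual contract.

Conventions:

* NARama scatter: square axes spanning [0, 360] degrees, theta-family angle
  on x, eta-family angle on y; one point per record whose two plotted angles
  are both defined; marker encodes sugar pucker (circle for C3'-endo,
  triangle for C2'-endo, cross for unknown); color follows residue index
  through a stable palette.
* Worm plot: 3-D polyline through (position, eta, theta); a segment is blue
  when both endpoints are helical, red otherwise; vertices with undefined
  angles break the line.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib import colormaps

from .geometry import TorsionAngle
from .pseudotorsion import (
    C2_ENDO,
    C3_ENDO,
    HELICAL,
    PseudoTorsionRecord,
)
from .wormdb import SENTINEL, Worm

logger = logging.getLogger(__name__)

__all__ = [
    "narama_plot",
    "worm_plot",
    "write_spreadsheet",
    "VARIANT_ETA_THETA",
    "VARIANT_PRIMED",
]

VARIANT_ETA_THETA = "eta-theta"
VARIANT_PRIMED = "etaprime-thetaprime"

_MARKER_FOR_PUCKER = {C3_ENDO: "circle", C2_ENDO: "triangle"}
_MPL_MARKER = {"circle": "o", "triangle": "^", "cross": "x"}

POINT_TABLE_HEADER = [
    "label",
    "chain",
    "seq_id",
    "residue",
    "x_theta",
    "y_eta",
    "marker",
    "pucker",
    "color_key",
]

SEGMENT_TABLE_HEADER = [
    "position",
    "seq_id",
    "residue",
    "eta",
    "theta",
    "helical",
    "segment_to_next",
]


def _fmt(angle: TorsionAngle) -> str:
    return SENTINEL if not angle.defined else f"{angle.value:.3f}"


def _variant_angles(
    rec: PseudoTorsionRecord, variant: str
) -> Tuple[TorsionAngle, TorsionAngle]:
    if variant == VARIANT_ETA_THETA:
        return rec.eta, rec.theta
    if variant == VARIANT_PRIMED:
        return rec.eta_prime, rec.theta_prime
    raise ValueError(f"unknown plot variant {variant!r}")


def narama_plot(
    records: Sequence[PseudoTorsionRecord],
    variant: str,
    out_path: str | Path,
    dpi: int = 150,
    title: str = "",
) -> Optional[Path]:
    """Draw a NARama (Ramachandran-like) scatter and its point table.

    Returns the image path, or ``None`` (with a warning) when no record has
    both plotted angles defined.  The point table is written beside the
    image as ``<image stem>_points.csv``.
    """
    out_path = Path(out_path)
    rows = []
    for idx, rec in enumerate(records):
        eta, theta = _variant_angles(rec, variant)
        if not (eta.defined and theta.defined):
            continue
        marker = _MARKER_FOR_PUCKER.get(rec.pucker, "cross")
        rows.append(
            {
                "label": f"{rec.chain_id}/{rec.seq_id}{rec.insertion_code}",
                "chain": rec.chain_id,
                "seq_id": rec.seq_id,
                "residue": rec.residue_name,
                "x_theta": theta.value,
                "y_eta": eta.value,
                "marker": marker,
                "pucker": rec.pucker,
                "color_key": idx,
            }
        )
    if not rows:
        logger.warning("narama_plot(%s): no plottable records", variant)
        return None

    table_path = out_path.with_name(out_path.stem + "_points.csv")
    with table_path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(POINT_TABLE_HEADER)
        for r in rows:
            writer.writerow(
                [
                    r["label"],
                    r["chain"],
                    r["seq_id"],
                    r["residue"],
                    f"{r['x_theta']:.3f}",
                    f"{r['y_eta']:.3f}",
                    r["marker"],
                    r["pucker"],
                    r["color_key"],
                ]
            )

    cmap = colormaps["viridis"]
    n_keys = max(r["color_key"] for r in rows) + 1
    fig, ax = plt.subplots(figsize=(6, 6))
    for marker_name in sorted({r["marker"] for r in rows}):
        sub = [r for r in rows if r["marker"] == marker_name]
        ax.scatter(
            [r["x_theta"] for r in sub],
            [r["y_eta"] for r in sub],
            c=[cmap(r["color_key"] / max(n_keys - 1, 1)) for r in sub],
            marker=_MPL_MARKER[marker_name],
            edgecolors="none" if marker_name == "cross" else "black",
            linewidths=0.4,
            s=45,
            label=marker_name,
        )
    if variant == VARIANT_ETA_THETA:
        ax.set_xlabel("theta (deg)")
        ax.set_ylabel("eta (deg)")
    else:
        ax.set_xlabel("theta' (deg)")
        ax.set_ylabel("eta' (deg)")
    ax.set_xlim(0, 360)
    ax.set_ylim(0, 360)
    ax.set_xticks(range(0, 361, 60))
    ax.set_yticks(range(0, 361, 60))
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8, title="sugar pucker")
    if title:
        ax.set_title(title)
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return out_path


def worm_plot(
    worm: Worm,
    helical_flags: Sequence[str],
    out_path: str | Path,
    dpi: int = 150,
    title: str = "",
) -> Optional[Path]:
    """Draw the 3-D worm (position, eta, theta) polyline and segment table.

    ``helical_flags`` holds one helical/non-helical/unknown label per worm
    position.  Segments whose two endpoints are both helical are blue; all
    other drawable segments are red.  The vertex/segment table is written as
    ``<image stem>_segments.csv``; vertices with undefined angles appear in
    the table with the NA sentinel but are not drawn.
    """
    out_path = Path(out_path)
    if len(worm) < 2:
        raise ValueError("worm plot needs a worm of length >= 2")
    if len(helical_flags) != len(worm):
        raise ValueError("one helical flag per worm position required")

    drawable = [e.eta.defined and e.theta.defined for e in worm.entries]
    if not any(drawable):
        logger.warning("worm_plot: all angles undefined; nothing to draw")
        return None

    seg_color: List[str] = []
    for i in range(len(worm)):
        if i == len(worm) - 1 or not (drawable[i] and drawable[i + 1]):
            seg_color.append(SENTINEL)
        elif helical_flags[i] == HELICAL and helical_flags[i + 1] == HELICAL:
            seg_color.append("blue")
        else:
            seg_color.append("red")

    table_path = out_path.with_name(out_path.stem + "_segments.csv")
    with table_path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SEGMENT_TABLE_HEADER)
        for i, e in enumerate(worm.entries):
            writer.writerow(
                [
                    e.position,
                    e.seq_id,
                    e.residue_name,
                    _fmt(e.eta),
                    _fmt(e.theta),
                    helical_flags[i],
                    seg_color[i],
                ]
            )

    fig = plt.figure(figsize=(8, 6))
    ax = fig.add_subplot(projection="3d")
    for i, e in enumerate(worm.entries[:-1]):
        if seg_color[i] == SENTINEL:
            continue
        nxt = worm.entries[i + 1]
        ax.plot(
            [e.position, nxt.position],
            [e.eta.value, nxt.eta.value],
            [e.theta.value, nxt.theta.value],
            color=seg_color[i],
            linewidth=2.0,
        )
    xs = [e.position for i, e in enumerate(worm.entries) if drawable[i]]
    ys = [e.eta.value for i, e in enumerate(worm.entries) if drawable[i]]
    zs = [e.theta.value for i, e in enumerate(worm.entries) if drawable[i]]
    ax.scatter(xs, ys, zs, color="black", s=10)
    ax.set_xlabel("sequence position")
    ax.set_ylabel("eta (deg)")
    ax.set_zlabel("theta (deg)")
    ax.set_ylim(0, 360)
    ax.set_zlim(0, 360)
    if title:
        ax.set_title(title)
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return out_path


SPREADSHEET_HEADER = [
    "chain",
    "seq_id",
    "insertion_code",
    "residue",
    "eta",
    "theta",
    "eta_prime",
    "theta_prime",
    "pucker",
    "helical",
]


def write_spreadsheet(
    records: Sequence[PseudoTorsionRecord], out_path: str | Path
) -> Path:
    """Write the per-nucleotide angle spreadsheet (CSV, one row per residue;
    undefined angles as NA).  An empty record list yields a header-only file."""
    out_path = Path(out_path)
    with out_path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SPREADSHEET_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.chain_id,
                    rec.seq_id,
                    rec.insertion_code,
                    rec.residue_name,
                    _fmt(rec.eta),
                    _fmt(rec.theta),
                    _fmt(rec.eta_prime),
                    _fmt(rec.theta_prime),
                    rec.pucker,
                    rec.helical,
                ]
            )
    return out_path
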