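"""Sliding-window motif search in (eta, theta) angle space.

A probe worm of length L is slid across every length-L window of every worm
in a database.  Each aligned position contributes a periodic Euclidean
distance in (eta, theta) space,

    delta_i = sqrt( d(eta_p, eta_w)^2 + d(theta_p, theta_w)^2 ),

where d(a, b) = min(|a - b|, 360 - |a - b|) is the circular angle
difference, and the window score aggregates the per-position deltas
(mean by default; sum available).  Windows are ranked ascending by score:
a score of 0 is an exact angular match.

Positions where either side has an undefined angle are *incomparable*; a
window whose incomparable fraction exceeds a threshold (default 0, i.e.
full strictness) is skipped rather than silently zero-filled, since chain
terminals always carry one undefined angle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .wormdb import Worm, WormDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "MotifHit",
    "ModeMismatchError",
    "angle_delta",
    "position_delta",
    "search",
    "write_results",
    "AGGREGATORS",
]

AGGREGATORS = ("mean", "sum")


class ModeMismatchError(ValueError):
    """Probe and database were built with different angle modes (eta/theta
    from C4' vs eta'/theta' from C1'); comparing them is meaningless."""


@dataclass(frozen=True)
class MotifHit:
    """One scored alignment of the probe against a database window."""

    source_id: str
    window_start: int  # 1-based position in the database worm
    window_length: int
    score: float  # aggregated per-position delta, degrees
    per_position_deltas: Tuple[float, ...]  # NaN at incomparable positions
    seq_start: int  # author seq_id of the first window residue
    seq_end: int  # author seq_id of the last window residue


def angle_delta(a: float, b: float) -> float:
    """Circular difference of two angles in degrees, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def position_delta(
    probe_entry: Tuple[Optional[float], Optional[float]],
    window_entry: Tuple[Optional[float], Optional[float]],
) -> float:
    """Periodic Euclidean distance between two (eta, theta) pairs, degrees.

    Returns NaN (the 'incomparable' marker) when any of the four angles is
    undefined (None).
    """
    pe, pt = probe_entry
    we, wt = window_entry
    if pe is None or pt is None or we is None or wt is None:
        return math.nan
    return math.hypot(angle_delta(pe, we), angle_delta(pt, wt))


def _angle_arrays(worm: Worm) -> Tuple[np.ndarray, np.ndarray]:
    """(eta, theta) arrays with NaN for undefined angles."""
    eta = np.array(
        [e.eta.value if e.eta.defined else np.nan for e in worm.entries]
    )
    theta = np.array(
        [e.theta.value if e.theta.defined else np.nan for e in worm.entries]
    )
    return eta, theta


def _circ_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % 360.0
    return np.minimum(d, 360.0 - d)


def _score_worm(
    probe_eta: np.ndarray,
    probe_theta: np.ndarray,
    worm: Worm,
    aggregator: str,
    max_incomparable_fraction: float,
) -> Iterable[Tuple[int, float, np.ndarray, int, int]]:
    """Yield (window_start, score, deltas, seq_start, seq_end) per window."""
    L = len(probe_eta)
    w_eta, w_theta = _angle_arrays(worm)
    n = len(worm)
    if n < L:
        return
    # All windows at once: rows are windows, columns are positions.
    win_eta = np.lib.stride_tricks.sliding_window_view(w_eta, L)
    win_theta = np.lib.stride_tricks.sliding_window_view(w_theta, L)
    de = _circ_diff(win_eta, probe_eta[np.newaxis, :])
    dt = _circ_diff(win_theta, probe_theta[np.newaxis, :])
    deltas = np.sqrt(de * de + dt * dt)  # NaN propagates from undefined angles
    incomparable = np.isnan(deltas)
    frac = incomparable.mean(axis=1)
    comparable_counts = L - incomparable.sum(axis=1)
    for w in range(n - L + 1):
        if frac[w] > max_incomparable_fraction or comparable_counts[w] == 0:
            continue
        row = deltas[w]
        total = float(np.nansum(row))
        score = total / comparable_counts[w] if aggregator == "mean" else total
        yield (
            w + 1,
            float(score),
            row,
            worm.entries[w].seq_id,
            worm.entries[w + L - 1].seq_id,
        )


def search(
    probe: Worm,
    db: WormDatabase | Sequence[Worm],
    aggregator: str = "mean",
    top_n: int = 20,
    max_incomparable_fraction: float = 0.0,
) -> List[MotifHit]:
    """Score a probe worm against every equal-length database window.

    Parameters
    ----------
    probe:
        Query worm, length >= 2.  Its mode must match the database's (a
        probe with no recorded mode is accepted with a warning).
    db:
        A :class:`~naworm.wormdb.WormDatabase`, or a plain sequence of worms
        (used directly, e.g. for in-memory decoy sets).
    aggregator:
        ``"mean"`` (default) or ``"sum"`` over comparable positions.
    top_n:
        Number of hits returned after ranking.
    max_incomparable_fraction:
        Windows whose fraction of incomparable positions exceeds this are
        skipped entirely (default 0: every position must be comparable).

    Hits are sorted ascending by score, ties broken by (source_id,
    window_start) lexicographically.
    """
    if len(probe) < 2:
        raise ValueError("probe worm must have length >= 2")
    if aggregator not in AGGREGATORS:
        raise ValueError(f"aggregator must be one of {AGGREGATORS}")
    if isinstance(db, WormDatabase):
        if probe.mode is None:
            logger.warning(
                "probe worm has no recorded mode; assuming database mode %r",
                db.mode,
            )
        elif probe.mode != db.mode:
            raise ModeMismatchError(
                f"probe mode {probe.mode!r} != database mode {db.mode!r}"
            )
        worms: Iterable[Worm] = db.worms()
    else:
        worms = db
        for w in worms:
            if probe.mode and w.mode and probe.mode != w.mode:
                raise ModeMismatchError(
                    f"probe mode {probe.mode!r} != worm {w.source_id!r} "
                    f"mode {w.mode!r}"
                )

    probe_eta, probe_theta = _angle_arrays(probe)
    L = len(probe)
    hits: List[MotifHit] = []
    any_window = False
    for worm in worms:
        if len(worm) >= L:
            any_window = True
        for start, score, deltas, seq_start, seq_end in _score_worm(
            probe_eta, probe_theta, worm, aggregator, max_incomparable_fraction
        ):
            hits.append(
                MotifHit(
                    source_id=worm.source_id,
                    window_start=start,
                    window_length=L,
                    score=score,
                    per_position_deltas=tuple(float(d) for d in deltas),
                    seq_start=seq_start,
                    seq_end=seq_end,
                )
            )
    if not any_window:
        logger.warning(
            "probe (length %d) is longer than every database worm; no hits", L
        )
    hits.sort(key=lambda h: (h.score, h.source_id, h.window_start))
    return hits[:top_n]


def write_results(
    hits: Sequence[MotifHit],
    path: str | Path,
    probe_id: str = "",
    mode: str = "",
    aggregator: str = "mean",
    database_root: str = "",
    probe_length: int = 0,
) -> None:
    """Write the ranked hit list as a single plain-text report."""
    path = Path(path)
    lines = [
        "# naworm motif search results",
        f"probe_id: {probe_id}",
        f"mode: {mode}",
        f"aggregator: {aggregator}",
        f"database: {database_root}",
        f"probe_length: {probe_length}",
        f"{len(hits)} hits",
    ]
    if hits:
        lines.append("rank\tsource_id\twindow(seq_ids)\tscore")
        for rank, hit in enumerate(hits, start=1):
            lines.append(
                f"{rank}\t{hit.source_id}\t{hit.seq_start}-{hit.seq_end}"
                f"\t{hit.score:.3f}"
            )
    path.write_text("\n".join(lines) + "\n")
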