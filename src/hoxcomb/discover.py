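"""Discovery of conserved flank motifs from same-class segment sets.

Given analysis segments of one putative ortholog class, scan a fixed
coordinate window (default the carboxy flank, positions 61-72) column by
column: a column is *conserved* when a small residue set (at most
``max_degeneracy`` residues) covers at least ``min_fraction`` of the
sequences.  Maximal runs of at least ``min_run`` consecutive conserved
columns are emitted as candidate signatures, named by their consensus
string with degenerate columns rendered ``(I/L)``-style.  This is exactly
the shape of the known flank signatures — five columns, at most one
two-way degenerate position — so the defaults (min_fraction 1.0,
max_degeneracy 2, min_run 4) recover motifs of the KLTGP / KS(I/L)ND kind
from clean ortholog sets, while uniformly random flanks produce nothing.

Discovery is positional, anchored to homeodomain coordinates: segments are
*not* realigned, because the claims such signatures support are claims
about fixed homeodomain-anchored positions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .errors import DataError
from .locator import SEGMENT_LENGTH, AnalysisSegment
from .signatures import LINEAGE_MOTIF, SignatureDef

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscoveryParams:
    """Knobs of the column-conservation scan (see module docstring)."""

    region: tuple[int, int] = (61, 72)
    min_fraction: float = 1.0
    max_degeneracy: int = 2
    min_run: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.region
        if not 1 <= lo <= hi <= SEGMENT_LENGTH:
            raise DataError(f"region must lie within 1..{SEGMENT_LENGTH}")
        if not 0.0 < self.min_fraction <= 1.0:
            raise DataError("min_fraction must be in (0, 1]")
        if self.max_degeneracy < 1:
            raise DataError("max_degeneracy must be >= 1")
        if self.min_run < 1:
            raise DataError("min_run must be >= 1")


def _smallest_covering_set(column: Sequence[str], min_fraction: float) -> frozenset[str]:
    """Smallest residue set covering >= min_fraction of the column.

    Residues are added in order of decreasing count (ties broken
    lexicographically, making the result deterministic).  ``X`` is never
    part of a covering set; sequences showing ``X`` simply cannot be
    covered.
    """
    n = len(column)
    counts = Counter(r for r in column if r != "X")
    chosen: set[str] = set()
    covered = 0
    for residue, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        chosen.add(residue)
        covered += count
        if covered / n >= min_fraction:
            return frozenset(chosen)
    return frozenset(column) | {"X"} if covered / n < min_fraction else frozenset(chosen)


def render_consensus(constraints: Sequence[tuple[int, frozenset[str]]]) -> str:
    """Human-readable consensus name: single residues verbatim, degenerate
    columns as ``(I/L)`` with residues in alphabetical order."""
    parts = []
    for _, allowed in constraints:
        ordered = sorted(allowed)
        parts.append(ordered[0] if len(ordered) == 1 else "(" + "/".join(ordered) + ")")
    return "".join(parts)


def discover(
    segments: Sequence[AnalysisSegment],
    params: DiscoveryParams | None = None,
) -> list[SignatureDef]:
    """Find conserved-column runs in a set of same-class segments.

    Segments whose flank does not cover the whole region are excluded with
    a warning; if none remain, that is an error.  Candidates are returned
    in order of start position.
    """
    if params is None:
        params = DiscoveryParams()
    if len(segments) < 2:
        raise DataError("discovery needs at least 2 segments")
    lo, hi = params.region
    usable = [s for s in segments if s.length >= hi]
    dropped = len(segments) - len(usable)
    if dropped:
        logger.warning(
            "discover: excluded %d segment(s) whose flank does not cover position %d",
            dropped,
            hi,
        )
    if len(usable) < 2:
        raise DataError(
            f"region {lo}..{hi} not covered by enough segments ({len(usable)} usable)"
        )

    conserved: list[frozenset[str] | None] = []
    for pos in range(lo, hi + 1):
        column = [s.residue_at(pos) for s in usable]
        cover = _smallest_covering_set(column, params.min_fraction)  # type: ignore[arg-type]
        conserved.append(cover if len(cover) <= params.max_degeneracy and "X" not in cover else None)

    candidates: list[SignatureDef] = []
    i = 0
    while i < len(conserved):
        if conserved[i] is None:
            i += 1
            continue
        j = i
        while j + 1 < len(conserved) and conserved[j + 1] is not None:
            j += 1
        if j - i + 1 >= params.min_run:
            constraints = tuple(
                (lo + k, conserved[k]) for k in range(i, j + 1)  # type: ignore[misc]
            )
            candidates.append(
                SignatureDef(
                    name=render_consensus(constraints),
                    constraints=constraints,
                    kind=LINEAGE_MOTIF,
                )
            )
        i = j + 1
    return candidates


# -- signature comparison ----------------------------------------------------


@dataclass(frozen=True)
class OverlapReport:
    """Side-by-side comparison of two signatures.

    ``shared_positions`` — positions constrained by both;
    ``conflicting_positions`` — shared positions whose allowed sets are
    disjoint; ``co_occurrence_possible`` — whether one flank could satisfy
    both signatures at once (true iff no shared position conflicts).
    """

    a: str
    b: str
    shared_positions: tuple[int, ...]
    conflicting_positions: tuple[int, ...]
    co_occurrence_possible: bool


def compare_signatures(a: SignatureDef, b: SignatureDef) -> OverlapReport:
    """Report shared positions, per-position conflicts, and co-occurrence."""
    shared = tuple(sorted(set(a.positions) & set(b.positions)))
    conflicts = tuple(
        p for p in shared if not (a.allowed_at(p) & b.allowed_at(p))  # type: ignore[operator]
    )
    return OverlapReport(
        a=a.name,
        b=b.name,
        shared_positions=shared,
        conflicting_positions=conflicts,
        co_occurrence_possible=not conflicts,
    )
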