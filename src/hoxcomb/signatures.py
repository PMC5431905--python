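"""Diagnostic residue sets and lineage motifs, and scoring segments against them.

A *signature* is a named set of (position, allowed residue set) constraints
in 1-based analysis-segment coordinates (homeodomain positions 1-60,
carboxy-flank positions 61-72).  Two kinds are distinguished:

``diagnostic_class``
    Residues treated as apomorphies of a Hox class, scored as the fraction
    of constraints matched (e.g. the central-class set Q6, LTR(R/K)RR at
    26-31 and E59, or the posterior-class set K3, A14, R18, Y20, V21).

``lineage_motif``
    Short contiguous flank motifs scored by full presence/absence, such as
    the Lox5-parapeptide KLTGP at 64-68 of lophotrochozoan PG6/7 genes and
    the gnathiferan PG6 motif KS(I/L)ND at 63-67 of rotifer and chaetognath
    Hox6 genes.

Matching is strict presence/absence: a residue matches a constraint iff it
is in the allowed set; ``X`` never matches; constraints that fall beyond a
truncated flank count as unmatched (conservative, and it keeps class-score
denominators comparable across records).

Signatures live in a human-editable TSV table, not in code, so the shipped
set can be extended (e.g. with anterior/PG3 diagnostics) without touching
the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DataError
from .io_formats import AMINO_ACIDS
from .locator import SEGMENT_LENGTH, AnalysisSegment

DIAGNOSTIC_CLASS = "diagnostic_class"
LINEAGE_MOTIF = "lineage_motif"
_KINDS = (DIAGNOSTIC_CLASS, LINEAGE_MOTIF)

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class SignatureDef:
    """A named set of positional residue constraints.

    ``constraints`` is an ordered tuple of (1-based segment position,
    frozenset of allowed residues) with strictly increasing positions.
    """

    name: str
    constraints: tuple[tuple[int, frozenset[str]], ...]
    kind: str = LINEAGE_MOTIF
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name or "\t" in self.name:
            raise DataError(f"invalid signature name {self.name!r}")
        if self.kind not in _KINDS:
            raise DataError(f"signature {self.name!r}: unknown kind {self.kind!r}")
        if not self.constraints:
            raise DataError(f"signature {self.name!r} has no constraints")
        last = 0
        for pos, allowed in self.constraints:
            if not last < pos <= SEGMENT_LENGTH:
                raise DataError(
                    f"signature {self.name!r}: positions must be strictly "
                    f"increasing and <= {SEGMENT_LENGTH} (got {pos})"
                )
            if not allowed or not allowed <= _AA_SET:
                raise DataError(
                    f"signature {self.name!r}: allowed set at position {pos} "
                    f"must be a non-empty subset of the 20 amino acids"
                )
            last = pos

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.constraints)

    def allowed_at(self, position: int) -> frozenset[str] | None:
        for p, allowed in self.constraints:
            if p == position:
                return allowed
        return None


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one signature against one segment."""

    signature: str
    n_constraints: int
    n_matched: int
    matched_positions: tuple[int, ...]
    full_match: bool = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_matched <= self.n_constraints:
            raise ValueError("n_matched out of range")
        object.__setattr__(self, "full_match", self.n_matched == self.n_constraints)


def match_signature(segment: AnalysisSegment, sig: SignatureDef) -> MatchResult:
    """Count which of a signature's constraints the segment satisfies.

    Constraints at positions beyond the segment's (possibly truncated)
    flank count as unmatched; ``X`` matches nothing.
    """
    matched = []
    for pos, allowed in sig.constraints:
        residue = segment.residue_at(pos)
        if residue is not None and residue in allowed:
            matched.append(pos)
    return MatchResult(
        signature=sig.name,
        n_constraints=len(sig.constraints),
        n_matched=len(matched),
        matched_positions=tuple(matched),
    )


def score_class(segment: AnalysisSegment, sig: SignatureDef) -> float:
    """Fraction of a diagnostic-class signature's constraints matched, in [0, 1]."""
    if sig.kind != DIAGNOSTIC_CLASS:
        raise DataError(
            f"score_class requires a diagnostic_class signature, got {sig.kind!r}"
        )
    m = match_signature(segment, sig)
    return m.n_matched / m.n_constraints


# -- signature table I/O -----------------------------------------------------


def parse_signature_table(text: str, origin: str = "<string>") -> list[SignatureDef]:
    """Parse the TSV signature-table dialect.

    One constraint per line ``name<TAB>position<TAB>allowed_residues[<TAB>kind]``;
    ``#`` comments; a ``#note<TAB>name<TAB>text`` directive attaches a note.
    Constraints of a signature may appear in any order; they are sorted by
    position.
    """
    rows: dict[str, list[tuple[int, frozenset[str]]]] = {}
    kinds: dict[str, str] = {}
    notes: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#note\t"):
            parts = line.split("\t", 2)
            if len(parts) == 3:
                notes[parts[1]] = parts[2]
            continue
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (3, 4):
            raise DataError(f"{origin}:{lineno}: expected 3 or 4 tab-separated fields")
        name, pos_s, allowed_s = parts[0], parts[1], parts[2]
        kind = parts[3] if len(parts) == 4 else LINEAGE_MOTIF
        try:
            pos = int(pos_s)
        except ValueError:
            raise DataError(f"{origin}:{lineno}: position {pos_s!r} is not an integer")
        if not 1 <= pos <= SEGMENT_LENGTH:
            raise DataError(f"{origin}:{lineno}: position {pos} outside 1..{SEGMENT_LENGTH}")
        allowed = frozenset(allowed_s.upper())
        if not allowed or not allowed <= _AA_SET:
            raise DataError(f"{origin}:{lineno}: bad allowed-residue set {allowed_s!r}")
        if name in kinds and kinds[name] != kind:
            raise DataError(f"{origin}:{lineno}: signature {name!r} has conflicting kinds")
        kinds[name] = kind
        rows.setdefault(name, []).append((pos, allowed))
    sigs = []
    for name, constraints in rows.items():
        constraints.sort()
        positions = [p for p, _ in constraints]
        if len(set(positions)) != len(positions):
            raise DataError(f"{origin}: signature {name!r} has duplicate positions")
        sigs.append(
            SignatureDef(
                name=name,
                constraints=tuple(constraints),
                kind=kinds[name],
                note=notes.get(name, ""),
            )
        )
    return sigs


def read_signature_table(path: str | Path) -> list[SignatureDef]:
    return parse_signature_table(Path(path).read_text(), origin=str(path))


def format_signature_table(sigs: Iterable[SignatureDef]) -> str:
    """Serialise signatures back to the TSV dialect (inverse of parsing)."""
    lines = []
    for sig in sigs:
        if sig.note:
            lines.append(f"#note\t{sig.name}\t{sig.note}")
        for pos, allowed in sig.constraints:
            lines.append(f"{sig.name}\t{pos}\t{''.join(sorted(allowed))}\t{sig.kind}")
    return "\n".join(lines) + "\n"


def write_signature_table(sigs: Iterable[SignatureDef], path: str | Path) -> None:
    Path(path).write_text(format_signature_table(sigs))


def builtin_signatures(extra: Sequence[SignatureDef] = ()) -> list[SignatureDef]:
    """The shipped signature set, optionally extended with user signatures.

    Returns the central-class and posterior-class diagnostic sets, the
    Lox5-parapeptide, and the gnathiferan PG6 motif, in table order,
    followed by any ``extra`` definitions (which may not shadow shipped
    names).
    """
    text = resources.files("hoxcomb.data").joinpath("signatures.tsv").read_text()
    sigs = parse_signature_table(text, origin="builtin signatures.tsv")
    names = {s.name for s in sigs}
    for sig in extra:
        if sig.name in names:
            raise DataError(f"user signature {sig.name!r} shadows a built-in name")
        sigs.append(sig)
    return sigs


def get_signature(name: str, sigs: Sequence[SignatureDef] | None = None) -> SignatureDef:
    """Look up a signature by name (from ``sigs`` or the built-in table)."""
    for sig in sigs if sigs is not None else builtin_signatures():
        if sig.name == name:
            return sig
    raise KeyError(name)
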