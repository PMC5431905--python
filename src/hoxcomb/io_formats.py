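"""Reading and writing the external formats the pipeline touches.

Protein FASTA (plain and aligned), tab-separated classification reports,
and newick trees.  Sequences are carried as :class:`SequenceRecord`; an
aligned set with verified uniform width is an :class:`Alignment`.

Conventions
-----------
* The record id is the first whitespace-delimited token of the FASTA
  header; the remainder of the header is kept as ``description``.
* Residues are uppercased on input.  The alphabet is the 20 standard
  amino acids plus ``X`` (unknown) and ``-`` (gap, alignments only).
  A trailing ``*`` (stop) is stripped; a ``*`` anywhere else is an error.
* Reports are TSV, not CSV, so free-text description fields never need
  quoting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue symbols accepted in input sequences.
VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X", "-"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence.

    ``id`` is the first whitespace token of the FASTA header and must be
    unique within a parsed file; ``residues`` is a non-empty uppercase
    string over the 20-letter alphabet plus ``X`` and ``-``.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise DataError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise DataError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise DataError(
                f"record {self.id!r} contains invalid residue(s): "
                f"{', '.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """An ordered list of equal-length records; gap character is ``-``."""

    records: tuple[SequenceRecord, ...]
    width: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError("alignment contains no sequences")
        widths = {len(r) for r in self.records}
        if len(widths) != 1:
            detail = ", ".join(f"{r.id}:{len(r)}" for r in self.records)
            raise DataError(f"ragged alignment (id:length = {detail})")
        object.__setattr__(self, "width", len(self.records[0]))

    def __len__(self) -> int:
        return len(self.records)

    def column(self, i: int) -> str:
        """Residues of 0-based column ``i``, in record order."""
        return "".join(r.residues[i] for r in self.records)


def _find_bad_char_line(path: Path, bad: str) -> int | None:
    """Best-effort line number of the first occurrence of ``bad`` in a sequence line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if bad in line.upper():
                return lineno
    return None


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a protein FASTA file.

    Residues are uppercased; a single trailing ``*`` stop symbol is
    stripped.  Duplicate ids and non-amino-acid characters are errors;
    an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        bad = set(residues) - VALID_RESIDUES
        if bad:
            ch = sorted(bad)[0]
            lineno = _find_bad_char_line(path, ch)
            where = f" at line {lineno}" if lineno is not None else ""
            raise DataError(
                f"record {rec.id!r}: invalid character {ch!r}{where} in {path}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        logger.warning("no sequences found in %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_alignment(path: str | Path) -> Alignment:
    """Parse an aligned FASTA file, verifying uniform width."""
    records = read_fasta(path)
    if not records:
        raise DataError(f"no sequences in alignment file {path}")
    return Alignment(records=tuple(records))


# -- classification report ---------------------------------------------------

REPORT_FIXED_COLUMNS = ("id", "assigned_label", "hd_start", "hd_score")


def write_report(results: Sequence, path: str | Path) -> None:
    """Write classification results as a TSV table.

    One row per input record, in input order.  Columns: id,
    assigned_label, hd_start (1-based, empty if no homeodomain),
    hd_score, one column per diagnostic-class score, and a
    semicolon-joined list of full-matching lineage motifs.
    """
    class_names = sorted({name for r in results for name in r.class_scores})
    header = list(REPORT_FIXED_COLUMNS) + [f"score_{c}" for c in class_names] + ["signature_hits"]
    lines = ["\t".join(header)]
    for r in results:
        if r.hit is None:
            start, score = "", ""
        else:
            start, score = str(r.hit.start + 1), f"{r.hit.score:.3f}"
        scores = [
            f"{r.class_scores[c]:.4f}" if c in r.class_scores else ""
            for c in class_names
        ]
        hits = ";".join(m.signature for m in r.motif_hits if m.full_match)
        lines.append("\t".join([r.seq_id, r.assigned_label, start, score, *scores, hits]))
    Path(path).write_text("\n".join(lines) + "\n")


# -- newick ------------------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,'\"]")


def escape_newick_label(label: str) -> str:
    """Quote a leaf label if it contains newick metacharacters."""
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree, path: str | Path) -> None:
    """Serialise a tree from :mod:`hoxcomb.phylo` as newick.

    Branch lengths are written to 6 significant digits; internal-node
    bootstrap supports, when present, appear as internal node labels.
    """
    Path(path).write_text(tree.to_newick() + "\n")
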