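"""Rule-based assignment of Hox proteins to paralog-group labels.

The classifier combines three kinds of evidence computed from the analysis
segment (homeodomain + 12-residue carboxy flank):

* the best-scoring homeodomain window and its profile score,
* per-class diagnostic fractions (central, posterior, plus any
  user-supplied class tables),
* full-match hits of lineage flank motifs (Lox5-parapeptide,
  gnathiferan PG6 motif, user additions).

Assignment is a fixed rule cascade; each rule that fires (and each that is
consulted) is recorded in the result's evidence notes so every call can be
audited.  The MedPost rule captures the hybrid profile that defines that
gene class: a predominantly central-class homeodomain that nevertheless
carries a small subset of posterior-class residues (K3 and/or Y20) while
scoring clearly below the posterior call threshold.

Thresholds are package choices, not published constants: the defaults
(0.75 central, 0.6 posterior) are set so that the canonical evidence
patterns — a full printed central match, and a 2-of-5 posterior match — fall
cleanly on the intended sides.  Both are exposed in
:class:`ClassifierConfig`.

Phylogenetic corroboration (see :mod:`hoxcomb.phylo`) is deliberately kept
out of ``classify``: residue evidence and tree evidence are reported side
by side, never fused.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import DataError
from .io_formats import SequenceRecord, read_fasta
from .locator import HomeodomainHit, ScoringProfile, locate_homeodomain
from .signatures import (
    DIAGNOSTIC_CLASS,
    LINEAGE_MOTIF,
    MatchResult,
    SignatureDef,
    builtin_signatures,
    match_signature,
    score_class,
)

logger = logging.getLogger(__name__)

# Label vocabulary (the decidable subset; classes whose diagnostics are not
# in the shipped table surface as the generic labels below).
LABEL_NO_HOMEODOMAIN = "no_homeodomain"
LABEL_UNCLASSIFIED = "unclassified_Hox"
LABEL_MEDPOST = "MedPost"
LABEL_LOX5 = "Lox5-like"
LABEL_GNATHIFERA = "Gnathifera-PG6-like"
LABEL_POSTERIOR = "posterior"
LABEL_GENERIC_CENTRAL = "PG6-7/central"

CENTRAL_CLASS = "central_class"
POSTERIOR_CLASS = "posterior_class"

_MOTIF_LABELS = {"lox5_parapeptide": LABEL_LOX5, "gnathifera_pg6": LABEL_GNATHIFERA}


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the rule cascade.

    ``medpost_posterior_positions`` are the posterior-class positions whose
    presence (any non-empty subset) marks the MedPost hybrid; ``min_hd_score``
    of ``None`` defers to the profile's calibrated threshold.
    """

    central_call_threshold: float = 0.75
    posterior_call_threshold: float = 0.6
    medpost_posterior_positions: frozenset[int] = frozenset({3, 20})
    min_hd_score: float | None = None

    def __post_init__(self) -> None:
        for name in ("central_call_threshold", "posterior_call_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DataError(f"{name} must be in (0, 1], got {v}")
        if not self.medpost_posterior_positions:
            raise DataError("medpost_posterior_positions must be non-empty")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "ClassifierConfig":
        kwargs = dict(data)
        if "medpost_posterior_positions" in kwargs:
            kwargs["medpost_posterior_positions"] = frozenset(
                int(p) for p in kwargs["medpost_posterior_positions"]
            )
        return cls(**kwargs)


@dataclass(frozen=True)
class ClassificationResult:
    """Label plus full evidence trail for one input record."""

    seq_id: str
    assigned_label: str
    class_scores: Mapping[str, float]
    motif_hits: tuple[MatchResult, ...]
    hit: HomeodomainHit | None
    notes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.assigned_label == LABEL_NO_HOMEODOMAIN) != (self.hit is None):
            raise DataError("no_homeodomain label must coincide with a missing hit")
        for name, v in self.class_scores.items():
            if not 0.0 <= v <= 1.0:
                raise DataError(f"class score {name}={v} outside [0, 1]")


def classify(
    record: SequenceRecord,
    profile: ScoringProfile,
    signatures: Sequence[SignatureDef] | None = None,
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Assign a paralog-group label to one protein.

    Pure function of (residues, profile, signatures, config); every
    degenerate input yields a label, never an exception.  The cascade:

    1. no homeodomain hit -> ``no_homeodomain``;
    2. central score >= threshold, some MedPost-marker posterior position
       matched, posterior score < threshold -> ``MedPost``;
    3. central score >= threshold and a lineage motif full-matches -> that
       motif's label (two full matches: the one with more constraints wins,
       a tie -> ``unclassified_Hox`` with a note);
    4. posterior score >= threshold and central score < threshold ->
       ``posterior``;
    5. central score >= threshold, no flank motif -> ``PG6-7/central``;
    6. otherwise ``unclassified_Hox``.
    """
    if signatures is None:
        signatures = builtin_signatures()
    if config is None:
        config = ClassifierConfig()
    notes: list[str] = []

    hit = locate_homeodomain(record, profile, min_score=config.min_hd_score)
    if hit is None:
        notes.append("rule 1: no homeodomain window above threshold")
        return ClassificationResult(
            seq_id=record.id,
            assigned_label=LABEL_NO_HOMEODOMAIN,
            class_scores={},
            motif_hits=(),
            hit=None,
            notes=tuple(notes),
        )
    if hit.ambiguous:
        notes.append("homeodomain hit ambiguous: second non-overlapping window within 5%")

    segment = hit.segment
    class_sigs = [s for s in signatures if s.kind == DIAGNOSTIC_CLASS]
    motif_sigs = [s for s in signatures if s.kind == LINEAGE_MOTIF]
    class_scores = {s.name: score_class(segment, s) for s in class_sigs}
    class_matches = {s.name: match_signature(segment, s) for s in class_sigs}
    motif_hits = tuple(match_signature(segment, s) for s in motif_sigs)

    central = class_scores.get(CENTRAL_CLASS, 0.0)
    posterior = class_scores.get(POSTERIOR_CLASS, 0.0)
    posterior_positions: frozenset[int] = frozenset(
        class_matches[POSTERIOR_CLASS].matched_positions
    ) if POSTERIOR_CLASS in class_matches else frozenset()

    central_ok = central >= config.central_call_threshold
    medpost_markers = posterior_positions & config.medpost_posterior_positions
    full_motifs = [m for m in motif_hits if m.full_match]

    def result(label: str) -> ClassificationResult:
        return ClassificationResult(
            seq_id=record.id,
            assigned_label=label,
            class_scores=class_scores,
            motif_hits=motif_hits,
            hit=hit,
            notes=tuple(notes),
        )

    # rule 2: hybrid central/posterior profile
    if central_ok and medpost_markers and posterior < config.posterior_call_threshold:
        notes.append(
            "rule 2: MedPost — central score "
            f"{central:.2f} >= {config.central_call_threshold}, posterior markers at "
            f"{sorted(medpost_markers)}, posterior score {posterior:.2f} < "
            f"{config.posterior_call_threshold}"
        )
        return result(LABEL_MEDPOST)

    # rule 3: central profile with a lineage flank motif
    if central_ok and full_motifs:
        best = max(m.n_constraints for m in full_motifs)
        top = [m for m in full_motifs if m.n_constraints == best]
        if len(top) > 1:
            notes.append(
                "rule 3: tie between full-matching motifs "
                f"{sorted(m.signature for m in top)} — unclassified"
            )
            return result(LABEL_UNCLASSIFIED)
        chosen = top[0]
        label = _MOTIF_LABELS.get(chosen.signature)
        if label is None:
            notes.append(
                f"rule 3: full match of user motif {chosen.signature!r} has no "
                "label mapping — unclassified"
            )
            return result(LABEL_UNCLASSIFIED)
        notes.append(
            f"rule 3: {label} — central score {central:.2f} and full match of "
            f"{chosen.signature} at {chosen.matched_positions}"
        )
        return result(label)

    # rule 4: plain posterior gene
    if posterior >= config.posterior_call_threshold and not central_ok:
        notes.append(
            f"rule 4: posterior — posterior score {posterior:.2f} >= "
            f"{config.posterior_call_threshold}, central score {central:.2f} below threshold"
        )
        return result(LABEL_POSTERIOR)

    # rule 5: generic central
    if central_ok:
        notes.append(
            f"rule 5: generic central — central score {central:.2f}, no flank motif"
        )
        return result(LABEL_GENERIC_CENTRAL)

    notes.append(
        f"rule 6: unclassified — central {central:.2f}, posterior {posterior:.2f}, "
        "no motif evidence"
    )
    return result(LABEL_UNCLASSIFIED)


def classify_file(
    fasta_path: str | Path,
    profile: ScoringProfile | None = None,
    signatures: Sequence[SignatureDef] | None = None,
    config: ClassifierConfig | None = None,
) -> list[ClassificationResult]:
    """Classify every record of a FASTA file, in input order.

    With no explicit profile, the profile built from the bundled seed
    alignment is used.  Logs a one-line per-label summary.
    """
    if profile is None:
        from .simulate import default_profile

        profile = default_profile()
    records = read_fasta(fasta_path)
    results = [classify(rec, profile, signatures, config) for rec in records]
    counts = Counter(r.assigned_label for r in results)
    logger.info(
        "classified %d records: %s",
        len(results),
        ", ".join(f"{lab}={n}" for lab, n in sorted(counts.items())) or "none",
    )
    return results
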