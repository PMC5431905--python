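"""Synthetic labeled Hox-like proteins for end-to-end testing.

Each generated record is a background protein of 150-600 residues with one
60-aa homeodomain embedded at a known offset.  The homeodomain is the
shipped neutral reference consensus with the diagnostic residues of the
record's class forced in place:

* central-type labels force Q6, L26, T27, R28, (R/K)29, R30, R31, E59;
* ``posterior`` forces K3, A14, R18, Y20, V21;
* ``MedPost`` forces the central set plus K3 and Y20, with positions
  14/18/21 explicitly forced to residues *outside* the posterior-class
  sets, so a MedPost record matches exactly the two posterior positions
  its namesake genes share;
* ``Lox5-like`` / ``Gnathifera-PG6-like`` are central-type and
  additionally plant KLTGP at flank positions 64-68 or KS(I/L)ND at
  63-67.

After planting, i.i.d. substitution noise at per-site rate ``mu``
(replacement by a uniformly chosen *different* residue) is applied to the
whole protein — including diagnostic positions, unless
``protect_signatures`` is set.  Ground truth (label, homeodomain offset,
planted signatures) travels with every record, and a fixed seed makes the
output byte-identical across runs.

The module also builds the bundled profile seed alignment from the same
class templates, and two clearly-labelled synthetic stand-in proteins
whose homeodomains and flanks realise the published diagnostic residue
patterns of the rotifer MedPost and Hox6 genes (the deposited sequences
themselves are fetched manually by users who want them; see README).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError
from .io_formats import AMINO_ACIDS, Alignment, SequenceRecord
from .locator import FLANK_LENGTH, HOMEODOMAIN_LENGTH, SEGMENT_LENGTH, ScoringProfile, build_profile

# Generator label vocabulary. Central-type labels share the central
# diagnostic set and differ in their flank motif (or lack of one).
LABEL_CENTRAL = "PG6-7/central"
LABEL_POSTERIOR = "posterior"
LABEL_MEDPOST = "MedPost"
LABEL_LOX5 = "Lox5-like"
LABEL_GNATHIFERA = "Gnathifera-PG6-like"

GENERATOR_LABELS = (
    LABEL_CENTRAL,
    LABEL_POSTERIOR,
    LABEL_MEDPOST,
    LABEL_LOX5,
    LABEL_GNATHIFERA,
)

# Forced residues per class, 1-based segment coordinates. A multi-residue
# string means one allowed residue is sampled (or the first taken when
# building deterministic templates).
_CENTRAL_FORCED: dict[int, str] = {
    6: "Q", 26: "L", 27: "T", 28: "R", 29: "RK", 30: "R", 31: "R", 59: "E",
}
_POSTERIOR_FORCED: dict[int, str] = {3: "K", 14: "A", 18: "R", 20: "Y", 21: "V"}

#: Posterior positions a MedPost homeodomain shares (K3, Y20) ...
_MEDPOST_SHARED: dict[int, str] = {3: "K", 20: "Y"}
#: ... and the posterior positions it must NOT match (forced to the complement).
_MEDPOST_EXCLUDED: dict[int, str] = {14: "A", 18: "R", 21: "V"}

_LOX5_FLANK: dict[int, str] = {64: "K", 65: "L", 66: "T", 67: "G", 68: "P"}
_GNATHIFERA_FLANK: dict[int, str] = {63: "K", 64: "S", 65: "IL", 66: "N", 67: "D"}

_FLANK_PLANTS: dict[str, dict[int, str]] = {
    LABEL_LOX5: _LOX5_FLANK,
    LABEL_GNATHIFERA: _GNATHIFERA_FLANK,
}
_PLANTED_SIGNATURE_NAME = {
    LABEL_LOX5: "lox5_parapeptide",
    LABEL_GNATHIFERA: "gnathifera_pg6",
}


@lru_cache(maxsize=1)
def reference_homeodomain() -> str:
    """The shipped 60-aa neutral reference homeodomain consensus."""
    text = resources.files("hoxcomb.data").joinpath("reference_homeodomain.txt").read_text()
    seq = "".join(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )
    if len(seq) != HOMEODOMAIN_LENGTH:
        raise DataError("reference homeodomain data file is not 60 residues")
    return seq


def _hd_forced(label: str) -> dict[int, str]:
    """Forced homeodomain residues (as option strings) for a generator label."""
    if label in (LABEL_CENTRAL, LABEL_LOX5, LABEL_GNATHIFERA):
        return dict(_CENTRAL_FORCED)
    if label == LABEL_POSTERIOR:
        return dict(_POSTERIOR_FORCED)
    if label == LABEL_MEDPOST:
        forced = dict(_CENTRAL_FORCED)
        forced.update(_MEDPOST_SHARED)
        # complement of the posterior-allowed residue at each excluded position
        for pos, avoid in _MEDPOST_EXCLUDED.items():
            forced[pos] = "".join(a for a in AMINO_ACIDS if a not in avoid)
        return forced
    raise DataError(f"unknown generator label {label!r}")


def _pick(options: str, rng: np.random.Generator | None) -> str:
    if len(options) == 1 or rng is None:
        return options[0]
    return options[int(rng.integers(len(options)))]


def class_homeodomain(label: str, rng: np.random.Generator | None = None) -> str:
    """The reference homeodomain with ``label``'s diagnostic residues forced.

    Without an ``rng`` the first option of any degenerate position is
    taken, giving a deterministic class template.
    """
    hd = list(reference_homeodomain())
    for pos, options in _hd_forced(label).items():
        hd[pos - 1] = _pick(options, rng)
    return "".join(hd)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    ``class_mix`` maps generator labels to proportions (default: uniform
    over the five labels); ``mu`` is the per-site substitution
    probability; ``protein_length`` is the inclusive length range.
    """

    n_records: int
    class_mix: Mapping[str, float] | None = None
    mu: float = 0.0
    protein_length: tuple[int, int] = (150, 600)
    background: Sequence[float] | None = None
    seed: int = 0
    protect_signatures: bool = False

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise DataError("n_records must be non-negative")
        if not 0.0 <= self.mu < 1.0:
            raise DataError("mu must be in [0, 1)")
        lo, hi = self.protein_length
        if lo < SEGMENT_LENGTH or hi < lo:
            raise DataError(
                f"protein_length range must satisfy {SEGMENT_LENGTH} <= lo <= hi"
            )
        mix = self.resolved_class_mix()
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise DataError("class_mix proportions must sum to 1")
        for label in mix:
            if label not in GENERATOR_LABELS:
                raise DataError(f"unknown label in class_mix: {label!r}")

    def resolved_class_mix(self) -> dict[str, float]:
        if self.class_mix is None:
            return {lab: 1.0 / len(GENERATOR_LABELS) for lab in GENERATOR_LABELS}
        return dict(self.class_mix)

    def resolved_background(self) -> np.ndarray:
        if self.background is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (len(AMINO_ACIDS),) or abs(bg.sum() - 1.0) > 1e-9:
            raise DataError("background must be 20 frequencies summing to 1")
        return bg


@dataclass(frozen=True)
class SyntheticRecord:
    """A generated protein with its ground truth."""

    record: SequenceRecord
    true_label: str
    hd_start: int
    planted_signatures: tuple[str, ...] = ()


def generate(config: GeneratorConfig) -> list[SyntheticRecord]:
    """Generate labeled synthetic proteins under ``config``.

    Deterministic in ``config.seed``: the same config yields byte-identical
    records.  Each record draws from its own spawned RNG stream, with the
    noise draws last, so cohorts generated at different ``mu`` from the
    same seed share their pre-noise records site for site.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_records)
    mix = config.resolved_class_mix()
    labels = sorted(mix)  # sorted for draw-order determinism
    probs = np.array([mix[lab] for lab in labels])
    bg = config.resolved_background()
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    lo, hi = config.protein_length

    out: list[SyntheticRecord] = []
    for i in range(config.n_records):
        rng = np.random.default_rng(children[i])
        label = labels[int(rng.choice(len(labels), p=probs))]
        length = int(rng.integers(lo, hi + 1))
        # keep the full 72-position segment inside the protein
        hd_start = int(rng.integers(0, length - SEGMENT_LENGTH + 1))
        seq = rng.choice(aa, size=length, p=bg)

        protected: set[int] = set()  # 0-based protein indices
        hd = class_homeodomain(label, rng)
        for p in range(HOMEODOMAIN_LENGTH):
            seq[hd_start + p] = hd[p]
        protected.update(hd_start + p - 1 for p in _hd_forced(label))

        planted: tuple[str, ...] = ()
        if label in _FLANK_PLANTS:
            for pos, options in sorted(_FLANK_PLANTS[label].items()):
                idx = hd_start + pos - 1
                seq[idx] = _pick(options, rng)
                protected.add(idx)
            planted = (_PLANTED_SIGNATURE_NAME[label],)

        if config.mu > 0.0:
            hits = np.flatnonzero(rng.random(length) < config.mu)
            for idx in hits:
                if config.protect_signatures and int(idx) in protected:
                    continue
                current = seq[idx]
                choices = [a for a in AMINO_ACIDS if a != current]
                seq[idx] = choices[int(rng.integers(len(choices)))]

        record = SequenceRecord(
            id=f"synth_{i:04d}",
            residues="".join(seq),
            description=f"true_label={label} hd_start={hd_start}",
        )
        out.append(
            SyntheticRecord(
                record=record,
                true_label=label,
                hd_start=hd_start,
                planted_signatures=planted,
            )
        )
    return out


# -- ground-truth table ------------------------------------------------------

_TRUTH_HEADER = ("id", "true_label", "hd_start", "planted_signatures")


def write_truth(records: Sequence[SyntheticRecord], path: str | Path) -> None:
    """Write the generator ground truth as TSV (hd_start is 0-based)."""
    lines = ["\t".join(_TRUTH_HEADER)]
    for r in records:
        lines.append(
            "\t".join(
                [r.record.id, r.true_label, str(r.hd_start), ";".join(r.planted_signatures)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> list[dict]:
    """Read a ground-truth TSV back as a list of dicts."""
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != _TRUTH_HEADER:
        raise DataError(f"{path} is not a hoxcomb truth table")
    out = []
    for line in lines[1:]:
        ident, label, start, planted = line.split("\t")
        out.append(
            {
                "id": ident,
                "true_label": label,
                "hd_start": int(start),
                "planted_signatures": tuple(p for p in planted.split(";") if p),
            }
        )
    return out


# -- bundled seed alignment and default profile ------------------------------


def make_seed_alignment() -> Alignment:
    """The bundled gap-free width-60 seed alignment for profile building.

    Five deterministic class templates: the neutral reference, central
    templates with R and with K at position 29, the posterior template,
    and the MedPost template.  Users with curated homeodomain alignments
    can supply their own instead.
    """
    central_k29 = list(class_homeodomain(LABEL_CENTRAL))
    central_k29[29 - 1] = "K"
    rows = [
        SequenceRecord(id="reference", residues=reference_homeodomain()),
        SequenceRecord(id="central_r29", residues=class_homeodomain(LABEL_CENTRAL)),
        SequenceRecord(id="central_k29", residues="".join(central_k29)),
        SequenceRecord(id="posterior", residues=class_homeodomain(LABEL_POSTERIOR)),
        SequenceRecord(id="medpost", residues=class_homeodomain(LABEL_MEDPOST)),
    ]
    return Alignment(records=tuple(rows))


@lru_cache(maxsize=1)
def default_profile() -> ScoringProfile:
    """Profile built from the bundled seed alignment (cached)."""
    return build_profile(make_seed_alignment())


# -- synthetic stand-ins for the deposited rotifer sequences -----------------


def _standin_protein(
    hd: str,
    flank_plants: dict[int, str],
    seed: int,
    n_term: int = 40,
    c_term: int = 30,
) -> str:
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    n = n_term + HOMEODOMAIN_LENGTH + FLANK_LENGTH + c_term
    seq = rng.choice(aa, size=n)
    seq[n_term : n_term + HOMEODOMAIN_LENGTH] = list(hd)
    for pos, res in flank_plants.items():
        seq[n_term + pos - 1] = res
    return "".join(seq)


def synthetic_bm_medpost_standin() -> SequenceRecord:
    """SYNTHETIC stand-in for the rotifer MedPost protein (not the deposited
    GenBank sequence).

    A 142-residue synthetic protein whose homeodomain realises the
    published MedPost diagnostic pattern: the full printed central-class
    set (Q6, LTR(R/K)RR 26-31, E59) plus exactly the two shared posterior
    residues K3 and Y20, with non-posterior residues at 14/18/21 and no
    flank motif.
    """
    return SequenceRecord(
        id="Bm-MedPost_synthetic_standin",
        residues=_standin_protein(class_homeodomain(LABEL_MEDPOST), {}, seed=989542),
        description="synthetic stand-in realising the published MedPost diagnostic residues",
    )


def synthetic_bm_hox6_standin() -> SequenceRecord:
    """SYNTHETIC stand-in for the rotifer Hox6 (PG6) protein (not the
    deposited GenBank sequence).

    A central-class homeodomain followed by a carboxy flank carrying the
    gnathiferan PG6 motif KSLND at segment positions 63-67.
    """
    plants = {pos: options[0] for pos, options in sorted(_GNATHIFERA_FLANK.items())}
    return SequenceRecord(
        id="Bm-Hox6_synthetic_standin",
        residues=_standin_protein(class_homeodomain(LABEL_GNATHIFERA), plants, seed=989541),
        description="synthetic stand-in carrying the gnathiferan PG6 flank motif KS(I/L)ND",
    )
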