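# Methods

This note documents the models, parameter choices and numerical
conventions behind hoxcomb, and what its synthetic benchmarks do and do
not demonstrate about real sequences.

## Coordinates and the analysis segment

All positional claims are made in 1-based *segment coordinates* anchored
to the homeodomain: positions 1–60 are the canonical 60-aa homeodomain,
positions 61–72 the 12 carboxy-flank residues that follow it. This is
the coordinate system in which the field states Hox diagnostics
("position 6 of the homeodomain", a flank motif "at 63–67"), so hoxcomb
never renumbers. Internally, protein offsets are 0-based half-open; the
report prints the 1-based homeodomain start for human readers, and the
conversion is covered by tests. The homeodomain length is fixed at 60:
the diagnostic coordinate system presupposes the canonical domain, and
segments with fewer than 12 flank residues arise only when the protein
ends early. The amino-terminal flank is not extracted — none of the
shipped diagnostics use it.

## Homeodomain location

Detection uses a 60×20 position-specific log-odds matrix. Column scores
are `ln((c_r + π·q_r)/(N + π)) − ln(q_r)` with pseudocount π = 1 and a
uniform background q = 1/20 by default; `X` and gap characters score 0
(background-neutral). This is an ungapped PSSM, not a profile HMM:
homeodomains are essentially indel-free over their 60 columns, and the
positional diagnostics downstream assume exact column register, so
insert/delete states would buy nothing and would blur the coordinate
anchoring. Only the best window per protein is reported (multi-domain
proteins are out of scope); a hit is flagged *ambiguous* when another
non-overlapping window scores within 5% of it.

**Hit threshold.** The default `min_score` is the 99th percentile of the
*per-protein maximum* window score over 1,000 background proteins of 600
residues, simulated once at profile build with a fixed internal seed (so
the threshold is a deterministic property of the profile). The
per-protein maximum — not the single-window score distribution — is the
relevant null, because a scan reports the best of the several hundred
windows a protein contains; calibrating on single windows at the same
percentile would let most background proteins through (measured: ~73% of
random 200-mers produce a spurious hit under a single-window 99th
percentile, and none under the per-protein-maximum one). The margin is
comfortable in both directions: true homeodomains score around +160 (and
still above +100 at 10% substitution noise), background maxima around
−50.

**Seed alignment.** The bundled profile is built from five deterministic
60-mers: a neutral reference homeodomain and the class templates
(central with R29, central with K29, posterior, MedPost) derived from
it. The reference is an Antennapedia-style sequence in which every
shipped diagnostic position holds a residue matching *no* diagnostic
constraint; it is shipped as an editable data file. Users with curated
homeodomain alignments (width 60, gap-free, ≥ 5 rows) can build their
own profile, and profiles serialise to a documented TSV.

## Signatures and scoring

Signatures live in a plain TSV table rather than code because the
published diagnostic sets are open-ended: the shipped central-class set
contains the 8 widely printed positions of an 11-position set (the table
records this in a note), and anterior/PG3 diagnostics can be added by
users without touching the scanner. Matching is strict presence/absence
— degenerate positions are residue *sets* ({R,K} at 29, {I,L} at 65),
with no substitution-matrix softening, because the diagnostic convention
itself is categorical. `X` never matches. A constraint beyond a
truncated flank counts as a mismatch rather than "not applicable": this
is conservative and keeps class-score denominators identical across
records, at the cost of penalising C-terminally truncated fragments.

## Classification cascade

Thresholds are package choices, not published constants. Central call
threshold 0.75 and posterior call threshold 0.6 are set so that the two
canonical evidence patterns fall cleanly where they belong: a full
8-of-8 printed central match (1.0) clears 0.75 even after a missed
residue or two, and the MedPost-defining 2-of-5 posterior match (0.4)
stays below 0.6 while a true posterior gene's 5-of-5 clears it. The
MedPost rule demands all three conditions — high central score, at least
one of the marker positions {3, 20} matched, posterior score *below*
threshold — because the class is defined by its predominantly central
profile; a gene matching most posterior diagnostics is a posterior gene,
whatever its K3/Y20 status. Matched positions are recorded so users can
audit whether 14/18/21 were absent or merely non-majority. Rule order
(MedPost before flank motifs) is safe because the marker positions and
the motif positions are disjoint and the generator's templates are
neutral off-class; each classification records exactly one fired rule in
its notes, which the tests assert on random and synthetic inputs alike.

Tree evidence is deliberately *not* consulted by `classify`: residue
diagnostics and phylogenetic corroboration are reported side by side so
disagreements stay visible, rather than being fused by an opaque rule.

## Motif discovery

Discovery scans fixed segment coordinates (default region 61–72) without
realignment, since flank signatures are claims about
homeodomain-anchored positions. Per column, the smallest residue set
covering ≥ `min_fraction` of sequences is found greedily by descending
count, ties broken lexicographically — deterministic output. Defaults
(`min_fraction` 1.0, `max_degeneracy` 2, `min_run` 4) mirror the target
motif shape: the known flank signatures are exceptionless in published
alignments, five columns long, with at most one two-way degenerate
column. `min_fraction` is a parameter, not a claim — real ortholog sets
show some flank variability, and relaxing it trades recall for noise.
Degenerate columns render alphabetically ("(I/L)"), and candidate names
are their consensus strings. With ten random flanks the probability of a
spurious 4-run of ≤ 2-residue columns is far below 10⁻⁶, which the
anti-discovery tests confirm empirically.

## Trees

Distances are uncorrected p-distances over the common covered segment
length, skipping positions where either residue is `X`. No LG+Γ+I-style
model correction is attempted: at 72 positions the variance of the
distance dominates what a substitution model would add, and the tree is
positioned as corroboration, not inference; the distance function is
pluggable for users who want corrected distances. Neighbor joining
follows Saitou–Nei with the Q-criterion; the Q values are evaluated on
the upper triangle only (the two float summation orders of a symmetric
formula differ in the last bit) and ties are broken by the
lexicographically smallest pair of cluster keys, making the topology
invariant under input permutation — a property test shuffles inputs 20
ways. Negative branch-length estimates are clamped to zero (standard
practice; logged). Bootstrap resamples the 72 columns with replacement,
recomputes distances and the NJ tree per replicate, and reports for each
internal edge of the original tree the fraction of replicates containing
its bipartition; supports are embedded in newick as internal node
labels. Identical runs are bit-identical given the seed.

## Synthetic data

The generator is the package's study-condition definition, not a
convenience. Proteins are 150–600 residues of uniform background with
one homeodomain embedded at a uniform offset chosen so the full
72-position segment fits. Class structure is minimal by design: all
non-diagnostic positions come from the single neutral reference, so
classes differ *exactly* by their diagnostic residues and classification
tests isolate the rules under test rather than profile-level
differences. MedPost templates force non-posterior residues at 14/18/21,
making the generated class unambiguous under the cascade. Substitution
noise is i.i.d. per site at rate μ, replacing a residue with a uniformly
chosen different one, applied to diagnostic positions too (realistic
degradation) unless `protect_signatures` is set for locator-only
experiments. Each record draws from its own spawned RNG stream with
noise drawn last, so cohorts at different μ from one seed share their
pre-noise records — which is how the calibration test measures the
realised substitution fraction (within 3 binomial standard errors of μ
over ≥ 10⁵ sites).

What the benchmarks show: at μ = 0 the pipeline is an exact identity on
ground truth (offsets, labels, planted motifs, 500 records); accuracy
degrades monotonically with μ and is ≥ 0.95 at μ = 0.02 under pinned
seeds, with the dominant error mode being a single substitution inside a
5-residue flank motif demoting a motif-bearing gene to generic central.
What they do not show: robustness to indels, compositional bias,
correlated (phylogenetic) sampling, multi-domain proteins, or
homeodomains diverged far from the seed alignment — real-data
performance on such inputs is untested and the generator deliberately
does not emulate them.

Because public sequence databases are not touched at build or test time,
the two worked examples run on *synthetic stand-ins*: proteins whose
homeodomain and flank realise the published diagnostic residue patterns
of the rotifer MedPost and Hox6 genes (full printed central set plus
exactly K3/Y20; central set plus KSLND at 63–67). They exercise the
same code path as the deposited sequences would, and users can rerun the
scan on the real records by downloading them manually.

## Problem sizes

Default verification sizes — 500-record noise-free cohorts, 200 records
per noise level, 100 bootstrap replicates on 8 taxa, 1,000 random
proteins for threshold calibration — keep the full test suite and the
acceptance script in the seconds-to-a-minute range on a single CPU while
leaving binomial standard errors on reported rates at or below ~2
percentage points.
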