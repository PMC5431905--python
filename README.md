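# hoxcomb

Homeodomain signature scanning, Hox paralog-group classification,
carboxy-flank motif discovery, and desk-scale neighbor-joining
phylogenetics for protein sequences.

## The problem

Hox genes encode homeodomain transcription factors whose ~60-aa
DNA-binding domain is so conserved that tree inference alone often cannot
resolve which ancestral paralog group (PG1–PG14) a newly cloned gene
belongs to. Practitioners therefore also read *signatures*: individual
diagnostic residues and short motifs at fixed, homeodomain-anchored
positions, inside the domain or in its carboxy flanking region. Classic
examples are the central-class residues Q6, LTR(R/K)RR at 26–31 and E59;
the posterior-class residues K3, A14, R18, Y20, V21; the
Lox5-parapeptide **KLTGP** at flank positions 64–68 that marks
lophotrochozoan/platyhelminth PG6/7 (*Lox5*) genes; and the gnathiferan
PG6 motif **KS(I/L)ND** at 63–67 found in rotifer and chaetognath *Hox6*
genes instead. A hybrid pattern — a predominantly central-class
homeodomain that still carries the posterior residues K3 and Y20 while
failing every other posterior diagnostic — defines the *MedPost* gene
class of chaetognaths and rotifers.

hoxcomb turns this manual reading into a tested, reusable pipeline for
people classifying homeobox sequences: it finds the homeodomain, cuts
the 72-residue *analysis segment* (homeodomain positions 1–60 plus the
12-residue carboxy flank, positions 61–72), scores diagnostic classes
and motifs, assigns a paralog-group label with a full evidence trail,
discovers new flank motifs from ortholog sets, and corroborates
groupings with a neighbor-joining tree and column bootstrap.

## The method in brief

* **Location.** A position-specific scoring matrix over the 60
  homeodomain columns, built from a gap-free seed alignment with
  per-column log-odds `ln((c_r + π·q_r)/(N + π)) − ln(q_r)` (pseudocount
  π = 1, background q uniform), is slid over the protein; the
  best-scoring window is a hit if it clears a background-calibrated
  threshold.
* **Scoring.** A signature is a set of `(position, allowed residue set)`
  constraints in 1-based segment coordinates. Diagnostic classes score
  as the matched fraction; lineage motifs by full presence/absence.
* **Classification.** A fixed rule cascade: no hit → `no_homeodomain`;
  central ≥ 0.75 with K3/Y20 present but posterior < 0.6 → `MedPost`;
  central plus a full flank motif → `Lox5-like` / `Gnathifera-PG6-like`;
  posterior ≥ 0.6 alone → `posterior`; bare central → `PG6-7/central`;
  else `unclassified_Hox`. Every firing is recorded in the result notes.
* **Discovery.** Columns of the flank region are conserved when ≤ 2
  residues cover all sequences; runs of ≥ 4 conserved columns become
  candidate signatures (exactly the KLTGP / KS(I/L)ND shape).
* **Trees.** p-distances on segments, Saitou–Nei neighbor joining
  (deterministic tie-breaking), support by resampling the 72 columns.
* **Simulation.** A generator plants class-specific homeodomains and
  flank motifs in background proteins at known offsets with tunable
  substitution noise, so every stage is testable against ground truth
  with no downloads.

## Worked example

`python examples/scan_diagnostic_patterns.py` scans two bundled
*synthetic stand-in* proteins constructed to the published diagnostic
patterns of the rotifer MedPost and Hox6 genes (the deposited GenBank
records KT989538–KT989542 can be substituted by downloading them
manually as protein FASTA):

```
Bm-MedPost_synthetic_standin: homeodomain at offset 40 (score 158.5)
  central_class      8/8 matched at [6, 26, 27, 28, 29, 30, 31, 59] FULL
  posterior_class    2/5 matched at [3, 20]
  lox5_parapeptide   1/5 matched at [66]
  gnathifera_pg6     0/5 matched at []
  assigned label: MedPost

Bm-Hox6_synthetic_standin: homeodomain at offset 40 (score 162.4)
  central_class      8/8 matched at [6, 26, 27, 28, 29, 30, 31, 59] FULL
  posterior_class    0/5 matched at []
  lox5_parapeptide   0/5 matched at []
  gnathifera_pg6     5/5 matched at [63, 64, 65, 66, 67] FULL
  assigned label: Gnathifera-PG6-like
```

Reading: the first protein matches the full printed central-class set
yet exactly two posterior diagnostics (K3, Y20) — the MedPost hybrid
pattern — while the second is a central-class gene whose flank carries
the full gnathiferan KS(I/L)ND motif beginning at segment position 63.

The other examples (`classify_synthetic_cohort.py`,
`discover_flank_motifs.py`, `tree_with_bootstrap.py`) demonstrate noisy
cohort classification, motif rediscovery plus the KS(I/L)ND-vs-KLTGP
incompatibility report, and bootstrap support of a planted clade.

## Command line

A thin CLI wraps the library: `hoxcomb simulate | classify | discover |
tree | report`; `hoxcomb --show-config` prints every tunable default,
and each command writes a JSON run manifest next to its output. Example:

```sh
hoxcomb simulate --n 200 --mu 0.05 --seed 7 --out synth.fasta --truth truth.tsv
hoxcomb classify --in synth.fasta --out report.tsv
hoxcomb tree --in synth.fasta --bootstrap 100 --seed 42 --out tree.nwk
```

The signature table is plain TSV (`name<TAB>position<TAB>allowed[<TAB>kind]`,
`#` comments) and can be extended with user classes without touching code;
see `src/hoxcomb/data/signatures.tsv`.

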