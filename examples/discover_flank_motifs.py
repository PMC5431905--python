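"""Rediscover a planted carboxy-flank signature from an ortholog set.

A cohort of Gnathifera-PG6-like records is generated noise-free, their
analysis segments extracted at the known offsets, and the flank region
(positions 61-72) scanned for conserved column runs.  The single expected
candidate is the planted KS(I/L)ND motif at 63-67, with the degenerate
column rendered explicitly; the comparison report then shows why this
motif and the Lox5-parapeptide (KLTGP at 64-68) cannot co-occur in one
flank.
"""

import hoxcomb as hx

cohort = hx.generate(
    hx.GeneratorConfig(n_records=40, mu=0.0, seed=11, class_mix={"Gnathifera-PG6-like": 1.0})
)
segments = [hx.extract_segment(r.record, r.hd_start) for r in cohort]

candidates = hx.discover(segments)
for cand in candidates:
    span = f"{cand.positions[0]}-{cand.positions[-1]}"
    print(f"candidate motif {cand.name!r} at segment positions {span}")

report = hx.compare_signatures(candidates[0], hx.get_signature("lox5_parapeptide"))
print(f"vs lox5_parapeptide: shared positions {list(report.shared_positions)}, "
      f"conflicting {list(report.conflicting_positions)}, "
      f"co-occurrence possible: {report.co_occurrence_possible}")
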