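"""Score the published diagnostic residue patterns on the two synthetic
stand-in proteins.

The MedPost stand-in carries a full central-class homeodomain (Q6,
LTR(R/K)RR at 26-31, E59) plus exactly the two posterior-class residues
K3 and Y20; the Hox6 stand-in carries the gnathiferan PG6 flank motif
KS(I/L)ND at segment positions 63-67.  The scan should report a 2-of-5
posterior match at {3, 20} for the first and a full 5-of-5 motif match
starting at 63 for the second — the residue evidence that defines the
MedPost gene class and separates rotifer/chaetognath PG6 genes from
Lox5-parapeptide-bearing lophotrochozoan ones.
"""

import hoxcomb as hx

profile = hx.default_profile()
signatures = hx.builtin_signatures()

for record in (hx.synthetic_bm_medpost_standin(), hx.synthetic_bm_hox6_standin()):
    hit = hx.locate_homeodomain(record, profile)
    print(f"{record.id}: homeodomain at offset {hit.start} (score {hit.score:.1f})")
    for sig in signatures:
        m = hx.match_signature(hit.segment, sig)
        flag = " FULL" if m.full_match else ""
        print(
            f"  {sig.name:18s} {m.n_matched}/{m.n_constraints} matched "
            f"at {list(m.matched_positions)}{flag}"
        )
    result = hx.classify(record, profile, signatures)
    print(f"  assigned label: {result.assigned_label}")
    print()
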