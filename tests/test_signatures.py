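"""Built-in signature content and segment matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hoxcomb as hx
from hoxcomb.signatures import parse_signature_table, format_signature_table

from conftest import make_segment, random_residues


class TestBuiltins:
    def test_exactly_four_shipped(self, signatures):
        assert [s.name for s in signatures] == [
            "central_class",
            "posterior_class",
            "lox5_parapeptide",
            "gnathifera_pg6",
        ]

    def test_lox5_parapeptide_is_kltgp_at_64_to_68(self, signatures):
        sig = hx.get_signature("lox5_parapeptide", signatures)
        assert sig.positions == (64, 65, 66, 67, 68)
        assert [sorted(a) for _, a in sig.constraints] == [["K"], ["L"], ["T"], ["G"], ["P"]]

    def test_gnathifera_pg6_is_ksilnd_at_63_to_67(self, signatures):
        sig = hx.get_signature("gnathifera_pg6", signatures)
        assert sig.positions == (63, 64, 65, 66, 67)
        assert sig.allowed_at(65) == frozenset("IL")

    def test_posterior_class_positions(self, signatures):
        sig = hx.get_signature("posterior_class", signatures)
        assert sig.positions == (3, 14, 18, 20, 21)
        assert [sorted(a) for _, a in sig.constraints] == [["K"], ["A"], ["R"], ["Y"], ["V"]]

    def test_central_class_printed_subset(self, signatures):
        sig = hx.get_signature("central_class", signatures)
        assert sig.positions == (6, 26, 27, 28, 29, 30, 31, 59)
        assert sig.allowed_at(29) == frozenset("RK")
        assert "11" in sig.note  # documented as a subset of the 11-position set

    def test_user_extension_cannot_shadow(self, signatures):
        extra = hx.SignatureDef(name="central_class", constraints=((1, frozenset("A")),))
        with pytest.raises(hx.DataError, match="shadow"):
            hx.builtin_signatures(extra=[extra])


class TestMatchSignature:
    def test_medpost_posterior_profile_matches_two_of_five(self, signatures):
        # K at 3, Y at 20, non-diagnostic residues at 14/18/21
        seg = make_segment(p3="K", p20="Y")
        m = hx.match_signature(seg, hx.get_signature("posterior_class", signatures))
        assert (m.n_matched, m.matched_positions, m.full_match) == (2, (3, 20), False)

    def test_planted_kslnd_full_match(self, signatures):
        seg = make_segment(cflank="NKKSLNDAQWEA")
        m = hx.match_signature(seg, hx.get_signature("gnathifera_pg6", signatures))
        assert m.full_match

    def test_truncated_flank_counts_as_mismatch(self, signatures):
        seg = make_segment(cflank="KL")
        m = hx.match_signature(seg, hx.get_signature("lox5_parapeptide", signatures))
        assert m.n_matched == 0 and not m.full_match

    def test_x_never_matches(self, signatures):
        seg = make_segment(p3="X", p20="Y")
        m = hx.match_signature(seg, hx.get_signature("posterior_class", signatures))
        assert m.matched_positions == (20,)

    def test_equals_naive_checker_on_random_pairs(self, signatures):
        """Oracle equivalence against an independent per-position loop."""
        rng = np.random.default_rng(31)
        sigs = list(signatures)
        for _ in range(1000):
            flank_len = int(rng.integers(0, 13))
            seg = hx.AnalysisSegment(
                hd=random_residues(rng, 60), cflank=random_residues(rng, flank_len)
            )
            sig = sigs[int(rng.integers(len(sigs)))]
            expected = []
            full = seg.hd + seg.cflank
            for pos, allowed in sig.constraints:
                if pos <= len(full) and full[pos - 1] in allowed and full[pos - 1] != "X":
                    expected.append(pos)
            m = hx.match_signature(seg, sig)
            assert m.matched_positions == tuple(expected)
            assert m.n_matched == len(expected)

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_breaking_a_matched_position_never_raises_count(self, signatures, seed):
        rng = np.random.default_rng(seed)
        seg = hx.AnalysisSegment(
            hd=random_residues(rng, 60), cflank=random_residues(rng, 12)
        )
        sig = list(signatures)[seed % len(signatures)]
        m = hx.match_signature(seg, sig)
        if not m.matched_positions:
            return
        pos = m.matched_positions[int(rng.integers(len(m.matched_positions)))]
        allowed = sig.allowed_at(pos)
        bad = next(a for a in "ACDEFGHIKLMNPQRSTVWY" if a not in allowed)
        residues = list(seg.hd + seg.cflank)
        residues[pos - 1] = bad
        mutated = hx.AnalysisSegment(
            hd="".join(residues[:60]), cflank="".join(residues[60:])
        )
        assert hx.match_signature(mutated, sig).n_matched == m.n_matched - 1


class TestScoreClass:
    def test_full_central_match_scores_one(self, signatures):
        seg = make_segment(
            p6="Q", p26="L", p27="T", p28="R", p29="R", p30="R", p31="R", p59="E"
        )
        assert hx.score_class(seg, hx.get_signature("central_class", signatures)) == 1.0

    def test_two_of_five_posterior_scores_point_four(self, signatures):
        seg = make_segment(p3="K", p20="Y")
        assert hx.score_class(seg, hx.get_signature("posterior_class", signatures)) == 0.4

    def test_flank_signature_on_empty_flank_scores_zero(self, signatures):
        flank_only = hx.SignatureDef(
            name="flank_only",
            constraints=((63, frozenset("K")), (64, frozenset("S"))),
            kind="diagnostic_class",
        )
        assert hx.score_class(make_segment(cflank=""), flank_only) == 0.0

    def test_wrong_kind_rejected(self, signatures):
        with pytest.raises(hx.DataError, match="diagnostic_class"):
            hx.score_class(make_segment(), hx.get_signature("lox5_parapeptide", signatures))


class TestTableIO:
    def test_roundtrip_is_identity(self, signatures):
        text = format_signature_table(signatures)
        back = parse_signature_table(text)
        assert back == list(signatures)

    def test_malformed_line_reports_position(self):
        with pytest.raises(hx.DataError, match=":2"):
            parse_signature_table("sig\t5\tK\nsig\tfive\tK\n")

    def test_position_out_of_range_rejected(self):
        with pytest.raises(hx.DataError, match="73"):
            parse_signature_table("sig\t73\tK\n")
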