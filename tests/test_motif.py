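"""Consensus model, mismatch scoring, scanning, and divergent assignment.

The scanning oracle here is deliberately independent of the package: a
literal per-position allowed-set table and a python loop over every 14-mer
on both strands.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nnrr_regulon.genome import Gene, GenomeAnnotation, reverse_complement
from nnrr_regulon.motif import (MotifHit, MotifModel, assign_divergent,
                                best_hit, mismatch_count, scan_promoter)
from nnrr_regulon.units import PromoterWindow, group_units, promoter_window

# independent oracle: TTGA/C-N6-T/GCAA, Hamming on constrained positions
ORACLE_ALLOWED = ["T", "T", "G", "AC",
                  "ACGT", "ACGT", "ACGT", "ACGT", "ACGT", "ACGT",
                  "TG", "C", "A", "A"]
_COMP = dict(zip("ACGTN", "TGCAN"))


def oracle_mm(w14: str) -> int:
    return sum(b not in allowed for b, allowed in zip(w14, ORACLE_ALLOWED))


def oracle_revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def oracle_scan(seq: str, max_mm: int) -> dict[int, int]:
    """position-offset -> best mismatch count over both strands."""
    out = {}
    L = len(seq)
    for i in range(L - 13):
        w = seq[i:i + 14]
        mm = min(oracle_mm(w), oracle_mm(oracle_revcomp(w)))
        if mm <= max_mm:
            out[i - L] = mm
    return out


def window_of(seq: str) -> PromoterWindow:
    return PromoterWindow(unit_id="u", sequence=seq, strand="+",
                          anchor=len(seq) + 1, replicon_length=len(seq) + 100)


class TestMotifModel:
    def test_width_and_constrained_positions(self):
        m = MotifModel()
        assert m.width == 14
        assert m.constrained_positions == (1, 2, 3, 4, 11, 12, 13, 14)
        assert m.allowed[3] == frozenset("AC")
        assert m.allowed[10] == frozenset("TG")

    def test_model_is_its_own_reverse_complement(self):
        assert MotifModel().is_palindromic()


class TestMismatchCount:
    @pytest.mark.parametrize("w14,expected", [
        ("TTGATTTTTTTCAA", 0),   # literal consensus instance
        ("TTGATCCAGCGCAA", 0),   # nosR promoter box
        ("TCGGGCCGGCTCAA", 2),   # positions 2 and 4 deviate
        ("TTGCTGCGGAGCAG", 1),   # position 14 deviates
        ("AAAAAAAAAAAAAA", 5),   # poly-A: positions 1,2,3,11,12 deviate
    ])
    def test_against_positionwise_oracle(self, w14, expected):
        assert oracle_mm(w14) == expected  # oracle agrees with hand count
        assert mismatch_count(w14) == expected

    def test_spacer_positions_never_contribute(self):
        base = "TTGA" + "ACGTAC" + "TCAA"
        for spacer in ("AAAAAA", "GGGGGG", "TCTCTC"):
            assert mismatch_count("TTGA" + spacer + "TCAA") == 0

    def test_ambiguous_base_counts_as_mismatch_by_default(self):
        assert mismatch_count("TTGANNNNNNTCAA") == 0  # N only in spacer
        assert mismatch_count("NTGATTTTTTTCAA") == 1

    def test_ambiguous_base_tolerated_when_configured(self):
        lenient = MotifModel(ambiguous_is_mismatch=False)
        assert mismatch_count("NTGATTTTTTTCAA", lenient) == 0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="14 bases"):
            mismatch_count("TTGA")

    @given(st.text(alphabet="ACGT", min_size=14, max_size=14))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_palindromic_strand_symmetry(self, w14):
        assert mismatch_count(w14) == mismatch_count(reverse_complement(w14))


class TestScanPromoter:
    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_equals_bruteforce_on_random_windows(self, max_mm):
        rng = np.random.default_rng(11)
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGT"), size=100))
            hits = scan_promoter(window_of(seq), max_mm=max_mm)
            got = {h.position: h.mismatches for h in hits}
            assert got == oracle_scan(seq, max_mm)

    def test_planted_perfect_box_found_exactly(self):
        """A perfect box 86 bp upstream -> single hit at -86, 0 mismatches."""
        seq = ["A"] * 200
        box = "TTGATCCAGCGCAA"
        # 5'-most base at offset -86 => index L - 86
        seq[200 - 86:200 - 86 + 14] = list(box)
        hits = scan_promoter(window_of("".join(seq)), max_mm=2)
        exact = [h for h in hits if h.mismatches == 0]
        assert len(exact) == 1
        assert exact[0].position == -86
        assert exact[0].sequence_14mer == box

    def test_reverse_complemented_window_same_mismatch_multiset(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=150))
        hits = scan_promoter(window_of(seq), max_mm=2)
        hits_rc = scan_promoter(window_of(reverse_complement(seq)), max_mm=2)
        assert sorted(h.mismatches for h in hits) \
            == sorted(h.mismatches for h in hits_rc)

    def test_short_window_returns_empty(self):
        assert scan_promoter(window_of("ACGTACGTACGTA")) == []

    def test_random_hit_rate_matches_poisson_expectation(self):
        """Perfect-box rate on uniform sequence: (L-13)/(4^6 * 2^2) hits.

        Six fixed consensus bases contribute (1/4) each and the two
        two-letter positions (1/2) each; the palindrome makes the two
        strands report the same positions, so there is no factor 2.
        """
        rng = np.random.default_rng(31)
        L = 1_000_000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        hits = scan_promoter(window_of(seq), max_mm=0)
        lam = (L - 13) * (1 / 4) ** 6 * (1 / 2) ** 2
        assert abs(len(hits) - lam) <= 3 * np.sqrt(lam)

    def test_hits_sorted_by_mismatch_then_distance(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        hits = scan_promoter(window_of(seq), max_mm=2)
        keys = [(h.mismatches, abs(h.position)) for h in hits]
        assert keys == sorted(keys)


class TestBestHit:
    def _hit(self, pos, mm, strand="same"):
        return MotifHit("u", pos, strand, "TTGATTTTTTTCAA", mm)

    def test_fewest_mismatches_wins(self):
        assert best_hit([self._hit(-300, 1), self._hit(-86, 0)]).position \
            == -86

    def test_tie_broken_by_distance(self):
        assert best_hit([self._hit(-250, 1), self._hit(-100, 1)]).position \
            == -100

    def test_tie_broken_by_strand(self):
        got = best_hit([self._hit(-100, 1, "opposite"),
                        self._hit(-100, 1, "same")])
        assert got.strand_of_hit == "same"

    def test_empty_returns_none(self):
        assert best_hit([]) is None


class TestAssignDivergent:
    def _layout(self, gap=300, f_offset=120):
        """'-' gene at 1000..1600, '+' gene after *gap* bp intergenic."""
        e = 1600
        s = e + gap + 1
        ann = GenomeAnnotation("r", 5000, [
            Gene("left", 1000, e, "-"), Gene("right", s, s + 500, "+")])
        units = {u.unit_id: u for u in group_units(ann, {"left", "right"})}
        box = MotifHit("right", -f_offset, "same", "TTGATCCAGCGCAA", 0)
        return ann, units["right"], units["left"], box, gap

    def test_both_records_upstream_and_sum_rule(self):
        """Positions sum to -(intergenic length + motif width)."""
        ann, u_fwd, u_rev, box, gap = self._layout()
        h_fwd, h_rev = assign_divergent(box, u_fwd, u_rev, ann)
        assert h_fwd.position < 0 and h_rev.position < 0
        assert h_fwd.position + h_rev.position == -(gap + 14)
        assert h_rev.sequence_14mer \
            == reverse_complement(h_fwd.sequence_14mer)

    @pytest.mark.parametrize("f_offset", [20, 100, 200, 290])
    def test_coordinate_oracle_on_toy_layout(self, f_offset):
        ann, u_fwd, u_rev, _, gap = self._layout(f_offset=f_offset)
        box = MotifHit("right", -f_offset, "same", "TTGATCCAGCGCAA", 0)
        h_fwd, h_rev = assign_divergent(box, u_fwd, u_rev, ann)
        # oracle: forward coordinate of the box, re-expressed for the '-' unit
        s, e = ann["right"].start, ann["left"].end
        f = s - f_offset
        assert h_rev.position == e - (f + 13)

    def test_box_outside_intergenic_refused(self):
        ann, u_fwd, u_rev, _, _ = self._layout(gap=300)
        box = MotifHit("right", -400, "same", "TTGATCCAGCGCAA", 0)
        with pytest.raises(ValueError, match="intergenic"):
            assign_divergent(box, u_fwd, u_rev, ann)

    def test_tandem_neighbors_refused(self):
        ann = GenomeAnnotation("r", 5000, [
            Gene("a", 1000, 1600, "+"), Gene("b", 1901, 2400, "+")])
        units = {u.unit_id: u for u in group_units(ann, {"a", "b"},
                                                   max_gap=100)}
        box = MotifHit("b", -100, "same", "TTGATCCAGCGCAA", 0)
        with pytest.raises(ValueError, match="strand"):
            assign_divergent(box, units["b"], units["a"], ann)
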