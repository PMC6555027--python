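"""Variant normalization, primitive decomposition and call-set comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from majorref.comparator import (
    ALLELE,
    POSITION,
    CallRecord,
    RefMismatchError,
    SortRequiredError,
    compare_sets,
    compute_fp_fn,
    decompose_primitives,
    filter_calls,
    normalize_variant,
)

from oracles import edit_distance, primitive_cost


def rec(pos, ref, alt, chrom="c", qual=50.0, dp=30):
    return CallRecord(chrom, pos, ref, alt, qual, dp)


@pytest.mark.parametrize("qual,dp,kept", [
    (11, 4, True),
    (10, 9, False),   # QUAL strict
    (30, 3, False),   # DP strict
    (None, 9, False),
    (30, None, False),
])
def test_filter_strictness(qual, dp, kept):
    r = CallRecord("c", 5, "A", "G", qual, dp)
    assert (filter_calls([r]) == [r]) is kept


class TestNormalize:
    GENOME = {"c": "GGGTTTT"}

    def test_minimal_snp_unchanged(self):
        g = {"c": "ACGTACG"}
        r = normalize_variant(g, rec(3, "G", "A"))
        assert (r.pos, r.ref, r.alt) == (3, "G", "A")

    def test_homopolymer_deletion_left_aligned(self):
        r = normalize_variant(self.GENOME, rec(4, "TT", "T"))
        assert (r.pos, r.ref, r.alt) == (3, "GT", "G")

    def test_mnp_core_extracted(self):
        g = {"c": "AAAACATGG"}
        r = normalize_variant(g, rec(5, "CAT", "CGT"))
        assert (r.pos, r.ref, r.alt) == (6, "A", "G")

    def test_idempotent(self):
        for raw in (rec(4, "TT", "T"), rec(2, "GGT", "GT"),
                    rec(5, "TTT", "TT")):
            once = normalize_variant(self.GENOME, raw)
            again = normalize_variant(self.GENOME, once)
            assert once == again

    def test_exhaustive_left_shift_oracle(self):
        """The normalized record is haplotype-equivalent and leftmost."""
        genome = {"c": "GGGTTTTACACACGG"}
        seq = genome["c"]
        raw = rec(9, "CAC", "C")  # a 2 bp deletion inside the ACAC repeat
        r = normalize_variant(genome, raw)
        assert (r.pos, r.ref, r.alt) == (7, "TAC", "T")

        def apply(v):
            return seq[:v.pos - 1] + v.alt + seq[v.pos - 1 + len(v.ref):]

        assert apply(r) == apply(raw)
        # oracle: no equivalent 2 bp deletion can be placed further left
        for p in range(1, r.pos):
            cand = rec(p, seq[p - 1:p + 2], seq[p - 1])
            assert apply(cand) != apply(raw)

    def test_ref_mismatch(self):
        with pytest.raises(RefMismatchError):
            normalize_variant(self.GENOME, rec(1, "T", "A"))


class TestDecompose:
    def test_mnp_to_snps(self):
        out = decompose_primitives(rec(5, "AT", "GC"))
        assert [(r.pos, r.ref, r.alt) for r in out] == \
            [(5, "A", "G"), (6, "T", "C")]

    def test_simple_records_pass_through(self):
        for r in (rec(5, "A", "G"), rec(5, "AT", "A"), rec(5, "A", "ACC")):
            assert decompose_primitives(r) == [r]

    def test_complex_substitution_conserves_cost(self):
        out = decompose_primitives(rec(5, "ACG", "TG"))
        assert primitive_cost(out) == edit_distance("ACG", "TG") == 2
        classes = sorted(r.vclass for r in out)
        assert classes == ["INDEL", "SNP"]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=20),
           st.text(alphabet="ACGT", min_size=2, max_size=20))
    def test_cost_conservation_property(self, ref, alt):
        if ref == alt or len(ref) == len(alt):
            return
        out = decompose_primitives(rec(50, ref, alt))
        assert primitive_cost(out) == edit_distance(ref, alt)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=20),
           st.text(alphabet="ACGT", min_size=1, max_size=20))
    def test_primitives_reconstruct_haplotype(self, ref, alt):
        """Applying all primitives simultaneously against the original
        reference coordinates reproduces REF -> ALT.  An INDEL's anchor
        base may coincide with a SNP, so substitutions, deletions and
        insertions are applied as independent per-base operations."""
        if ref == alt:
            return
        out = decompose_primitives(rec(1, ref, alt))
        chars = list(ref)
        before = [""] * (len(ref) + 1)  # insertions before base i
        after = [""] * len(ref)
        for r in out:
            s = r.pos - 1
            if len(r.ref) == len(r.alt) == 1:
                assert ref[s] == r.ref
                chars[s] = r.alt
            elif len(r.alt) < len(r.ref):  # deletion
                if r.ref[0] == r.alt:      # prefix-anchored
                    for k in range(s + 1, s + len(r.ref)):
                        chars[k] = ""
                else:                       # suffix-anchored (leading gap)
                    assert r.ref[-1] == r.alt
                    for k in range(s, s + len(r.ref) - 1):
                        chars[k] = ""
            else:                           # insertion
                if r.alt[0] == r.ref:      # prefix-anchored
                    after[s] += r.alt[1:]
                else:                       # suffix-anchored
                    assert r.alt[-1] == r.ref
                    before[s] += r.alt[:-1]
        hap = "".join(
            before[i] + chars[i] + after[i] for i in range(len(ref))
        ) + before[len(ref)]
        assert hap == alt


class TestCompareSets:
    def test_worked_example(self):
        a = [rec(5, "A", "G", "1"), rec(10, "AT", "A", "1"),
             rec(7, "C", "T", "2")]
        b = [rec(5, "G", "A", "1"), rec(7, "C", "T", "2"),
             rec(30, "A", "AGG", "2")]
        rep = compare_sets(a, b)
        tot = {k: sum(getattr(c, k) for c in rep.per_class.values())
               for k in ("total_a", "total_b", "common", "unique_a",
                         "unique_b")}
        assert tot == {"total_a": 3, "total_b": 3, "common": 2,
                       "unique_a": 1, "unique_b": 1}
        fp, fn = compute_fp_fn(tot["total_a"], tot["unique_a"],
                               tot["total_b"], tot["unique_b"])
        assert (fp, fn) == (33.33, 33.33)

    def test_identical_sets_zero_rates(self):
        a = [rec(5, "A", "G"), rec(9, "AT", "A")]
        rep = compare_sets(a, list(a))
        for counts in rep.per_class.values():
            assert counts.unique_a == counts.unique_b == 0

    def test_swap_pair_common_in_allele_mode(self):
        a = [rec(5, "A", "G")]
        b = [rec(5, "G", "A")]
        assert compare_sets(a, b, mode=ALLELE).per_class["SNP"].common == 1

    def test_allele_mode_rejects_different_alleles(self):
        a = [rec(5, "A", "G")]
        b = [rec(5, "A", "T")]
        assert compare_sets(a, b, mode=ALLELE).per_class["SNP"].common == 0
        assert compare_sets(a, b, mode=POSITION).per_class["SNP"].common == 1

    def test_overlapping_indels_reconciled(self):
        a = [rec(10, "ATTT", "A")]
        b = [rec(11, "TTTG", "T")]
        assert compare_sets(a, b).per_class["INDEL"].common == 1

    def test_indel_window_extends_vicinity(self):
        a = [rec(10, "AT", "A")]
        b = [rec(14, "CT", "C")]
        assert compare_sets(a, b).per_class["INDEL"].common == 0
        assert compare_sets(a, b, indel_window=2) \
            .per_class["INDEL"].common == 1

    def test_one_to_one_greedy_nearest(self):
        a = [rec(10, "ATT", "A"), rec(12, "TTG", "T")]
        b = [rec(11, "TTG", "T")]
        counts = compare_sets(a, b).per_class["INDEL"]
        assert (counts.common, counts.unique_a, counts.unique_b) == (1, 1, 0)

    def test_symmetry(self, scenario):
        fwd = compare_sets(scenario.callset_a, scenario.callset_b)
        rev = compare_sets(scenario.callset_b, scenario.callset_a)
        for cls in fwd.per_class:
            f, r = fwd.per_class[cls], rev.per_class[cls]
            assert (f.common, f.unique_a, f.unique_b) == \
                (r.common, r.unique_b, r.unique_a)

    def test_unsorted_input_rejected(self):
        a = [rec(9, "A", "G"), rec(5, "C", "T")]
        with pytest.raises(SortRequiredError):
            compare_sets(a, [])

    @pytest.mark.parametrize("mode", [POSITION, ALLELE])
    def test_planted_truth_recovered(self, scenario, mode):
        rep = compare_sets(scenario.callset_a, scenario.callset_b,
                           mode=mode)
        truth = scenario.callset_truth
        for cls in ("SNP", "INDEL"):
            counts = rep.per_class[cls]
            assert counts.common == truth.common[cls]
            assert counts.unique_a == truth.unique_a[cls]
            assert counts.unique_b == truth.unique_b[cls]


class TestComputeFpFn:
    def test_wgs_indel_row(self):
        assert compute_fp_fn(809_628, 20_014, 807_394, 17_782) == \
            (2.47, 2.20)

    def test_wes_indel_row_three_decimals(self):
        assert compute_fp_fn(4251, 60, 4245, 54, decimals=3) == \
            (1.411, 1.272)

    def test_zero_unique(self):
        assert compute_fp_fn(100, 0, 100, 0) == (0.0, 0.0)

    def test_zero_total_is_na(self):
        assert compute_fp_fn(0, 0, 10, 1) == (None, 10.0)


def test_prepare_calls_pipeline(scenario):
    from majorref.comparator import prepare_calls

    out = feed = prepare_calls(scenario.callset_a, scenario.genome)
    keys = [(r.chrom, r.pos) for r in out]
    assert keys == sorted(keys)
    for r in feed:
        # normalized minimality
        if len(r.ref) > 1 and len(r.alt) > 1:
            assert r.ref[0] != r.alt[0] and r.ref[-1] != r.alt[-1]
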