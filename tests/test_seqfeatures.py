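import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import oracle_complement_lengths, oracle_ssrs
from orphanlc.seqfeatures import (
    CodonUsageTable,
    cai,
    default_codon_usage,
    find_ssrs,
    gc_content,
    intergenic_lengths,
    ssr_fraction_of_cds,
    windowed_features,
)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ATGCN", 0.5)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")
        with pytest.raises(ValueError):
            gc_content("")


class TestCai:
    def test_optimal_codons_give_one(self):
        usage = default_codon_usage()
        cds = "".join(c for c, w in sorted(usage.w.items()) if w == 1.0)
        assert cai(cds, usage) == pytest.approx(1.0)

    def test_geometric_mean_by_hand(self):
        # two-codon family: GGG preferred (w=1), GGA rare (w=0.25)
        usage = CodonUsageTable({"GGG": 0.08, "GGA": 0.02})
        assert cai("GGAGGG", usage) == pytest.approx(np.sqrt(0.25 * 1.0))

    def test_single_codon_families_excluded(self):
        usage = default_codon_usage()
        base = "GGAGGG"
        assert cai(base + "ATG", usage) == pytest.approx(cai(base, usage))
        assert cai("TGG" + base, usage) == pytest.approx(cai(base, usage))

    def test_higher_w_synonym_increases_cai(self):
        usage = default_codon_usage()
        fam = sorted(
            [c for c in usage.w if c.startswith("GC")], key=usage.w.get
        )
        low, high = fam[0], fam[-1]
        base = "GGAAAA"
        assert cai(base + high, usage) > cai(base + low, usage)

    def test_frame_violation(self):
        with pytest.raises(ValueError):
            cai("ATGA", default_codon_usage())


class TestFindSsrs:
    def test_sixteen_bp_dinucleotide(self):
        (hit,) = find_ssrs("AC" * 8)
        assert (hit.motif, hit.repeat_count, hit.length) == ("AC", 8, 16)

    def test_fourteen_bp_below_threshold(self):
        assert find_ssrs("AC" * 7) == []

    def test_primitive_motif_reported(self):
        (hit,) = find_ssrs("ACAC" * 4)
        assert hit.motif == "AC" and hit.repeat_count == 8

    def test_homopolymer(self):
        (hit,) = find_ssrs("A" * 20)
        assert hit.motif == "A" and hit.repeat_count == 20

    def test_matches_enumeration_oracle(self, rng):
        """Scanner equals exhaustive (start, motif) enumeration on random
        sequences with planted repeats."""
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            motif = ["A", "AT", "CAG"][rng.integers(0, 3)]
            planted = motif * (24 // len(motif))
            p = int(rng.integers(0, 350))
            seq = seq[:p] + planted + seq[p:]
            mine = [
                (h.motif, h.start, h.end, h.repeat_count) for h in find_ssrs(seq)
            ]
            assert mine == oracle_ssrs(seq)


class TestSsrFraction:
    def test_fraction(self):
        cds = "AC" * 8 + "G" * 144
        assert ssr_fraction_of_cds(cds, find_ssrs("AC" * 8)) == pytest.approx(
            0.1
        )

    def test_no_hits(self):
        assert ssr_fraction_of_cds("ACGT" * 10, []) == 0.0

    def test_out_of_bounds_hit(self):
        with pytest.raises(ValueError):
            ssr_fraction_of_cds("ACGT", find_ssrs("A" * 20))


class TestWindowedFeatures:
    def test_partial_window_dropped(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2500))
        wins = windowed_features({"chr1": seq}, window=1000)
        assert [(w.start, w.end) for w in wins] == [(0, 1000), (1000, 2000)]

    def test_homopolymer_gc_zero(self):
        wins = windowed_features({"chr1": "A" * 2000}, window=1000)
        assert all(w.gc == 0 for w in wins)

    def test_planted_ssr_density_localised(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        seq = seq[:100] + "AG" * 20 + seq[140:]
        wins = windowed_features({"chr1": seq}, window=1000)
        assert wins[0].ssr_density > 0
        assert wins[0].ssr_density >= max(w.ssr_density for w in wins[1:])

    def test_short_sequence_empty(self):
        assert windowed_features({"c": "ACGT" * 100}, window=1000) == []

    def test_window_floor(self):
        with pytest.raises(ValueError):
            windowed_features({"c": "A" * 5000}, window=500)


class TestIntergenicLengths:
    def test_two_genes(self):
        assert intergenic_lengths([(0, 10), (20, 30)], 40) == [10, 10]

    def test_full_coverage(self):
        assert intergenic_lengths([(0, 40)], 40) == []

    def test_overlaps_unioned_and_clipped(self):
        assert intergenic_lengths([(-5, 12), (8, 20)], 30) == [10]

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=999),
                st.integers(min_value=0, max_value=999),
            ).map(lambda t: (min(t), max(t))),
            max_size=15,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_matches_per_base_oracle(self, intervals):
        assert intergenic_lengths(intervals, 1000) == oracle_complement_lengths(
            intervals, 1000
        )

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=500),
                st.integers(min_value=0, max_value=500),
            ).map(lambda t: (min(t), max(t))),
            max_size=10,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_length_conservation(self, intervals):
        """Intergenic lengths plus unioned gene length equals chromosome
        length."""
        chrom = 500
        inter = sum(intergenic_lengths(intervals, chrom))
        base = np.zeros(chrom, dtype=bool)
        for s, e in intervals:
            base[s:e] = True
        assert inter + int(base.sum()) == chrom
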