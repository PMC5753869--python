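"""Effect classification, frequency spectra and the Yates chi-square."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivescan.coding import (
    CdsSegment,
    CodingAnnotation,
    assign_frequency_class,
    classify_snp_effect,
    frequency_class_bounds,
    ns_s_spectrum,
    site_frequency_counts,
    yates_chi_square,
)

# the standard nuclear genetic code, frozen here as the independent oracle
ORACLE_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


class TestEffectClassifier:
    def test_third_position_lys_codon_is_synonymous(self):
        # AAA -> AAG : Lys -> Lys
        ref = "TT" + "AAA" + "TT"
        ann = CodingAnnotation([CdsSegment("g", 2, 5, "+")])
        assert classify_snp_effect(5, "A", "G", ann, ref) == "synonymous"

    def test_first_position_lys_to_glu_is_nonsynonymous(self):
        ref = "TT" + "AAA" + "TT"
        ann = CodingAnnotation([CdsSegment("g", 2, 5, "+")])
        assert classify_snp_effect(3, "A", "G", ann, ref) == "nonsynonymous"

    def test_minus_strand_leu_codon_synonymous(self):
        # coding TTA (Leu); genomic carries its reverse complement TAA;
        # genomic A->G at the last codon base reads T->C on the coding strand
        # giving CTA (Leu)
        ref = "GG" + revcomp("TTA") + "GG"
        ann = CodingAnnotation([CdsSegment("g", 2, 5, "-")])
        # coding-strand position of T (codon index 0) is genomic index 4
        assert classify_snp_effect(5, "A", "G", ann, ref) == "synonymous"

    def test_noncoding_position(self):
        ref = "TTAAATT"
        ann = CodingAnnotation([CdsSegment("g", 2, 5, "+")])
        assert classify_snp_effect(1, "T", "C", ann, ref) == "noncoding"

    def test_ref_mismatch_is_an_error(self):
        ref = "TTAAATT"
        ann = CodingAnnotation([CdsSegment("g", 2, 5, "+")])
        with pytest.raises(ValueError, match="position 3"):
            classify_snp_effect(3, "C", "G", ann, ref)

    def test_exhaustive_codon_enumeration_both_strands(self):
        """Agreement with the frozen codon table over all 64 x 9 single-base
        changes, plus- and minus-strand."""
        bases = "ACGT"
        n_checked = 0
        for c0 in bases:
            for c1 in bases:
                for c2 in bases:
                    codon = c0 + c1 + c2
                    for strand in "+-":
                        genomic = codon if strand == "+" else revcomp(codon)
                        ref = "CC" + genomic + "CC"
                        ann = CodingAnnotation([CdsSegment("g", 2, 5, strand)])
                        for ci in range(3):
                            gpos0 = 2 + ci if strand == "+" else 4 - ci
                            ref_base = ref[gpos0]
                            for alt_base in bases.replace(ref_base, ""):
                                got = classify_snp_effect(
                                    gpos0 + 1, ref_base, alt_base, ann, ref
                                )
                                alt_codon = (
                                    codon[:ci]
                                    + (alt_base if strand == "+" else COMP[alt_base])
                                    + codon[ci + 1:]
                                )
                                expected = (
                                    "synonymous"
                                    if ORACLE_CODE[codon] == ORACLE_CODE[alt_codon]
                                    else "nonsynonymous"
                                )
                                assert got == expected, (codon, strand, ci, alt_base)
                                n_checked += 1
        assert n_checked == 64 * 9 * 2

    def test_multi_transcript_overlap_is_ns_if_ns_in_any(self):
        # same site synonymous on the plus-strand gene, nonsynonymous on a
        # second, frame-shifted plus-strand gene
        ref = "AAAAAAGAA"
        ann = CodingAnnotation(
            [CdsSegment("g1", 0, 6, "+"), CdsSegment("g2", 2, 8, "+")]
        )
        # pos 6 (1-based): third base of AAA in g1 (syn A->G would be...) use A->C
        eff = classify_snp_effect(6, "A", "C", ann, ref)
        assert eff == "nonsynonymous"

    def test_gff3_round_trip(self, tmp_path, small_run):
        ann = small_run.annotation
        path = tmp_path / "ann.gff3"
        ann.write_gff3(path, chrom_length=small_run.config.chrom_length)
        again = CodingAnnotation.from_gff3(path)
        assert len(again) == len(ann)
        s0, s1 = ann.segments[0], again.segments[0]
        assert (s0.start, s0.end, s0.strand, s0.gene_id) == (s1.start, s1.end, s1.strand, s1.gene_id)


class TestFrequencyClasses:
    def test_het_counts_once_hom_counts_twice(self):
        gt = np.array([1, 1, 1, 2, 2, 0, -1])
        assert site_frequency_counts(gt, list(range(7))) == 7

    def test_absent_from_group_counts_zero(self):
        gt = np.array([0, 0, -1])
        assert site_frequency_counts(gt, [0, 1, 2]) == 0

    def test_all_hom_equals_chromosome_count(self):
        gt = np.full(12, 2)
        assert site_frequency_counts(gt, list(range(12))) == 24

    def test_quartile_bounds_24_chromosomes(self):
        assert frequency_class_bounds(24) == [(1, 6), (7, 12), (13, 18), (19, 24)]
        assert frequency_class_bounds(16) == [(1, 4), (5, 8), (9, 12), (13, 16)]
        assert frequency_class_bounds(4) == [(1, 1), (2, 2), (3, 3), (4, 4)]

    def test_count_7_of_24_is_class_2(self):
        assert assign_frequency_class(7, 24) == 2

    def test_fixed_pseudo_driver_count_is_class_4(self):
        assert assign_frequency_class(4, 4) == 4

    def test_count_above_n_chromosomes_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            assign_frequency_class(25, 24)

    def test_non_quartile_n_requires_explicit_bounds(self):
        with pytest.raises(ValueError, match="divisible"):
            frequency_class_bounds(10)
        assert assign_frequency_class(9, 10, bounds=[(1, 5), (6, 10)]) == 2


class TestSpectrum:
    def test_ratio_and_conservation(self):
        effects = ["nonsynonymous"] * 6 + ["synonymous"] * 3 + ["noncoding"] * 4
        counts = [4] * 9 + [1] * 4
        sp = ns_s_spectrum(effects, counts, 4)
        assert sp.ratio(4) == pytest.approx(2.0)
        # conservation: total tallies equal the number of coding SNPs observed
        assert sp.ns.sum() + sp.s.sum() == 9

    def test_stratum_filtering(self):
        effects = ["synonymous", "synonymous", "nonsynonymous"]
        counts = [2, 2, 2]
        strata = ["C", "A", "C"]
        sp = ns_s_spectrum(effects, counts, 4, strata=strata, stratum="C")
        assert sp.ns.sum() == 1 and sp.s.sum() == 1

    def test_zero_count_sites_ignored(self):
        sp = ns_s_spectrum(["synonymous"], [0], 4)
        assert sp.s.sum() == 0


def chi2_tail_oracle(x: float) -> float:
    """Survival function of chi-square(1): erfc(sqrt(x/2))."""
    return math.erfc(math.sqrt(x / 2.0))


class TestYates:
    def test_balanced_table_statistic_zero(self):
        stat, p = yates_chi_square([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_textbook_table(self):
        # E = 20 in every cell, |O-E| = 10 -> 4 * 9.5^2 / 20 = 18.05
        stat, p = yates_chi_square([[30, 10], [10, 30]])
        assert stat == pytest.approx(18.05)
        assert p == pytest.approx(chi2_tail_oracle(18.05), abs=1e-12)

    def test_clamp_when_correction_exceeds_deviation(self):
        # |O-E| = 0.5 in every cell -> corrected terms clamp to zero
        stat, p = yates_chi_square([[1, 0], [0, 1]])
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            yates_chi_square([[0, 0], [5, 5]])

    def test_negative_cell_is_an_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            yates_chi_square([[-1, 2], [3, 4]])

    @pytest.mark.parametrize(
        "table",
        [
            [[12, 7], [5, 21]], [[100, 1], [1, 100]], [[3, 3], [3, 4]],
            [[50, 60], [70, 20]], [[2, 9], [11, 4]], [[8, 8], [9, 7]],
            [[1, 2], [3, 4]], [[40, 2], [2, 40]], [[15, 0], [3, 12]],
            [[7, 13], [13, 7]], [[33, 44], [55, 22]], [[5, 5], [5, 6]],
            [[0, 10], [10, 0]], [[6, 1], [1, 6]], [[25, 25], [24, 26]],
            [[9, 2], [2, 9]], [[18, 3], [4, 17]], [[60, 40], [35, 65]],
            [[2, 2], [2, 3]], [[14, 6], [7, 13]],
        ],
    )
    def test_statistic_matches_hand_formula_and_tail_oracle(self, table):
        obs = np.asarray(table, dtype=float)
        rows, cols, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(rows, cols) / n
        manual = sum(
            max(abs(obs[i, j] - expected[i, j]) - 0.5, 0.0) ** 2 / expected[i, j]
            for i in range(2)
            for j in range(2)
        )
        stat, p = yates_chi_square(table)
        assert stat == pytest.approx(manual, abs=1e-12)
        assert p == pytest.approx(chi2_tail_oracle(stat), abs=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=200), min_size=4, max_size=4))
    def test_agrees_with_scipy_when_correction_does_not_clamp(self, cells):
        """Where |O-E| >= 0.5 everywhere, the clamp rule coincides with
        scipy's sign-shift continuity correction."""
        from scipy.stats import chi2_contingency

        obs = np.array(cells, dtype=float).reshape(2, 2)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        if np.any(np.abs(obs - expected) < 0.5):
            return
        stat, p = yates_chi_square(obs)
        res = chi2_contingency(obs, correction=True)
        assert stat == pytest.approx(res.statistic, rel=1e-12)
        assert p == pytest.approx(res.pvalue, rel=1e-9)
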