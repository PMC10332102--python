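"""NG86 site/difference counting, Ka/Ks, homolog-pair filters."""

from itertools import permutations

import numpy as np
import pytest
from Bio.Data import CodonTable
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from familyscope.io_formats import NUCLEOTIDE, SequenceSet
from familyscope.selection_analysis import (
    SENSE_CODONS,
    alignment_identity,
    classify_selection,
    codon_align,
    compute_kaks,
    count_differences,
    count_sites,
    find_homolog_pairs,
)
from familyscope.synthetic_data import evolve_pair, random_cds, reverse_translate

_ORACLE_TABLE = CodonTable.unambiguous_dna_by_id[1]
_ORACLE_STOPS = set(_ORACLE_TABLE.stop_codons)


def oracle_translate(codon):
    return str(Seq(codon).translate())


def oracle_sites(codon):
    """Independent per-codon site count via Biopython translation."""
    syn = 0.0
    for pos in range(3):
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1 :]
            if mutant not in _ORACLE_STOPS and oracle_translate(
                mutant
            ) == oracle_translate(codon):
                syn += 1 / 3
    return 3 - syn, syn


def oracle_differences(codon_a, codon_b):
    """Explicit pathway enumeration with stop-path exclusion."""
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    unrestricted = []
    for order in permutations(positions):
        cur, nd, sd, blocked = codon_a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _ORACLE_STOPS:
                blocked = True
            if oracle_translate(cur) == oracle_translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        unrestricted.append((nd, sd))
        if not blocked:
            results.append((nd, sd))
    pool = results or unrestricted
    return (
        sum(r[0] for r in pool) / len(pool),
        sum(r[1] for r in pool) / len(pool),
    )


class TestSiteCounting:
    @pytest.mark.parametrize(
        "codon,s_sites",
        [("ATG", 0.0), ("TTT", 1 / 3), ("GGG", 1.0), ("TGG", 0.0)],
    )
    def test_enumerated_examples(self, codon, s_sites):
        n, s = count_sites(codon)
        assert s == pytest.approx(s_sites)
        assert n + s == pytest.approx(3.0)

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert count_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            count_sites("TAA")


class TestDifferenceCounting:
    def test_identical_codons(self):
        assert count_differences("TTT", "TTT")[:2] == (0.0, 0.0)

    def test_single_synonymous_step(self):
        nd, sd, blocked = count_differences("TTT", "TTC")
        assert (nd, sd) == (0.0, 1.0) and not blocked

    def test_two_difference_pathway_average(self):
        nd, sd, _ = count_differences("TTT", "GTC")
        assert (nd, sd) == pytest.approx(oracle_differences("TTT", "GTC"))

    def test_random_codon_pairs_match_pathway_oracle(self):
        rng = np.random.default_rng(6)
        codons = list(SENSE_CODONS)
        for _ in range(300):
            a = codons[rng.integers(len(codons))]
            b = codons[rng.integers(len(codons))]
            nd, sd, _ = count_differences(a, b)
            ond, osd = oracle_differences(a, b)
            assert nd == pytest.approx(ond) and sd == pytest.approx(osd)
            k = sum(x != y for x, y in zip(a, b))
            assert nd + sd == pytest.approx(k)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(a=st.sampled_from(SENSE_CODONS), b=st.sampled_from(SENSE_CODONS))
def test_difference_counts_sum_to_hamming_distance(a, b):
    """nd + sd always equals the number of differing codon positions."""
    nd, sd, _ = count_differences(a, b)
    assert nd + sd == pytest.approx(sum(x != y for x, y in zip(a, b)))
    assert nd >= 0 and sd >= 0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(codon=st.sampled_from(SENSE_CODONS))
def test_site_counts_conserve_three_sites(codon):
    n, s = count_sites(codon)
    assert 0 <= s <= 3 and n + s == pytest.approx(3.0)


class TestCodonAlign:
    def test_equal_length_gapless_pair_fully_paired(self):
        rng = np.random.default_rng(1)
        a = random_cds(rng, 40)
        assert len(codon_align(a, a)) == 40

    def test_inserted_codon_excluded_and_frame_kept(self):
        rng = np.random.default_rng(2)
        prot_a = "MKFGLW"
        prot_b = "MKFGW"  # L deleted
        a = reverse_translate(prot_a, rng)
        b = reverse_translate(prot_b, rng)
        pairs = codon_align(a, b)
        assert len(pairs) == 5
        for ca, cb in pairs:
            assert len(ca) == len(cb) == 3

    def test_ambiguous_base_column_dropped(self):
        a = "ATGAAATTTGGG"
        b = "ATGAANTTTGGG"
        assert len(codon_align(a, b)) == 3

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codon_align("ATGTAAAAA", "ATGAAAAAA")


class TestComputeKaks:
    def test_identical_sequences_zero_rates(self):
        rng = np.random.default_rng(3)
        a = random_cds(rng, 50)
        res = compute_kaks(a, a)
        assert res.ka == res.ks == 0.0
        assert res.ratio == 0.0

    def test_synonymous_only_divergence_gives_ratio_zero(self):
        a = "TTT" * 40
        b = "TTC" * 5 + "TTT" * 35  # 5 synonymous codon changes
        res = compute_kaks(a, b)
        assert res.ka == 0.0 and res.ks > 0.0
        assert res.ratio == 0.0
        assert res.selection_class == "purifying"

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a = random_cds(rng, 100)
        b, _ = evolve_pair(a, 0.5, 0.2, 5)
        r1 = compute_kaks(a, b)
        r2 = compute_kaks(b, a)
        assert r1.ka == pytest.approx(r2.ka)
        assert r1.ks == pytest.approx(r2.ks)

    def test_site_conservation_totals_three_per_codon(self):
        rng = np.random.default_rng(5)
        a = random_cds(rng, 80)
        b, _ = evolve_pair(a, 1.0, 0.2, 6)
        res = compute_kaks(a, b)
        assert res.n_sites + res.s_sites == pytest.approx(3 * res.compared_codons)

    def test_saturation_raises(self):
        a = "TTT" * 40
        b = "TTC" * 40
        with pytest.raises(ValueError, match="3/4"):
            compute_kaks(a, b)

    def test_too_few_codons_rejected(self):
        with pytest.raises(ValueError, match="30"):
            compute_kaks("ATGAAA", "ATGAAA")


class TestClassifySelection:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (1.049774, "positive"),
            (0.159517, "purifying"),
            (1.0, "neutral"),
            (0.0, "purifying"),
            (None, "undefined"),
        ],
    )
    def test_rule(self, ratio, expected):
        assert classify_selection(ratio) == expected


class TestHomologPairs:
    def test_identical_400bp_pair_is_paralog_with_identity_one(self):
        rng = np.random.default_rng(7)
        seq = random_cds(rng, 134)  # 402 bp
        pairs = find_homolog_pairs(
            SequenceSet([("a", seq), ("b", seq)], NUCLEOTIDE)
        )
        assert len(pairs) == 1
        assert pairs[0].relationship == "paralog"
        assert pairs[0].identity == pytest.approx(1.0)

    def test_short_sequences_dropped_by_length_filter(self):
        rng = np.random.default_rng(8)
        seq = random_cds(rng, 66)  # 198 bp < 300
        with pytest.warns(UserWarning):
            pairs = find_homolog_pairs(
                SequenceSet([("a", seq), ("b", seq)], NUCLEOTIDE)
            )
        assert pairs == []

    def test_unrelated_random_cds_fall_below_identity_floor(self):
        rng = np.random.default_rng(9)
        a = random_cds(rng, 200)
        b = random_cds(rng, 200)
        ident = alignment_identity(a, b)
        assert ident < 0.40
        assert find_homolog_pairs(
            SequenceSet([("a", a), ("b", b)], NUCLEOTIDE)
        ) == []

    def test_reciprocal_best_match_orthologs(self):
        rng = np.random.default_rng(10)
        anc1 = random_cds(rng, 150)
        anc2 = random_cds(rng, 150)
        der1, _ = evolve_pair(anc1, 0.5, 0.1, 11)
        der2, _ = evolve_pair(anc2, 0.5, 0.1, 12)
        set_a = SequenceSet([("a1", anc1), ("a2", anc2)], NUCLEOTIDE)
        set_b = SequenceSet([("b1", der1), ("b2", der2)], NUCLEOTIDE)
        pairs = find_homolog_pairs(set_a, set_b)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {("a1", "b1"), ("a2", "b2")}
        assert all(p.relationship == "ortholog" for p in pairs)
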