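"""Codon/codon-pair counting, RSCU and percentile ranks against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silentshift import (
    CodingSequence,
    ExpressionTable,
    GeneratorConfig,
    compute_rscu,
    count_codon_pairs,
    count_codons,
    gen_cds,
    pair_frequencies,
)
from silentshift.genetic_code import CODON_PAIRS, CODONS, SYNONYMOUS_FAMILIES


def brute_force_codon_counts(cds_set, weights=None):
    """Independent sliding-window counter over every in-frame position."""
    counts = {}
    for cds in cds_set:
        w = 1.0 if weights is None else weights[cds.id]
        for i in range(0, len(cds.seq) - 2, 3):
            codon = cds.seq[i : i + 3]
            counts[codon] = counts.get(codon, 0.0) + w
    return counts


def brute_force_pair_counts(cds_set, weights=None):
    counts = {}
    for cds in cds_set:
        w = 1.0 if weights is None else weights[cds.id]
        for i in range(0, len(cds.seq) - 5, 3):
            pair = (cds.seq[i : i + 3], cds.seq[i + 3 : i + 6])
            counts[pair] = counts.get(pair, 0.0) + w
    return counts


class TestCodingSequence:
    def test_rejects_frameshifted_and_ambiguous_sequences(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            CodingSequence("x", "ATGC")
        with pytest.raises(ValueError, match="invalid characters"):
            CodingSequence("x", "ATGNNNTAA")
        with pytest.raises(ValueError):
            CodingSequence("x", "")

    def test_codon_slicing_is_one_based(self):
        cds = CodingSequence("x", "ATGCCGTAA")
        assert cds.codons() == ["ATG", "CCG", "TAA"]
        assert cds.codon(2) == "CCG"
        with pytest.raises(IndexError):
            cds.codon(4)


class TestCountCodons:
    def test_single_cds_direct_enumeration(self):
        table = count_codons([CodingSequence("x", "ATGCCGTAA")])
        nonzero = {c: n for c, n in table.counts.items() if n}
        assert nonzero == {"ATG": 1.0, "CCG": 1.0, "TAA": 1.0}

    def test_zero_weight_annihilates_and_tpm_scales(self):
        cds = CodingSequence("a", "ATGCCGTAA")
        twin = CodingSequence("b", "ATGCCGTAA")
        weights = ExpressionTable({"a": 0.0, "b": 10.0})
        weighted = count_codons([cds, twin], weights)
        single = count_codons([cds])
        for codon in CODONS:
            assert weighted.counts[codon] == pytest.approx(10.0 * single.counts[codon])

    def test_missing_weight_id_is_named(self):
        with pytest.raises(KeyError, match="orphan"):
            count_codons([CodingSequence("orphan", "ATGTAA")], ExpressionTable({"x": 1.0}))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_codons([])

    def test_matches_brute_force_on_synthetic_set(self):
        cfg = GeneratorConfig(seed=7, n_sequences=50, codons_per_seq=100)
        cds_set = gen_cds(cfg)
        table = count_codons(cds_set)
        oracle = brute_force_codon_counts(cds_set)
        for codon in CODONS:
            assert table.counts[codon] == oracle.get(codon, 0.0)

    def test_weight_linearity(self):
        cfg = GeneratorConfig(seed=8, n_sequences=10, codons_per_seq=50)
        cds_set = gen_cds(cfg)
        weights = ExpressionTable({c.id: 2.5 for c in cds_set})
        scaled = count_codons(cds_set, weights)
        plain = count_codons(cds_set)
        for codon in CODONS:
            assert scaled.counts[codon] == pytest.approx(2.5 * plain.counts[codon])


class TestRscu:
    def test_uniform_proline_usage_gives_one(self):
        counts = {c: 0.0 for c in CODONS}
        for c in ("CCG", "CCA", "CCC", "CCT"):
            counts[c] = 5.0
        table = compute_rscu(count_codons([CodingSequence("x", "ATGTAA")]))
        table.counts = counts
        table = compute_rscu(table)
        assert all(table.rscu[c] == pytest.approx(1.0) for c in ("CCG", "CCA", "CCC", "CCT"))

    def test_matches_formula_oracle_on_random_counts(self):
        rng = np.random.default_rng(42)
        counts = dict(zip(CODONS, rng.integers(0, 500, size=64).astype(float)))
        table = count_codons([CodingSequence("x", "ATGTAA")])
        table.counts = dict(counts)
        compute_rscu(table)
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            t_i = sum(counts[c] for c in codons)
            for c in codons:
                if t_i > 0:
                    assert table.rscu[c] == pytest.approx(counts[c] * len(codons) / t_i)

    def test_family_sums_equal_family_size(self):
        cfg = GeneratorConfig(seed=9, n_sequences=30, codons_per_seq=80)
        table = compute_rscu(count_codons(gen_cds(cfg)))
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            if sum(table.counts[c] for c in codons) > 0:
                assert sum(table.rscu[c] for c in codons) == pytest.approx(
                    len(codons), rel=1e-9
                )

    def test_zero_count_family_reported_missing_not_zero(self):
        table = count_codons([CodingSequence("x", "ATGTAA")])
        compute_rscu(table)
        # no tryptophan codon present -> its RSCU is undefined
        assert "TGG" not in table.rscu
        assert table.rscu["ATG"] == pytest.approx(1.0)


class TestCodonPairs:
    def test_two_pair_enumeration(self):
        table = count_codon_pairs([CodingSequence("x", "ATGAAATAA")])
        nonzero = {p: n for p, n in table.counts.items() if n}
        assert nonzero == {("ATG", "AAA"): 1.0, ("AAA", "TAA"): 1.0}

    def test_repeated_codon(self):
        table = count_codon_pairs([CodingSequence("x", "ATGATGATG")])
        assert table.counts[("ATG", "ATG")] == 2.0
        assert table.total == 2.0

    def test_single_codon_cds_contributes_nothing(self):
        table = count_codon_pairs([CodingSequence("x", "ATG"), CodingSequence("y", "ATGTAA")])
        assert table.total == 1.0

    def test_indexes_all_4096_ordered_pairs(self):
        table = count_codon_pairs([CodingSequence("x", "ATGTAA")])
        assert len(table.counts) == 64 * 64 == 4096
        assert set(table.counts) == set(CODON_PAIRS)

    def test_matches_brute_force_on_synthetic_set(self):
        cfg = GeneratorConfig(seed=10, n_sequences=30, codons_per_seq=60)
        cds_set = gen_cds(cfg)
        table = count_codon_pairs(cds_set)
        oracle = brute_force_pair_counts(cds_set)
        for pair in CODON_PAIRS:
            assert table.counts[pair] == oracle.get(pair, 0.0)


class TestPairFrequencies:
    def test_single_nonzero_pair_hits_extremes(self):
        table = count_codon_pairs([CodingSequence("x", "ATGTAA")])
        pair_frequencies(table)
        assert table.freq_per_million[("ATG", "TAA")] == pytest.approx(1e6)
        assert table.percentile[("ATG", "TAA")] == pytest.approx(100.0)
        assert table.percentile[("AAA", "AAA")] == 0.0

    def test_equal_counts_give_zero_percentiles(self):
        table = count_codon_pairs([CodingSequence("x", "ATGTAA")])
        table.counts = {p: 3.0 for p in CODON_PAIRS}
        pair_frequencies(table)
        assert all(v == 0.0 for v in table.percentile.values())

    def test_frequencies_sum_to_one_million(self):
        cfg = GeneratorConfig(seed=12, n_sequences=20, codons_per_seq=100)
        table = pair_frequencies(count_codon_pairs(gen_cds(cfg)))
        assert sum(table.freq_per_million.values()) == pytest.approx(1e6, rel=1e-6)

    def test_matches_sort_based_rank_oracle(self):
        rng = np.random.default_rng(77)
        counts = rng.integers(0, 50, size=4096).astype(float)
        table = count_codon_pairs([CodingSequence("x", "ATGTAA")])
        table.counts = dict(zip(CODON_PAIRS, counts))
        pair_frequencies(table)
        for i in rng.choice(4096, size=200, replace=False):
            pair = CODON_PAIRS[i]
            expected = 100.0 * np.sum(counts < counts[i]) / 4095
            assert table.percentile[pair] == pytest.approx(expected)

    def test_percentile_weakly_monotone_in_frequency(self):
        cfg = GeneratorConfig(seed=13, n_sequences=10, codons_per_seq=200)
        table = pair_frequencies(count_codon_pairs(gen_cds(cfg)))
        freqs = np.array([table.freq_per_million[p] for p in CODON_PAIRS])
        pcts = np.array([table.percentile[p] for p in CODON_PAIRS])
        order = np.argsort(freqs)
        assert (np.diff(pcts[order]) >= -1e-12).all()

    def test_zero_total_rejected(self):
        table = count_codon_pairs([CodingSequence("x", "ATGTAA")])
        table.counts = {p: 0.0 for p in CODON_PAIRS}
        with pytest.raises(ValueError, match="zero total"):
            pair_frequencies(table)

    def test_scale_invariance_of_rscu_and_percentiles(self):
        """Multiplying all TPM weights by a constant changes no RSCU or rank."""
        cfg = GeneratorConfig(seed=14, n_sequences=15, codons_per_seq=60)
        cds_set = gen_cds(cfg)
        base = ExpressionTable({c.id: 1.0 + i for i, c in enumerate(cds_set)})
        scaled = ExpressionTable({k: 7.5 * v for k, v in base.tpm.items()})
        r1 = compute_rscu(count_codons(cds_set, base))
        r2 = compute_rscu(count_codons(cds_set, scaled))
        assert r1.rscu == pytest.approx(r2.rscu)
        p1 = pair_frequencies(count_codon_pairs(cds_set, base))
        p2 = pair_frequencies(count_codon_pairs(cds_set, scaled))
        assert p1.percentile == pytest.approx(p2.percentile)
        assert p1.freq_per_million == pytest.approx(p2.freq_per_million)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.sampled_from(CODONS), min_size=2, max_size=60))
def test_rscu_family_sums_property(codon_list):
    """For any CDS, every represented family's RSCU sums to its size."""
    table = compute_rscu(count_codons([CodingSequence("h", "".join(codon_list))]))
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        total = sum(table.counts[c] for c in codons)
        if total > 0:
            assert sum(table.rscu[c] for c in codons) == pytest.approx(len(codons))
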