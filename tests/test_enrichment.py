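"""k-mer counting and the enrichment statistic against independent oracles."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promoscan.enrichment import (EnrichmentRecord, bh_adjust, count_motifs,
                                  enrichment_fraction, filter_enriched,
                                  hypergeom_pvalue, score_motifs)


def brute_force_windows(seq, k):
    """Reference k-mer scan: dict of counts over clean windows."""
    out = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if set(w) <= set("ACGT"):
            out[w] = out.get(w, 0) + 1
    return out


def exact_upper_tail(k, K, n, N):
    """P(X >= k) by exact integer summation of the hypergeometric pmf."""
    num = sum(comb(n, i) * comb(N - n, K - i) for i in range(k, min(K, n) + 1))
    return num / comb(N, K)


class TestCountMotifs:
    def test_occurrence_mode_enumerable_by_hand(self):
        table = count_motifs({"p1": "ACGTACGT"}, ["p1"], k=6, mode="occurrence")
        assert table.counts["n_bg"].to_dict() == {"ACGTAC": 1, "CGTACG": 1, "GTACGT": 1}
        assert table.N_bg == 3 and table.K_fg == 3

    def test_presence_mode_enumerable_by_hand(self):
        table = count_motifs({"p1": "ACGTACGT"}, ["p1"], k=6, mode="presence")
        assert table.counts["n_bg"].to_dict() == {"ACGTAC": 1, "CGTACG": 1, "GTACGT": 1}
        assert table.K_fg == 1 and table.N_bg == 1
        assert (table.counts["k_fg"] == table.counts["n_bg"]).all()

    def test_windows_containing_n_are_skipped(self):
        table = count_motifs({"p1": "ACGTACNTTTTTTT"}, [], k=6, mode="occurrence")
        # windows start at 0..8; those covering position 6 (the N) are dropped
        assert table.counts["n_bg"].sum() == 3  # ACGTAC + TTTTTT + TTTTTT
        assert table.counts.loc["TTTTTT", "n_bg"] == 2

    def test_occurrence_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(12)
        seqs = {f"p{i:02d}": "".join(rng.choice(list("ACGTN"), size=1000,
                                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
                for i in range(20)}
        table = count_motifs(seqs, list(seqs)[:5], k=6, mode="occurrence")
        expected = {}
        total = 0
        for s in seqs.values():
            for w, c in brute_force_windows(s, 6).items():
                expected[w] = expected.get(w, 0) + c
                total += c
        assert table.counts["n_bg"].to_dict() == expected
        assert table.N_bg == total

    def test_presence_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(13)
        seqs = {f"p{i:02d}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(15)}
        fg = list(seqs)[:4]
        table = count_motifs(seqs, fg, k=6, mode="presence")
        for motif in table.counts.sample(50, random_state=0).index:
            assert table.counts.loc[motif, "n_bg"] == sum(motif in s for s in seqs.values())
            assert table.counts.loc[motif, "k_fg"] == sum(motif in seqs[g] for g in fg)
        assert (table.counts["k_fg"] <= table.counts["n_bg"]).all()
        assert (table.counts["n_bg"] <= table.N_bg).all()

    def test_missing_foreground_gene_is_named(self):
        with pytest.raises(KeyError, match="ghost"):
            count_motifs({"p1": "ACGTACGT"}, ["ghost"], k=6)


class TestEnrichmentFraction:
    @pytest.mark.parametrize("k,K,n,N,expected", [
        (128, 849, 3824, 34417, 1.35692989),   # published up-cluster G-box row
        (110, 631, 3947, 34417, 1.52008968),   # published down-cluster site II row
        (10, 100, 100, 1000, 1.0),
    ])
    def test_known_values(self, k, K, n, N, expected):
        assert enrichment_fraction(k, K, n, N) == pytest.approx(expected, abs=5e-7)

    def test_zero_background_is_an_error(self):
        with pytest.raises(ValueError):
            enrichment_fraction(1, 10, 0, 100)
        with pytest.raises(ValueError):
            enrichment_fraction(1, 0, 5, 100)

    @given(st.integers(0, 500), st.integers(1, 500), st.integers(1, 5000),
           st.integers(1, 5000), st.integers(1, 1000))
    @settings(max_examples=200, derandomize=True)
    def test_scale_free(self, k, K, n, N, c):
        e1 = enrichment_fraction(k, K, n, N)
        e2 = enrichment_fraction(k * c, K * c, n * c, N * c)
        assert e2 == pytest.approx(e1, rel=1e-12)


class TestHypergeomPvalue:
    def test_zero_observed_covers_whole_support(self):
        assert hypergeom_pvalue(0, 8, 6, 20) == 1.0

    def test_small_case_by_enumeration(self):
        # N=4, n=2, K=2: of the C(4,2)=6 samples exactly one holds both successes
        assert hypergeom_pvalue(2, 2, 2, 4) == pytest.approx(1 / 6, rel=1e-12)

    def test_matches_direct_summation(self):
        assert hypergeom_pvalue(4, 8, 6, 20) == pytest.approx(
            exact_upper_tail(4, 8, 6, 20), rel=1e-12)

    def test_strictly_decreasing_in_observed_count(self):
        ps = [hypergeom_pvalue(k, 10, 12, 40) for k in range(0, 11)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(7, 5, 10, 20)   # k > K
        with pytest.raises(ValueError):
            hypergeom_pvalue(4, 10, 3, 20)   # k > n
        with pytest.raises(ValueError):
            hypergeom_pvalue(1, 30, 10, 20)  # K > N

    def test_realistic_scale_against_summation(self):
        p = hypergeom_pvalue(128, 849, 3824, 34417)
        assert p == pytest.approx(exact_upper_tail(128, 849, 3824, 34417), rel=1e-9)


class TestBHAdjust:
    def test_single_and_empty(self):
        assert bh_adjust([0.05]) == [0.05]
        assert bh_adjust([]) == []

    def test_hand_evaluated_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.01])

    def test_q_dominates_p_and_is_monotone_in_sorted_order(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            q = np.array(bh_adjust(p))
            assert (q >= p - 1e-15).all()
            assert (q <= 1.0).all()
            order = np.argsort(p, kind="stable")
            assert (np.diff(q[order]) >= -1e-15).all()


class TestScoreAndFilter:
    def _rec(self, enrichment, q, p=1e-4):
        return EnrichmentRecord("CACGTG", 1, 10, 1, 100, enrichment, p, q)

    def test_published_grade_record_survives_filter(self):
        rec = self._rec(1.35692989, 0.000215)
        kept = filter_enriched([rec])
        assert kept == [rec] and rec.passes

    def test_sub_threshold_enrichment_dropped_despite_tiny_q(self):
        rec = self._rec(1.09, 1e-9)
        assert filter_enriched([rec]) == [] and not rec.passes

    def test_non_significant_dropped_despite_high_enrichment(self):
        rec = self._rec(1.5, 0.2)
        assert filter_enriched([rec]) == [] and not rec.passes

    def test_sorted_by_enrichment_then_p(self):
        recs = [EnrichmentRecord("AAAAAA", 5, 10, 10, 100, 1.5, 0.002, 0.01),
                EnrichmentRecord("CCCCCC", 6, 10, 12, 100, 1.8, 0.001, 0.01),
                EnrichmentRecord("GGGGGG", 5, 10, 10, 100, 1.5, 0.001, 0.01)]
        kept = filter_enriched(recs)
        assert [r.motif for r in kept] == ["CCCCCC", "GGGGGG", "AAAAAA"]

    def test_absent_motifs_keep_family_size_stable(self):
        seqs = {"p1": "ACGTACGTAA", "p2": "TTTTTTTTTT"}
        table = count_motifs(seqs, ["p2"], k=6, mode="presence")
        records = score_motifs(table)
        by_motif = {r.motif: r for r in records}
        assert len(records) == len(table.counts)          # family = observed motifs
        absent = by_motif["ACGTAC"]                       # not in foreground promoter
        assert absent.k_fg == 0 and absent.enrichment == 0.0 and absent.p_raw == 1.0
        assert all(r.q_bh >= r.p_raw - 1e-15 for r in records)
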