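"""Hypergeometric layer: enumeration oracle, worked examples, combo grid."""

import math

import numpy as np
import pytest
from scipy import stats

from g4prom.enrichment_stats import (
    N_COMBO_CELLS,
    hypergeom_test,
    loop_combo_enrichment,
    membership_enrichment,
    subset_enrichment,
)
from g4prom.g4scan import PG4Motif
from g4prom.sequence_io import GeneList, TSSRecord
from g4prom.tss_map import assign_nearest


def enum_tails(N, K, n, k):
    """Exhaustive enumeration over all C(N, n) draws: exact tail masses."""
    total = math.comb(N, n)
    ge = sum(math.comb(K, j) * math.comb(N - K, n - j)
             for j in range(k, min(n, K) + 1))
    le = sum(math.comb(K, j) * math.comb(N - K, n - j)
             for j in range(max(0, n + K - N), k + 1))
    return ge / total, le / total


def make_motif(loops, seq_id="c", start=0, strand="+"):
    matched = "GGG" + "GGG".join(loops) + "GGG"
    return PG4Motif(seq_id, start, start + len(matched), strand, matched,
                    ("GGG",) * (len(loops) + 1), tuple(loops))


class TestHypergeomTest:
    def test_worked_example(self):
        r = hypergeom_test(10, 5, 4, 4)
        assert r.p_enrich == pytest.approx(5 / 210, abs=1e-12)

    def test_symmetric_depletion(self):
        r = hypergeom_test(10, 5, 4, 0)
        assert r.p_deplete == pytest.approx(5 / 210, abs=1e-12)
        assert r.p_enrich == pytest.approx(1.0, abs=1e-12)

    def test_printed_contingency_percentages(self):
        # PhenDC3: 1,804 of 2,212 DE genes G4-positive; genome 16,607/24,651
        r = hypergeom_test(24651, 16607, 2212, 1804)
        assert r.pct_sample == pytest.approx(81.5, abs=0.1)
        assert r.pct_universe == pytest.approx(67.3, abs=0.1)

    def test_exhaustive_enumeration_small_n(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        r = hypergeom_test(N, K, n, k)
                        ge, le = enum_tails(N, K, n, k)
                        assert r.p_enrich == pytest.approx(ge, abs=1e-12)
                        assert r.p_deplete == pytest.approx(le, abs=1e-12)

    def test_pmf_normalizes(self, rng):
        for _ in range(50):
            N = int(rng.integers(2, 501))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            ks = np.arange(max(0, n + K - N), min(n, K) + 1)
            total = stats.hypergeom(N, K, n).pmf(ks).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotonicity_in_k(self):
        N, K, n = 100, 40, 30
        ps = [hypergeom_test(N, K, n, k).p_enrich
              for k in range(max(0, n + K - N), min(n, K) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_tails_overlap_at_k(self):
        r = hypergeom_test(50, 20, 10, 4)
        assert r.p_enrich + r.p_deplete >= 1.0

    def test_bound_violations_named(self):
        with pytest.raises(ValueError, match="K <= N"):
            hypergeom_test(5, 6, 2, 1)
        with pytest.raises(ValueError, match="k <= min"):
            hypergeom_test(10, 5, 4, 5)
        with pytest.raises(ValueError, match="n \\+ K - N"):
            hypergeom_test(10, 9, 9, 7)

    def test_large_universe_no_underflow(self):
        r = hypergeom_test(24651, 16607, 2212, 1804)
        assert 0 < r.p_enrich < 1e-50


class TestMembershipEnrichment:
    def test_worked_example(self):
        uni = GeneList("u", "universe", frozenset("abcdefghij"))
        sample = GeneList("s", "up", frozenset("abcd"))
        r = membership_enrichment(sample, set("abcde"), uni)
        assert (r.N, r.K, r.n, r.k) == (10, 5, 4, 4)
        assert r.p_enrich == pytest.approx(5 / 210, abs=1e-12)

    def test_sample_equals_universe(self):
        uni = GeneList("u", "universe", frozenset("abcdef"))
        r = membership_enrichment(GeneList("s", "up", uni.gene_ids), set("abc"), uni)
        assert r.fold == pytest.approx(1.0)
        assert r.p_enrich == pytest.approx(1.0)

    def test_empty_feature(self):
        uni = GeneList("u", "universe", frozenset("abcdef"))
        r = membership_enrichment(GeneList("s", "up", frozenset("ab")), set(), uni)
        assert (r.K, r.k) == (0, 0)
        assert r.p_enrich == pytest.approx(1.0)

    def test_sample_outside_universe_rejected(self):
        uni = GeneList("u", "universe", frozenset("abc"))
        with pytest.raises(ValueError, match="outside universe"):
            membership_enrichment(GeneList("s", "up", frozenset("az")), set(), uni)


class TestSubsetEnrichment:
    def _assignments(self, subset_counts, seq="chr1"):
        """Build real assignments hitting the requested af/ar/bf/br counts."""
        out = []
        start = 0
        placements = {
            "af": (3000, "+"), "ar": (3000, "-"), "bf": (1000, "+"), "br": (1000, "-"),
        }
        anchor = TSSRecord("g", "m", seq, 2000, "+")
        for subset, count in subset_counts.items():
            pos, strand = placements[subset]
            for i in range(count):
                m = make_motif(("A", "T", "C"), seq_id=seq, start=pos + 20 * i, strand=strand)
                a, _ = assign_nearest([m], [anchor])
                assert a[0].subset == subset
                out.extend(a)
            start += 1000
        return out

    def test_concentrated_vs_uniform(self):
        sample = self._assignments({"af": 8})
        ref = self._assignments({"af": 2, "ar": 2, "bf": 2, "br": 2})
        res = subset_enrichment(sample, ref)
        assert res["af"].p_enrich < res["ar"].p_enrich

    def test_identical_composition_fold_one(self):
        sample = self._assignments({"af": 2, "ar": 2, "bf": 2, "br": 2})
        ref = self._assignments({"af": 2, "ar": 2, "bf": 2, "br": 2})
        res = subset_enrichment(sample, ref)
        for s in ("af", "ar", "bf", "br"):
            assert res[s].fold == pytest.approx(1.0)

    def test_tiny_case_matches_enumeration(self):
        sample = self._assignments({"af": 3, "br": 1})
        ref = self._assignments({"af": 1, "ar": 1, "bf": 1, "br": 1})
        res = subset_enrichment(sample, ref)
        ge, le = enum_tails(8, 4, 4, 3)
        assert res["af"].p_enrich == pytest.approx(ge, abs=1e-12)
        assert res["af"].p_deplete == pytest.approx(le, abs=1e-12)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            subset_enrichment(self._assignments({"af": 1}), [])


class TestLoopComboEnrichment:
    def test_grid_has_343_cells(self):
        ms = [make_motif(("A", "T", "C"), start=20 * i) for i in range(4)]
        table = loop_combo_enrichment(ms, ms)
        assert len(table.table) == N_COMBO_CELLS == 343

    def test_count_conservation_single_cell(self):
        ms = [make_motif(("A", "C", "T"), start=20 * i) for i in range(5)]
        t = loop_combo_enrichment(ms, ms)
        assert t.counts.sum() == 5
        assert t.counts[0, 0, 0] == 5
        assert (t.counts > 0).sum() == 1

    def test_set_equals_background_fold_one(self):
        loops_choices = [("A", "TT", "CCC"), ("AAAA", "T", "C"), ("A", "T", "C")]
        ms = []
        start = 0
        for loops in loops_choices:
            for _ in range(120):
                ms.append(make_motif(loops, start=start))
                start += 40
        t = loop_combo_enrichment(ms, ms)
        assert not t.skip_testing
        tested = t.table[t.table["flag"] == ""]
        for row in tested.itertuples(index=False):
            if row.count_set:
                assert row.count_set == row.count_bg

    def test_small_set_skips_testing(self):
        ms = [make_motif(("A", "T", "C"), start=20 * i) for i in range(10)]
        t = loop_combo_enrichment(ms, ms)
        assert t.skip_testing
        assert t.table["p_enrich"].isna().all()

    def test_long_loops_routed_to_bin_seven(self, caplog):
        m = make_motif(("GAGGAGGA", "T", "C"))  # 8 nt first loop
        with caplog.at_level("INFO"):
            t = loop_combo_enrichment([m], [m])
        assert t.counts[6, 0, 0] == 1

    def test_non_four_tract_rejected(self):
        m5 = make_motif(("A", "T", "C", "A"))
        with pytest.raises(ValueError, match="4-tract"):
            loop_combo_enrichment([m5], [m5])

    def test_no_data_flag(self):
        ms = [make_motif(("A", "T", "C"), start=20 * i) for i in range(400)]
        t = loop_combo_enrichment(ms, ms)
        nd = t.table[t.table["flag"] == "no_data"]
        assert len(nd) == 342  # all but the single occupied cell
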