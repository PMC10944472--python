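import itertools
import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unilib.mhg_enrichment import (
    EnrichmentConfig,
    brute_force_pvalue,
    classify_motifs,
    enrich_motifs,
    enrich_submotifs,
    hypergeometric_tail,
    mhg_exact_pvalue,
    mhg_score,
    mhg_test,
)


class TestHypergeometricTail:
    def test_direct_counting_case(self):
        # P(both labeled in a 2-prefix | 2 of 4 labeled) = 1/C(4,2)
        assert hypergeometric_tail(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_tail_from_zero_is_one(self):
        assert hypergeometric_tail(0, 3, 2, 10) == 1.0

    def test_matches_pmf_summation_oracle(self):
        """Tail equals brute-force pmf summation for all small cases."""
        for N in range(1, 11):
            for B in range(N + 1):
                for n in range(N + 1):
                    for b in range(min(n, B) + 1):
                        expected = sum(
                            math.comb(B, k) * math.comb(N - B, n - k)
                            for k in range(b, min(n, B) + 1)
                        ) / math.comb(N, n)
                        assert hypergeometric_tail(b, n, B, N) == \
                            pytest.approx(expected, abs=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(3, 2, 5, 10)


class TestMHGScore:
    def test_top_enrichment(self):
        score, n_star = mhg_score([1, 1, 0, 0])
        assert score == pytest.approx(1 / 6)
        assert n_star == 2

    def test_no_labels(self):
        score, n_star = mhg_score([0, 0, 0, 0])
        assert score == 1.0 and n_star is None

    def test_bottom_enrichment_scores_one(self):
        score, _ = mhg_score([0, 0, 1, 1])
        assert score == 1.0

    def test_exhaustive_minimum(self, rng):
        """Score equals the explicit minimum over prefix tails."""
        for _ in range(50):
            N = int(rng.integers(2, 15))
            labels = (rng.random(N) < 0.4).astype(int).tolist()
            B = sum(labels)
            score, _ = mhg_score(labels)
            if B == 0:
                assert score == 1.0
                continue
            expected = min(
                hypergeometric_tail(sum(labels[:n]), n, B, N)
                for n in range(1, N)
            ) if N > 1 else 1.0
            assert score == pytest.approx(min(expected, 1.0))


class TestExactPValue:
    def test_four_item_enumeration(self):
        # only [1,1,0,0] attains 1/6 among the 6 arrangements
        assert mhg_exact_pvalue(1 / 6, 4, 2) == pytest.approx(1 / 6)

    def test_b_zero(self):
        assert mhg_exact_pvalue(0.5, 10, 0) == 1.0

    def test_dp_equals_enumeration_small_lattice(self):
        """DP p-value equals brute-force enumeration over all arrangements
        for every (N, B) with N <= 9 and every attainable score."""
        for N in range(2, 10):
            for B in range(N + 1):
                scores = set()
                for ones in itertools.combinations(range(N), B):
                    labels = [0] * N
                    for i in ones:
                        labels[i] = 1
                    scores.add(round(mhg_score(labels)[0], 12))
                for s in scores:
                    assert mhg_exact_pvalue(s, N, B) == \
                        pytest.approx(brute_force_pvalue(s, N, B), abs=1e-9), \
                        (N, B, s)

    @given(st.integers(2, 40), st.data())
    @settings(max_examples=150, deadline=None)
    def test_score_pvalue_bounds(self, N, data):
        """mhg_score <= p_exact <= min(1, N * mhg_score) on random lists."""
        labels = data.draw(st.lists(st.integers(0, 1), min_size=N, max_size=N))
        res = mhg_test(labels)
        assert 0 < res.mhg_score <= 1
        assert res.p_exact >= res.mhg_score - 1e-12
        assert res.p_exact <= min(1.0, res.N * res.mhg_score) + 1e-9

    def test_reversal_swaps_directions(self, rng):
        """mHG on the reversed list equals the down-direction result."""
        for _ in range(20):
            N = int(rng.integers(4, 30))
            labels = (rng.random(N) < 0.3).astype(int).tolist()
            up = mhg_test(labels)
            down_manual = mhg_test(labels[::-1])
            assert down_manual.mhg_score == pytest.approx(
                mhg_test(list(reversed(labels))).mhg_score)
            assert up.B == down_manual.B

    def test_prepending_hits_never_worsens_score(self, rng):
        for _ in range(30):
            N = int(rng.integers(3, 25))
            labels = (rng.random(N) < 0.3).astype(int).tolist()
            s0, _ = mhg_score([1] + labels)
            s1, _ = mhg_score([1, 1] + labels)
            assert s1 <= s0 + 1e-12


class TestMotifScreen:
    @staticmethod
    def _records(vm, expr):
        return pd.DataFrame(
            {"expression": expr, "total_reads": [100] * len(expr)},
            index=list(vm),
        )

    def test_planted_activator_detected_up_only(self, rng):
        n = 300
        vm = {}
        expr = []
        for i in range(n):
            has = i < 100
            vm[f"v{i}"] = ("act",) if has else ("neutral",)
            expr.append(3000 + (1500 if has else 0) + rng.normal(0, 150))
        records = self._records(vm, expr)
        results = enrich_motifs(records, vm, config=EnrichmentConfig())
        by = {(r.motif_id, r.direction): r for r in results}
        assert by[("act", "up")].p_exact < 1e-4
        assert by[("act", "down")].p_exact > 1e-4
        cls = classify_motifs([r for r in results if r.direction == "up"],
                              [r for r in results if r.direction == "down"])
        assert cls.loc["act", "classification"] == "activating"
        assert cls.loc["neutral", "classification"] == "repressing"

    def test_absent_motif_scores_one(self):
        vm = {"v1": ("m1",), "v2": ()}
        records = self._records(vm, [2000.0, 1000.0])
        results = enrich_motifs(records, vm, motif_ids=["m1", "ghost"])
        ghost = [r for r in results if r.motif_id == "ghost"]
        assert all(r.mhg_score == 1.0 for r in ghost)

    def test_min_reads_filter(self):
        vm = {"v1": ("m1",), "v2": ()}
        records = pd.DataFrame({"expression": [2000.0, 1000.0],
                                "total_reads": [100, 10]}, index=["v1", "v2"])
        results = enrich_motifs(records, vm, config=EnrichmentConfig(min_reads=40))
        assert all(r.N == 1 for r in results)

    def test_classification_conflict_flagged(self):
        from unilib.mhg_enrichment import MHGResult
        mk = lambda d, p: MHGResult("m", d, p, 1, p, 5, 10, 1e-4)
        cls = classify_motifs([mk("up", 1e-6)], [mk("down", 1e-6)])
        assert cls.loc["m", "classification"] == "undetermined"
        assert bool(cls.loc["m", "conflict"])


class TestSubmotifScreen:
    def test_effect_on_single_submotif_recovered(self, mixed_catalog, rng):
        """Only the sub-motif carrying the planted effect comes out significant."""
        # variants: single-motif mx2 (one K position); sub-variant G boosted
        n = 260
        index = pd.MultiIndex.from_tuples(
            [(f"v{i}", "G" if i % 2 else "T") for i in range(n)],
            names=["variant_id", "subvariant"],
        )
        vm = {f"v{i}": ("mx2",) for i in range(n)}
        expr = [4000 + rng.normal(0, 100) if sub == "G" else
                2500 + rng.normal(0, 100) for _, sub in index]
        recs = pd.DataFrame(
            {"expression": expr, "total_reads": [100] * n}, index=index)
        results = enrich_submotifs(recs, mixed_catalog, vm)
        by = {(r.motif_id, r.direction): r for r in results}
        assert by[("mx2|G", "up")].p_exact < 1e-4
        assert by[("mx2|T", "up")].p_exact > 1e-4

    def test_catalog_expansion_counts(self, mixed_catalog):
        """A catalog with 2 plain motifs and mixed motifs with 2 and 1
        mixed positions screens 2 + 4 + 2 sub-motifs."""
        recs = pd.DataFrame(
            {"expression": [1.0], "total_reads": [100]},
            index=pd.MultiIndex.from_tuples([("v0", "")],
                                            names=["variant_id", "subvariant"]),
        )
        results = enrich_submotifs(recs, mixed_catalog, {"v0": ()},
                                   directions=("up",))
        assert len(results) == 4 + 2 + 1 + 1
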