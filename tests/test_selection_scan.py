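"""Top-percentile selection, set intersection, gene annotation, enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    GeneAnnotation,
    annotate_genes,
    candidate_windows,
    enrichment_test,
    overlap_regions,
    top_percentile,
)


def keys_for(n, chrom="chr1"):
    return [(chrom, i * 100 + 1, i * 100 + 100) for i in range(n)]


class TestTopPercentile:
    def test_quantile_threshold_on_1_to_100(self):
        keys = keys_for(100)
        vals = np.arange(1.0, 101.0)
        selected, threshold = top_percentile(keys, vals, q=0.01)
        assert threshold == pytest.approx(99.01)
        assert selected == {keys[99]}

    def test_ties_at_threshold_all_selected(self):
        keys = keys_for(10)
        vals = np.array([0.0] * 7 + [5.0, 5.0, 5.0])
        selected, threshold = top_percentile(keys, vals, q=0.1)
        assert set(selected) == set(keys[7:])  # all tied windows kept

    def test_infinite_values_always_selected(self):
        keys = keys_for(5)
        vals = np.array([1.0, 2.0, 3.0, 4.0, np.inf])
        selected, _ = top_percentile(keys, vals, q=0.2)
        assert keys[4] in selected

    def test_nan_values_excluded_from_ranking(self):
        keys = keys_for(6)
        vals = np.array([1.0, np.nan, 3.0, np.nan, 5.0, 7.0])
        selected, threshold = top_percentile(keys, vals, q=0.25)
        assert keys[1] not in selected and keys[3] not in selected

    def test_too_few_defined_values_error(self):
        with pytest.raises(ValueError):
            top_percentile(keys_for(2), np.array([1.0, np.nan]), q=0.01)

    def test_fixed_count_method(self):
        keys = keys_for(100)
        vals = np.arange(1.0, 101.0)
        selected, _ = top_percentile(keys, vals, q=0.05, method="count")
        assert len(selected) == 5


def stats_frame(z, ratio, d):
    n = len(z)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 100_000 + 1,
        "end": np.arange(n) * 100_000 + 100_000,
        "z_fst": z,
        "log2_ratio": ratio,
        "tajima_d_focal": d,
    })


class TestCandidateWindows:
    def test_tajima_filter_sign_behavior(self):
        z = np.zeros(100); z[:3] = [10.0, 9.0, 8.0]
        ratio = np.zeros(100); ratio[:3] = [5.0, 4.0, 3.0]
        d = np.zeros(100)
        d[0] = -2.8   # strongly negative: retained
        d[1] = 0.1    # positive: excluded
        d[2] = np.nan  # undefined: excluded
        cs = candidate_windows(stats_frame(z, ratio, d), q=0.03)
        finals = {w[1] for w in cs.final}
        assert finals == {1}
        assert len(cs.shared) == 3

    def test_set_inclusions_always_hold(self, rng):
        for _ in range(20):
            n = 200
            z = rng.normal(size=n)
            ratio = rng.normal(size=n)
            d = rng.normal(size=n)
            d[rng.integers(0, n, 10)] = np.nan
            cs = candidate_windows(stats_frame(z, ratio, d), q=0.05)
            assert cs.final <= cs.shared
            assert cs.shared <= cs.top_fst and cs.shared <= cs.top_ratio

    def test_monotone_in_q(self, rng):
        z = rng.normal(size=300)
        ratio = rng.normal(size=300)
        d = rng.normal(size=300)
        small = candidate_windows(stats_frame(z, ratio, d), q=0.01)
        large = candidate_windows(stats_frame(z, ratio, d), q=0.5)
        assert small.top_fst <= large.top_fst
        assert small.shared <= large.shared
        assert small.final <= large.final


class TestAnnotateGenes:
    @staticmethod
    def annotation():
        return GeneAnnotation(pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [150, 301, 250],
            "end": [250, 400, 350],
            "gene_id": ["g1", "g2", "g3"],
            "gene_name": ["G1", "G2", "G3"],
        }))

    def test_overlap_is_inclusive_one_bp(self):
        genes, n = annotate_genes({("chr1", 200, 300)}, self.annotation())
        assert genes[("chr1", 200, 300)] == ["G1", "G3"]
        # gene starting at 301 does not touch a window ending at 300
        assert "G2" not in genes[("chr1", 200, 300)]

    def test_gene_spanning_two_windows_counted_once(self):
        wins = {("chr1", 100, 260), ("chr1", 200, 360)}
        genes, n_distinct = annotate_genes(wins, self.annotation())
        total_listed = sum(len(v) for v in genes.values())
        assert n_distinct <= total_listed
        assert n_distinct == 3


class TestOverlapRegions:
    def test_partial_overlap(self):
        assert overlap_regions([("chr1", 1, 100)], [("chr1", 50, 150)]) == \
            [("chr1", 50, 100)]

    def test_disjoint_sets_empty_result(self):
        assert overlap_regions([("chr1", 1, 100)], [("chr1", 200, 300)]) == []

    def test_contained_interval(self):
        assert overlap_regions([("chr1", 1, 1000)], [("chr1", 50, 150)]) == \
            [("chr1", 50, 150)]

    def test_different_chromosomes_do_not_overlap(self):
        assert overlap_regions([("chr1", 1, 100)], [("chr2", 1, 100)]) == []


# ---------------------------------------------------------------------------
# enrichment: exact hypergeometric-tail oracle in rational arithmetic
# ---------------------------------------------------------------------------

def fisher_oracle(k, M, n, N) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, n, N), exact."""
    total = Fraction(0)
    for x in range(k, min(n, N) + 1):
        total += Fraction(comb(n, x) * comb(M - n, N - x), comb(M, N))
    return float(total)


class TestEnrichment:
    def test_extreme_enrichment_is_minimal_p(self):
        background = {f"g{i}" for i in range(100)}
        candidates = {f"g{i}" for i in range(5)}
        sets = {
            "exact_match": set(candidates),
            "random": {f"g{i}" for i in range(40, 60)},
            "disjoint": {f"g{i}" for i in range(90, 100)},
        }
        table = enrichment_test(candidates, background, sets)
        assert table.iloc[0]["term"] == "exact_match"
        disjoint = table[table["term"] == "disjoint"].iloc[0]
        assert disjoint["p_value"] == 1.0

    def test_p_matches_hypergeometric_tail(self, rng):
        background = {f"g{i}" for i in range(60)}
        for _ in range(100):
            n_cand = int(rng.integers(3, 20))
            n_term = int(rng.integers(1, 40))
            candidates = set(rng.choice(sorted(background), n_cand, replace=False))
            term = set(rng.choice(sorted(background), n_term, replace=False))
            table = enrichment_test(candidates, background, {"t": term})
            k = len(term & candidates)
            expected = 1.0 if k == 0 else fisher_oracle(k, 60, n_term, n_cand)
            assert table.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_bh_correction_matches_manual(self):
        background = {f"g{i}" for i in range(50)}
        candidates = {f"g{i}" for i in range(8)}
        sets = {f"t{j}": {f"g{i}" for i in range(j, j + 10)} for j in range(5)}
        table = enrichment_test(candidates, background, sets)
        p = table["p_value"].to_numpy()
        m = len(p)
        # manual step-up BH on the sorted p-values
        ranked = p * m / (np.arange(m) + 1)
        manual = np.minimum.accumulate(ranked[::-1])[::-1]
        np.testing.assert_allclose(table["fdr_bh"].to_numpy(), np.minimum(manual, 1))

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            enrichment_test(set(), {"a"}, {})

    def test_candidates_outside_background_error(self):
        with pytest.raises(ValueError):
            enrichment_test({"x"}, {"a"}, {})
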