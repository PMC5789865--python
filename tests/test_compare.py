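"""Cross-population statistics: Kruskal-Wallis, Dunn's, chi-square, ransacking."""

import math

import numpy as np
import pytest
from scipy.stats import chi2, norm

from poprisk import (DiseasePanel, GenotypeMatrix, chisq_single_snp, compare_all,
                     dunn_posthoc, kruskal_wallis, ransacking_critical_value,
                     ransacking_posthoc, simulate_genotypes)
from tests.conftest import make_marker


def dunn_z_oracle(groups, i, j):
    """Mean-rank Dunn z from first principles (manual ranking, tie-corrected)."""
    pooled = [x for g in groups for x in g]
    order = sorted(range(len(pooled)), key=lambda k: pooled[k])
    ranks = [0.0] * len(pooled)
    k = 0
    while k < len(order):
        tied = [order[k]]
        while k + len(tied) < len(order) and pooled[order[k + len(tied)]] == pooled[order[k]]:
            tied.append(order[k + len(tied)])
        avg = (2 * k + len(tied) + 1) / 2  # mean of ranks k+1 .. k+len(tied)
        for idx in tied:
            ranks[idx] = avg
        k += len(tied)
    n = len(pooled)
    bounds = [0]
    for g in groups:
        bounds.append(bounds[-1] + len(g))
    mean_ranks = [
        sum(ranks[bounds[a]:bounds[a + 1]]) / (bounds[a + 1] - bounds[a])
        for a in range(len(groups))
    ]
    from collections import Counter
    ties = Counter(pooled)
    tie_term = sum(t**3 - t for t in ties.values()) / (12 * (n - 1))
    var = (n * (n + 1) / 12 - tie_term) * (1 / len(groups[i]) + 1 / len(groups[j]))
    return (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)


class TestKruskalWallis:
    def test_hand_rank_example(self):
        # ranks 1..9 split into thirds: rank sums 6, 15, 24 give H = 7.2
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.h == pytest.approx(7.2)
        assert res.p == pytest.approx(float(chi2.sf(7.2, 2)))

    def test_all_identical_degenerate(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5], [5]])
        assert res.degenerate and res.p == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([[1, 2], []])

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=20), rng.normal(1, 1, size=25), rng.normal(size=15)]
        base = kruskal_wallis(groups)
        transformed = kruskal_wallis([np.exp(g) for g in groups])
        assert transformed.h == pytest.approx(base.h)

    def test_null_calibration(self, rng):
        # type-I error at alpha=0.05 over exchangeable null data
        n_reps, alpha = 2000, 0.05
        rejections = 0
        for _ in range(n_reps):
            data = rng.standard_normal((3, 25))
            if kruskal_wallis(list(data)).p < alpha:
                rejections += 1
        rate = rejections / n_reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_reps)


class TestDunn:
    def test_identical_groups_adjusted_p_one(self, rng):
        shared = list(rng.normal(size=30))
        others = [list(rng.normal(3, 1, size=30)), list(rng.normal(-3, 1, size=30))]
        pairs = dunn_posthoc([shared, shared.copy()] + others,
                             labels=["a", "b", "c", "d"])
        row = pairs[(pairs.pop_a == "a") & (pairs.pop_b == "b")]
        assert row.adjusted_p.iloc[0] == 1.0
        assert not row.significant.iloc[0]

    def test_bonferroni_never_below_unadjusted(self, rng):
        groups = [list(rng.normal(m, 1, size=12)) for m in (0, 0.5, 1)]
        pairs = dunn_posthoc(groups)
        for rec in pairs.itertuples():
            raw = 2 * norm.sf(abs(rec.statistic))
            assert rec.adjusted_p >= raw - 1e-12

    def test_z_matches_rank_arithmetic_oracle(self):
        groups = [[1.2, 3.4, 3.4, 5.0], [2.2, 3.4, 7.7], [0.1, 8.8, 9.9, 10.0, 4.4]]
        pairs = dunn_posthoc(groups, labels=["a", "b", "c"])
        for (i, j, la, lb) in [(0, 1, "a", "b"), (0, 2, "a", "c"), (1, 2, "b", "c")]:
            row = pairs[(pairs.pop_a == la) & (pairs.pop_b == lb)]
            assert row.statistic.iloc[0] == pytest.approx(
                dunn_z_oracle(groups, i, j), rel=1e-12
            )

    def test_two_groups_reduce_to_two_sample_case(self, rng):
        # with two groups Dunn has a single unadjusted pair; its significance
        # agrees with the omnibus at matched alpha
        for _ in range(50):
            groups = [list(rng.normal(0, 1, size=18)),
                      list(rng.normal(rng.uniform(0, 1.2), 1, size=22))]
            omnibus = kruskal_wallis(groups)
            pair = dunn_posthoc(groups).iloc[0]
            assert (omnibus.p < 0.05) == bool(pair.significant)

    def test_direction_reflects_mean_ranks(self, rng):
        groups = [list(rng.normal(5, 1, size=40)), list(rng.normal(0, 1, size=40))]
        pair = dunn_posthoc(groups, labels=["hi", "lo"]).iloc[0]
        assert pair.significant and pair.direction == "a_greater"


class TestChisq:
    def test_identical_rows_no_signal(self):
        stat, df, p = chisq_single_snp([[10, 20, 30], [10, 20, 30]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_pearson_2x2(self):
        # expected cells (20,80/20,80): chi2 = 5 + 1.25 + 5 + 1.25 = 12.5
        stat, df, p = chisq_single_snp([[10, 90], [30, 70]])
        assert stat == pytest.approx(12.5)
        assert df == 1
        assert p == pytest.approx(float(chi2.sf(12.5, 1)), rel=1e-9)

    def test_df_formula(self):
        stat, df, p = chisq_single_snp(np.ones((4, 3)) * 20)
        assert df == 6

    def test_low_expected_warns(self):
        with pytest.warns(UserWarning, match="expected"):
            chisq_single_snp([[0, 50], [1, 60]])

    def test_null_calibration(self, rng):
        n_reps, alpha, n = 2000, 0.05, 300
        probs = [0.49, 0.42, 0.09]  # HWE at p=0.3
        rejections = 0
        for _ in range(n_reps):
            table = rng.multinomial(n, probs, size=3)
            _, _, p = chisq_single_snp(table)
            if p < alpha:
                rejections += 1
        rate = rejections / n_reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_reps)


class TestRansacking:
    def test_critical_value_prints_as_2_8(self):
        crit = ransacking_critical_value(alpha=0.05, df_omnibus=3)
        assert crit == pytest.approx(2.795, abs=0.005)
        assert round(crit, 1) == 2.8

    def test_identical_frequencies_nonsignificant(self):
        pairs = ransacking_posthoc({"a": (30, 100), "b": (30, 100)})
        assert pairs.statistic.iloc[0] == 0.0
        assert not pairs.significant.iloc[0]

    def test_pooled_two_proportion_formula(self):
        x1, n1, x2, n2 = 150, 500, 225, 500  # freqs 0.30 vs 0.45
        pairs = ransacking_posthoc({"a": (x1, n1), "b": (x2, n2)})
        pool = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert pairs.statistic.iloc[0] == pytest.approx(z, rel=1e-12)
        assert abs(z) > 2.8 and pairs.significant.iloc[0]
        assert pairs.direction.iloc[0] == "b_greater"

    def test_zero_variance_degenerate_flag(self):
        pairs = ransacking_posthoc({"a": (0, 100), "b": (0, 100)})
        assert pairs.degenerate.iloc[0]
        assert not pairs.significant.iloc[0]


class TestCompareAll:
    def _panels(self):
        multi = DiseasePanel("multi", [
            make_marker(f"rs{i}", orx=1.4, risk_allele_freq={"discovery": 0.4})
            for i in range(3)
        ])
        single = DiseasePanel("single", [
            make_marker("rs9", orx=1.6, risk_allele_freq={"discovery": 0.4})
        ])
        return {"multi": multi, "single": single}

    def _cohort(self, freq_by_pop, n=200, seed=0):
        parts = []
        for k, (label, freqs) in enumerate(freq_by_pop.items()):
            parts.append(simulate_genotypes(
                freqs, n=n, seed=seed + k, population=label,
                rsids=["rs0", "rs1", "rs2", "rs9"], sample_prefix=label,
            ))
        return GenotypeMatrix.concat_samples(parts)

    def test_dispatch_by_panel_size(self):
        g = self._cohort({"a": [0.4] * 4, "b": [0.4] * 4})
        results = compare_all(self._panels(), g)
        methods = {r.disease_name: r.method for r in results}
        assert methods == {"multi": "kruskal_dunn", "single": "chisq_ransacking"}

    def test_planted_shift_detected_with_direction(self):
        g = self._cohort({"a": [0.25] * 4, "b": [0.55] * 4}, n=800, seed=3)
        results = compare_all(self._panels(), g)
        for r in results:
            assert r.omnibus_p < 0.05
            pair = r.pairs.iloc[0]
            assert pair.significant and pair.direction == "b_greater"

    def test_absent_population_errors(self):
        g = self._cohort({"a": [0.4] * 4, "b": [0.4] * 4})
        with pytest.raises(ValueError, match="ghost"):
            compare_all(self._panels(), g, populations=["a", "ghost"])

    def test_null_calibration_fraction(self, rng):
        # identical frequencies: each disease rejects at ~alpha
        panels = self._panels()
        rejections = {"multi": 0, "single": 0}
        n_reps = 120
        for rep in range(n_reps):
            g = self._cohort({"a": [0.4] * 4, "b": [0.4] * 4}, n=150,
                             seed=1000 + 7 * rep)
            for r in compare_all(panels, g):
                if r.omnibus_p < 0.05:
                    rejections[r.disease_name] += 1
        for name, count in rejections.items():
            rate = count / n_reps
            assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_reps), name
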