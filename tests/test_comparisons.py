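"""Sharing tables, discordant peaks, element classes, Spearman statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epienrich.annotations import GenomicInterval, merge_intervals
from epienrich.cheers import specificity_scores
from epienrich.comparisons import (
    classify_peak_elements,
    collapse_classes,
    discordant_peaks,
    selective_peaks,
    sharing_counts,
    spearman_exact,
    spearman_rho_from_s,
)


class TestSharingCounts:
    def test_two_disorder_example(self):
        tbl = sharing_counts({"A": {"p1", "p2"}, "B": {"p2"}})
        cells = dict(zip(tbl["disorders"], tbl["n_peaks"]))
        assert cells == {"A": 1, "A+B": 1}

    def test_single_disorder_single_cell(self):
        tbl = sharing_counts({"A": {"p1", "p2", "p3"}})
        assert tbl["n_peaks"].tolist() == [3]

    def test_cells_match_set_algebra_oracle_and_sum_to_total(self):
        rng = np.random.default_rng(70)
        peaks = [f"p{i}" for i in range(40)]
        overlaps = {d: set(rng.choice(peaks, size=rng.integers(5, 25),
                                      replace=False))
                    for d in "ABCD"}
        tbl = sharing_counts(overlaps)
        total = len(set().union(*overlaps.values()))
        assert tbl["n_peaks"].sum() == total
        for combo_len in range(1, 5):
            for combo in itertools.combinations("ABCD", combo_len):
                inside = set.intersection(*(overlaps[d] for d in combo))
                outside = set().union(*(overlaps[d] for d in "ABCD"
                                        if d not in combo), set())
                expected = len(inside - outside)
                row = tbl[tbl["disorders"] == "+".join(combo)]
                got = int(row["n_peaks"].iloc[0]) if len(row) else 0
                assert got == expected


@pytest.fixture()
def psm_random():
    rng = np.random.default_rng(71)
    return specificity_scores(rng.lognormal(size=(100, 3)),
                              quantile_normalize=False,
                              drop_bottom_fraction=0.0)


def _overlap_table(psm, idx):
    return pd.DataFrame({
        "peak_index": list(idx),
        "peak_id": psm.peaks["peak_id"].iloc[list(idx)].to_numpy(),
        "SNP": [f"v{i}" for i in range(len(idx))],
    })


class TestDiscordantPeaks:
    def test_identical_overlap_sets_give_empty_report(self, psm_random):
        sel = selective_peaks(psm_random, ["state_1"], 0.5)
        ov = _overlap_table(psm_random, sel[:5])
        rep = discordant_peaks(psm_random, ov, ov, states=["state_1"],
                               specificity_threshold=0.5)
        assert rep.a_not_b.empty and rep.b_not_a.empty

    def test_symmetric_difference_of_selective_peaks(self, psm_random):
        sel = selective_peaks(psm_random, ["state_1"], 0.5)
        ova = _overlap_table(psm_random, [sel[0]])
        ovb = _overlap_table(psm_random, [sel[1]])
        rep = discordant_peaks(psm_random, ova, ovb, states=["state_1"],
                               specificity_threshold=0.5)
        assert len(rep.a_not_b) == 1 and len(rep.b_not_a) == 1
        assert set(rep.a_not_b["peak_index"]).isdisjoint(
            rep.b_not_a["peak_index"])

    def test_matches_set_algebra_oracle(self, psm_random):
        rng = np.random.default_rng(72)
        thr, states = 0.7, ["state_2", "state_3"]
        ia = rng.choice(100, size=30, replace=False)
        ib = rng.choice(100, size=30, replace=False)
        rep = discordant_peaks(psm_random, _overlap_table(psm_random, ia),
                               _overlap_table(psm_random, ib),
                               states=states, specificity_threshold=thr)
        cols = [psm_random.state_index(s) for s in states]
        sel = {i for i in range(100)
               if (psm_random.norm_ranks[i, cols] > thr).any()}
        assert set(rep.a_not_b["peak_index"]) == (set(ia) & sel) - set(ib)
        assert set(rep.b_not_a["peak_index"]) == (set(ib) & sel) - set(ia)


class TestClassifyPeakElements:
    def _classes(self):
        return {
            "promoter": merge_intervals(
                [GenomicInterval("1", 100, 200)], "promoter"),
            "enhancer": merge_intervals(
                [GenomicInterval("1", 200, 300)], "enhancer"),
        }

    def test_peak_inside_promoter(self):
        peaks = pd.DataFrame({"peak_id": ["p"], "CHR": ["1"],
                              "start": [120], "end": [180]})
        assert classify_peak_elements(peaks, self._classes()) == \
            [frozenset({"promoter"})]

    def test_boundary_spanning_peak_gets_both_labels(self):
        peaks = pd.DataFrame({"peak_id": ["p"], "CHR": ["1"],
                              "start": [199], "end": [201]})
        # one bp in each element suffices
        assert classify_peak_elements(peaks, self._classes()) == \
            [frozenset({"promoter", "enhancer"})]

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(73)
        classes = {
            name: merge_intervals(
                [GenomicInterval("1", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(0, 9000, 20),
                                 rng.integers(1, 400, 20))], name)
            for name in ("promoter", "enhancer", "genic_enhancer")
        }
        peaks = pd.DataFrame({
            "peak_id": [f"p{i}" for i in range(50)],
            "CHR": "1",
            "start": rng.integers(0, 9500, 50),
        })
        peaks["end"] = peaks["start"] + rng.integers(1, 300, 50)
        got = classify_peak_elements(peaks, classes)
        base = {name: np.zeros(12_000, dtype=bool) for name in classes}
        for name, ann in classes.items():
            for s, e in ann.intervals["1"]:
                base[name][s:e] = True
        for i, row in peaks.iterrows():
            expected = frozenset(
                n for n, cov in base.items() if cov[row.start:row.end].any())
            assert got[i] == expected

    def test_priority_collapse(self):
        labels = [frozenset({"promoter", "enhancer"}),
                  frozenset({"enhancer", "genic_enhancer"}),
                  frozenset()]
        assert collapse_classes(labels) == \
            ["promoter", "genic_enhancer", "none"]


class TestSpearmanExact:
    def test_printed_rho_values_reconstructed_from_s(self):
        # S = 16, 120, 116 at n = 9 are the worked rank statistics
        assert round(spearman_rho_from_s(16, 9), 2) == 0.87
        assert spearman_rho_from_s(120, 9) == 0.0
        assert round(spearman_rho_from_s(116, 9), 2) == 0.03

    def _pairs_with_s(self, s_target, n=9, seed=0):
        rng = np.random.default_rng(seed)
        x = np.arange(1, n + 1, dtype=float)
        while True:
            y = rng.permutation(n) + 1.0
            if ((x - y) ** 2).sum() == s_target:
                return x, y

    def test_exact_p_matches_reference_for_s16(self):
        # independently verified with R cor.test(method="spearman",
        # exact=TRUE): S=16, n=9 -> p=0.004508, rho=0.866667
        x, y = self._pairs_with_s(16)
        r = spearman_exact(x, y, n_boot=100, seed=1)
        assert r.rho == pytest.approx(0.866667, abs=1e-6)
        assert r.p == pytest.approx(0.004508, abs=1e-5)

    def test_exact_p_is_one_at_rho_zero(self):
        x, y = self._pairs_with_s(120)
        r = spearman_exact(x, y, n_boot=100, seed=1)
        assert r.rho == 0.0 and r.p == 1.0

    def test_exact_p_for_s116(self):
        # R reference: p = 0.948391, rho = 0.033333
        x, y = self._pairs_with_s(116)
        r = spearman_exact(x, y, n_boot=100, seed=1)
        assert r.rho == pytest.approx(1 / 30, abs=1e-9)
        assert r.p == pytest.approx(0.948391, abs=1e-4)

    def test_identical_rankings_give_minimum_exact_p(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        r = spearman_exact(x, x * 2 + 1, n_boot=100, seed=1)
        assert r.s_statistic == 0.0 and r.rho == 1.0
        assert r.p == pytest.approx(2 / math.factorial(6))

    def test_agrees_with_permutation_oracle_for_small_n(self):
        # brute force: two-sided tail of |rho| over all n! permutations
        rng = np.random.default_rng(74)
        for n in (4, 5, 6, 7):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r = spearman_exact(x, y, n_boot=50, seed=1)
            rx = stats.rankdata(x)
            null = []
            for perm in itertools.permutations(stats.rankdata(y)):
                null.append(abs(stats.pearsonr(rx, perm).statistic))
            expected = np.mean(np.array(null) >= abs(r.rho) - 1e-12)
            assert r.p == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(75)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r1 = spearman_exact(x, y, n_boot=50, seed=3)
        r2 = spearman_exact(np.exp(x), y ** 3, n_boot=50, seed=3)
        assert r1.rho == pytest.approx(r2.rho)
        assert r1.p == pytest.approx(r2.p)

    def test_ties_fall_back_with_warning(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        with pytest.warns(UserWarning, match="ties"):
            r = spearman_exact(x, y, n_boot=50, seed=1)
        assert r.ties and r.p_method == "t-approx (ties)"
        expected = stats.spearmanr(x, y)
        assert r.rho == pytest.approx(expected.statistic)

    def test_bootstrap_ci_reproducible_and_contains_rho(self):
        rng = np.random.default_rng(76)
        x, y = rng.normal(size=9), rng.normal(size=9)
        r1 = spearman_exact(x, y, n_boot=2000, seed=42)
        r2 = spearman_exact(x, y, n_boot=2000, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.rho <= r1.ci_high

    def test_bootstrap_coverage_on_bivariate_normal(self):
        # nominal 95% percentile CI keeps >= 90% coverage at n = 9
        # (small-n undercoverage is expected)
        rng = np.random.default_rng(77)
        rho_true_r = 0.5  # Pearson rho of the generating normal
        rho_true = 6 / np.pi * np.arcsin(rho_true_r / 2)  # Spearman analogue
        cov = [[1, rho_true_r], [rho_true_r, 1]]
        hits = 0
        reps = 500
        for i in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=9)
            r = spearman_exact(xy[:, 0], xy[:, 1], n_boot=300, seed=i,
                               exact_max_n=0)  # CI only; skip enumeration
            hits += r.ci_low <= rho_true <= r.ci_high
        assert hits / reps >= 0.90

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            spearman_exact([1, 2], [3, 4])
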