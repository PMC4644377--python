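"""Differential binding: counting, moderation, permutation, clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from chromsig.diffbind import (
    CountMatrix,
    DiffBindParams,
    GroupDesign,
    cluster_samples,
    count_fragments_in_regions,
    enrichment_ratio_classifier,
    estimate_prior,
    moderated_differential_test,
    normalize_log_signal,
    permutation_robustness,
)
from chromsig.intervals import GenomicInterval
from chromsig.simulate import simulate_counts
from chromsig.stats import bh_fdr


def _design(n_a, n_b):
    labels = {f"A{i}": "A" for i in range(n_a)}
    labels.update({f"B{i}": "B" for i in range(n_b)})
    return GroupDesign(labels)


def _regions(n):
    return [GenomicInterval("chr1", i * 1000, i * 1000 + 400)
            for i in range(n)]


class TestCounting:
    def test_midpoint_membership(self):
        regions = [GenomicInterval("chr1", 150, 250)]
        frags = {"s": [GenomicInterval("chr1", 100, 300)]}  # midpoint 200
        cm = count_fragments_in_regions(frags, regions)
        assert cm.counts[0, 0] == 1
        assert cm.library_sizes[0] == 1

    def test_midpoint_at_region_end_excluded(self):
        regions = [GenomicInterval("chr1", 100, 200)]
        frags = {"s": [GenomicInterval("chr1", 150, 250)]}  # midpoint 200
        cm = count_fragments_in_regions(frags, regions)
        assert cm.counts[0, 0] == 0

    def test_matches_per_fragment_oracle(self, rng):
        regions = sorted(
            (GenomicInterval("chr1", int(s), int(s) + 300)
             for s in rng.choice(np.arange(0, 50_000, 400), 30, replace=False)),
            key=lambda iv: iv.start,
        )
        frags = {
            f"s{j}": [
                GenomicInterval("chr1", int(a), int(a) + 120)
                for a in rng.integers(0, 50_000, size=500)
            ]
            for j in range(3)
        }
        cm = count_fragments_in_regions(frags, regions)
        for j, sample in enumerate(cm.samples):
            for i, r in enumerate(cm.regions):
                expected = sum(
                    r.start <= f.midpoint < r.end for f in frags[sample]
                )
                assert cm.counts[i, j] == expected

    def test_disjoint_regions_conserve_fragments(self, rng):
        regions = _regions(20)
        frags = {"s": [GenomicInterval("chr1", int(a), int(a) + 50)
                       for a in rng.integers(0, 25_000, size=800)]}
        cm = count_fragments_in_regions(frags, regions)
        assert cm.counts.sum() <= 800

    def test_empty_sample_warns_and_zero_column(self):
        regions = _regions(3)
        with pytest.warns(UserWarning, match="no fragments"):
            cm = count_fragments_in_regions({"empty": []}, regions)
        assert (cm.counts == 0).all()


class TestNormalization:
    def test_closed_forms(self):
        cm = CountMatrix(_regions(2), ["s"], np.array([[0], [1000]]),
                         np.array([1e6]))
        y = normalize_log_signal(cm)
        assert y[0, 0] == pytest.approx(math.log2(0.5))
        assert y[1, 0] == pytest.approx(math.log2(1000.5))

    def test_depth_scale_invariance(self, rng):
        # exact up to the half-count offset, which becomes negligible
        # away from zero counts
        counts = rng.integers(50, 500, size=(30, 4))
        cm1 = CountMatrix(_regions(30), list("abcd"), counts,
                          np.full(4, 1e6))
        cm2 = CountMatrix(_regions(30), list("abcd"), counts * 2,
                          np.full(4, 2e6))
        np.testing.assert_allclose(
            normalize_log_signal(cm1), normalize_log_signal(cm2), atol=0.01
        )


class TestModeratedTest:
    def _simulated(self, seed=0, n_diff=0, fold=1.0, n_regions=2000,
                   n_a=5, n_b=3):
        design = _design(n_a, n_b)
        cm, truth = simulate_counts(
            _regions(n_regions), design, n_diff=n_diff, fold_change=fold,
            dispersion=0.05, seed=seed,
        )
        return cm, design, truth

    def test_null_has_no_discoveries(self):
        cm, design, _ = self._simulated(seed=1, fold=1.0)
        res = moderated_differential_test(cm, design)
        assert res.n_significant / len(res.table) < 0.01

    def test_planted_recall(self):
        cm, design, truth = self._simulated(seed=2, n_diff=200, fold=4.0)
        res = moderated_differential_test(cm, design)
        sig = set(np.flatnonzero(res.table["direction"].to_numpy() != "ns"))
        recall = len(sig & set(truth.differential_indices)) / 200
        assert recall >= 0.8

    def test_label_swap_antisymmetry(self):
        cm, design, _ = self._simulated(seed=3, n_diff=50, fold=3.0,
                                        n_regions=300)
        res = moderated_differential_test(cm, design)
        flipped = GroupDesign(
            {s: ("A" if g == "B" else "B")
             for s, g in design.group_of.items()}
        )
        res2 = moderated_differential_test(cm, flipped)
        np.testing.assert_allclose(res.table["t_mod"], -res2.table["t_mod"],
                                   rtol=1e-10)
        np.testing.assert_allclose(res.table["p_value"],
                                   res2.table["p_value"], rtol=1e-10)

    def test_prior_df_limits(self):
        cm, design, _ = self._simulated(seed=4, n_regions=400)
        y_params_inf = DiffBindParams(prior_df=np.inf)
        y_params_zero = DiffBindParams(prior_df=0.0)
        res_inf = moderated_differential_test(cm, design, y_params_inf)
        res_zero = moderated_differential_test(cm, design, y_params_zero)
        # d0 = 0 reproduces the ordinary t-test
        from scipy import stats as sps

        y = normalize_log_signal(cm)
        t_ord, p_ord = sps.ttest_ind(y[:, :5], y[:, 5:], axis=1)
        np.testing.assert_allclose(res_zero.table["t_mod"], t_ord,
                                   rtol=1e-8)
        # d0 = inf pools every region to one variance (z-like statistic)
        delta = res_inf.table["mean_log2_A"] - res_inf.table["mean_log2_B"]
        ratio = res_inf.table["t_mod"] / delta
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_q_values_match_bh_oracle(self):
        cm, design, _ = self._simulated(seed=5, n_regions=500, n_diff=40,
                                        fold=3.0)
        res = moderated_differential_test(cm, design)
        np.testing.assert_allclose(
            res.table["q_value"], bh_fdr(res.table["p_value"].to_numpy())
        )

    def test_empirical_fdr_controlled(self):
        # 10% planted 4-fold effects; empirical FDR at q<=0.10 stays <= 0.15
        fdrs = []
        for seed in (10, 11, 12):
            cm, design, truth = self._simulated(seed=seed, n_diff=200,
                                                fold=4.0)
            res = moderated_differential_test(cm, design)
            sig = set(np.flatnonzero(
                res.table["direction"].to_numpy() != "ns"))
            if sig:
                fp = len(sig - set(truth.differential_indices))
                fdrs.append(fp / len(sig))
        assert np.mean(fdrs) <= 0.15

    def test_few_regions_falls_back_to_ordinary_t(self):
        cm, design, _ = self._simulated(seed=6, n_regions=5)
        with pytest.warns(UserWarning, match="ordinary t"):
            res = moderated_differential_test(cm, design)
        assert not res.moderated

    def test_small_groups_rejected(self):
        design = _design(1, 3)
        cm, _, _ = self._simulated(seed=7, n_regions=20)
        with pytest.raises(ValueError, match="two samples per group"):
            moderated_differential_test(cm, design)


class TestPriorEstimation:
    def test_recovers_known_prior(self, rng):
        d0_true, s0_true, d = 8.0, 0.25, 6
        s2 = (
            s0_true * d0_true / rng.chisquare(d0_true, size=4000)
        ) * rng.chisquare(d, size=4000) / d
        d0_hat, s0_hat = estimate_prior(s2, d)
        assert d0_hat == pytest.approx(d0_true, rel=0.25)
        assert s0_hat == pytest.approx(s0_true, rel=0.1)

    def test_homogeneous_variances_give_infinite_prior(self, rng):
        # chi-square spread alone (no extra variance heterogeneity)
        s2 = rng.chisquare(6, size=3000) / 6 * 0.3
        d0_hat, _ = estimate_prior(s2, 6)
        assert d0_hat > 50 or math.isinf(d0_hat)


class TestPermutationRobustness:
    def test_enumerates_56_distinct_relabelings(self):
        cm, _ = simulate_counts(_regions(50), _design(5, 3), n_diff=5,
                                fold_change=4.0, seed=0)
        report = permutation_robustness(cm, _design(5, 3))
        assert report.n_relabelings == math.comb(8, 3) == 56
        assert report.table["group_b"].nunique() == 56
        assert report.table["is_true"].sum() == 1

    def test_true_labeling_ranks_first_on_planted_signal(self):
        design = _design(5, 3)
        cm, _ = simulate_counts(_regions(400), design, n_diff=40,
                                fold_change=4.0, seed=8)
        report = permutation_robustness(cm, design)
        assert report.true_rank == 1

    def test_null_rank_not_extreme(self):
        design = _design(5, 3)
        cm, _ = simulate_counts(_regions(400), design, fold_change=1.0,
                                seed=9)
        report = permutation_robustness(cm, design)
        true_n = report.table.loc[report.table["is_true"],
                                  "n_significant"].iloc[0]
        assert true_n <= report.table["n_significant"].max()

    def test_too_many_relabelings_rejected(self):
        design = _design(10, 8)
        cm, _ = simulate_counts(_regions(10), design, seed=0)
        with pytest.raises(ValueError, match="subsample"):
            permutation_robustness(cm, design)


class TestClustering:
    def test_recovers_planted_groups(self, rng):
        n_regions = 100
        base = rng.normal(100, 5, size=n_regions)
        counts = np.empty((n_regions, 8))
        shift = np.ones(n_regions)
        shift[:50] = 6.0  # group-B regions strongly enriched
        for j in range(8):
            mean = base * (shift if j >= 5 else 1.0)
            counts[:, j] = rng.poisson(mean)
        cm = CountMatrix(_regions(n_regions),
                         [f"s{j}" for j in range(8)], counts.astype(int),
                         np.full(8, 1e6))
        _, labels = cluster_samples(cm)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_duplicate_samples_merge_first(self, rng):
        counts = rng.integers(10, 100, size=(50, 3))
        counts = np.hstack([counts, counts[:, [0]]])  # s3 duplicates s0
        cm = CountMatrix(_regions(50), ["s0", "s1", "s2", "s3"], counts,
                         np.full(4, 1e6))
        linkage, _ = cluster_samples(cm)
        first = sorted(linkage[0, :2])
        assert first == [0, 3]

    def test_zero_variance_sample_rejected(self):
        counts = np.array([[5, 5], [5, 9], [5, 2]])
        cm = CountMatrix(_regions(3), ["flat", "ok"], counts,
                         np.full(2, 1e6))
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(cm)


class TestRatioClassifier:
    def test_arithmetic_and_tie_rule(self):
        enr = pd.DataFrame(
            {"p1": [4.0, 2.0], "p2": [4.0, 2.0],
             "r1": [2.0, 2.0], "r2": [2.0, 2.0]},
            index=["high", "tie"],
        )
        out = enrichment_ratio_classifier(enr, ["p1", "p2"], ["r1", "r2"])
        assert out.loc["high", "ratio"] == pytest.approx(2.0)
        assert out.loc["high", "label"] == "primary-like"
        # ratio exactly 1 is labeled resistant-like (tie rule: not > 1)
        assert out.loc["tie", "label"] == "resistant-like"

    def test_zero_denominator_flagged_inf(self):
        enr = pd.DataFrame({"p": [3.0], "r": [0.0]}, index=["s"])
        out = enrichment_ratio_classifier(enr, ["p"], ["r"])
        assert math.isinf(out.loc["s", "ratio"])
        assert out.loc["s", "label"] == "primary-like"
        assert bool(out.loc["s", "flagged"])

    def test_simulated_validation_accuracy(self, rng):
        # two-fold planted separation between group profiles
        n = 40
        rows = []
        labels = []
        for i in range(n):
            primary = i < n // 2
            p_mean, r_mean = (4.0, 2.0) if primary else (2.0, 4.0)
            rows.append(
                np.concatenate([
                    rng.gamma(9, p_mean / 9, size=5),
                    rng.gamma(9, r_mean / 9, size=5),
                ])
            )
            labels.append("primary-like" if primary else "resistant-like")
        enr = pd.DataFrame(
            rows, columns=[f"p{i}" for i in range(5)]
            + [f"r{i}" for i in range(5)],
        )
        out = enrichment_ratio_classifier(
            enr, [f"p{i}" for i in range(5)], [f"r{i}" for i in range(5)]
        )
        acc = (out["label"].to_numpy() == np.array(labels)).mean()
        assert acc >= 0.9


class TestCountMatrixIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        cm = CountMatrix(_regions(5), ["a", "b"],
                         rng.integers(0, 50, size=(5, 2)),
                         np.array([1e6, 2e6]))
        path = tmp_path / "cm.tsv"
        cm.to_tsv(path)
        back = CountMatrix.from_tsv(path)
        np.testing.assert_array_equal(back.counts, cm.counts)
        np.testing.assert_array_equal(back.library_sizes, cm.library_sizes)
        assert back.region_keys == cm.region_keys

    def test_library_size_invariant(self):
        with pytest.raises(ValueError, match="library sizes"):
            CountMatrix(_regions(2), ["s"], np.array([[5], [6]]),
                        np.array([10.0]))
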