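"""Survival analytics: KM, log-rank, Cox, AUC, D'Amico, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from chromsig.survival import (
    auc_at_horizon,
    center_expression,
    cluster_patients,
    cox_fit,
    damico_classify,
    encode_clinical,
    km_curve,
    logrank_test,
    multivariate_adjustment,
    pca_projection,
    prognostic_index,
)
from tests.conftest import simulate_survival


class TestCenterExpression:
    def test_centering_and_idempotence(self):
        df = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "g2": [4.0, 4.0, 4.0]})
        c = center_expression(df)
        np.testing.assert_allclose(c["g1"], [-1, 0, 1])
        pd.testing.assert_frame_equal(center_expression(c), c)

    def test_probe_averaging(self):
        df = pd.DataFrame({"p1": [1.0, 3.0], "p2": [3.0, 5.0]})
        c = center_expression(df, probe_to_gene={"p1": "G", "p2": "G"})
        np.testing.assert_allclose(c["G"], [-1, 1])


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        km = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        s = km.set_index("time")["survival"]
        assert s.loc[2.0] == pytest.approx(0.5)
        assert s.loc[4.0] == pytest.approx(0.0)

    def test_all_censored_is_flat_one(self):
        km = km_curve([5.0], [0])
        assert (km["survival"] == 1.0).all()
        assert km.attrs["all_censored"]

    def test_worked_six_patient_table(self):
        # hand computation: events at 2 (1/6), 4 (1/4), 7 (1/2);
        # censored at 3, 5; S(7) = 5/6 * 3/4 * 1/2 = 0.3125
        time = [2, 3, 4, 5, 7, 8]
        event = [1, 0, 1, 0, 1, 0]
        km = km_curve(time, event).set_index("time")["survival"]
        assert km.loc[2.0] == pytest.approx(5 / 6)
        assert km.loc[4.0] == pytest.approx(5 / 6 * 3 / 4)
        assert km.loc[7.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)


def _logrank_oracle(time, event, groups):
    """Hand-built O/E/V table summation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    g1 = groups == np.unique(groups)[0]
    num = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        n = (time >= t).sum()
        n1 = ((time >= t) & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else num**2 / var


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_group_swap_symmetry(self, rng):
        t = rng.exponential(size=30)
        e = rng.integers(0, 2, size=30)
        g = rng.integers(0, 2, size=30)
        if len(set(g)) < 2:
            g[0] = 1 - g[0]
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic)

    def test_exhaustive_small_instances_match_oracle(self):
        # every assignment of 8 patients into two nonempty groups on a
        # fixed survival table
        time = [1, 2, 3, 4, 5, 6, 7, 8]
        event = [1, 0, 1, 1, 0, 1, 1, 0]
        for bits in range(1, 2**7):  # patient 0 fixed to group 0
            groups = [0] + [(bits >> i) & 1 for i in range(7)]
            if len(set(groups)) < 2:
                continue
            res = logrank_test(time, event, groups)
            assert res.statistic == pytest.approx(
                _logrank_oracle(time, event, groups), abs=1e-9
            )

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll

        t = rng.exponential(size=100)
        e = rng.integers(0, 2, size=100)
        g = rng.integers(0, 2, size=100)
        ours = logrank_test(t, e, g)
        theirs = ll(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert ours.statistic == pytest.approx(theirs.test_statistic)
        assert ours.p == pytest.approx(theirs.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCoxFit:
    def test_null_covariate_near_zero(self):
        X, t, e = simulate_survival(1500, [0.0], 2.0, seed=0)
        fit = cox_fit(X, t, e)
        assert abs(fit.coef[0]) < 3 * fit.se[0]

    def test_parameter_recovery(self):
        X, t, e = simulate_survival(2000, [0.7], 2.33, seed=1)
        fit = cox_fit(X, t, e)
        assert fit.coef[0] == pytest.approx(0.7, abs=0.1)

    def test_score_vanishes_at_optimum(self):
        from chromsig.survival import _cox_stats

        X, t, e = simulate_survival(500, [0.5, -0.3], 2.0, seed=2)
        fit = cox_fit(X, t, e)
        _, grad, _ = _cox_stats(X, t, e, fit.coef)
        assert np.linalg.norm(grad) < 1e-6

    def test_matches_lifelines_with_ties(self, rng):
        import lifelines

        n = 120
        X = rng.standard_normal((n, 2))
        t = rng.integers(1, 15, size=n).astype(float)  # heavy ties
        e = rng.integers(0, 2, size=n)
        e[:2] = 1
        fit = cox_fit(X, t, e)
        cph = lifelines.CoxPHFitter()
        df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "t": t, "e": e})
        cph.fit(df, "t", "e")  # lifelines uses Efron ties too
        np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values,
                                   atol=1e-5)

    def test_hazard_ratio_ci(self):
        X, t, e = simulate_survival(300, [0.6], 2.0, seed=3)
        fit = cox_fit(X, t, e)
        assert fit.hr[0] == pytest.approx(math.exp(fit.coef[0]))
        assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]

    def test_constant_covariate_rejected(self):
        X, t, e = simulate_survival(50, [0.5], 2.0, seed=4, p=2)
        X[:, 1] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(X, t, e)

    def test_separation_detected(self):
        # covariate perfectly ordered with event time -> monotone likelihood
        n = 30
        t = np.arange(1, n + 1, dtype=float)
        e = np.ones(n, dtype=int)
        x = -t
        with pytest.raises(ValueError):
            cox_fit(x, t, e)


class TestPrognosticIndex:
    def test_boundary_is_low_risk(self):
        pi, grp = prognostic_index(
            pd.Series({"a": 2.0, "b": 1.0}), {"a": 0.5, "b": -1.0}
        )
        assert pi == 0.0 and grp == "low"

    def test_bilinearity(self):
        row = pd.Series({"a": 1.5, "b": -2.0})
        coef = {"a": 0.3, "b": 0.7}
        pi, _ = prognostic_index(row, coef)
        pi_neg, _ = prognostic_index(-row, {g: -c for g, c in coef.items()})
        assert pi == pytest.approx(pi_neg)

    def test_missing_gene_listed(self):
        with pytest.raises(KeyError, match="missing"):
            prognostic_index(pd.Series({"a": 1.0}), {"a": 1.0, "b": 2.0})

    def test_dataframe_form(self):
        df = pd.DataFrame({"a": [1.0, -1.0]}, index=["p1", "p2"])
        out = prognostic_index(df, {"a": 1.0})
        assert list(out["risk_group"]) == ["high", "low"]


class TestAucAtHorizon:
    def test_perfect_separation(self):
        pi = np.array([3.0, 2.5, 0.1, 0.0])
        t = np.array([10, 20, 100, 100])
        e = np.array([1, 1, 0, 0])
        assert auc_at_horizon(pi, t, e, horizon=60) == 1.0

    def test_null_score_near_half(self, rng):
        n = 2000
        pi = rng.normal(size=n)
        t = rng.exponential(60, size=n)
        e = rng.integers(0, 2, size=n)
        auc = auc_at_horizon(pi, t, e, horizon=60)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_monotone_transform_invariance(self, rng):
        pi = rng.normal(size=200)
        t = rng.exponential(60, size=200)
        e = rng.integers(0, 2, size=200)
        a = auc_at_horizon(pi, t, e)
        b = auc_at_horizon(np.exp(2 * pi), t, e)
        assert a == pytest.approx(b)

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError):
            auc_at_horizon([1, 2], [100, 120], [0, 0], horizon=60)


class TestDamico:
    @pytest.mark.parametrize(
        "ct,gleason,psa,expected",
        [
            ("T1c", 6, 5.0, "low"),
            ("T2a", 7, 6.0, "intermediate"),
            ("T2b", 6, 5.0, "intermediate"),
            ("T1c", 6, 12.0, "intermediate"),
            ("T2a", 6, 25.0, "high"),
            ("T2c", 6, 5.0, "high"),
            ("T1c", 8, 5.0, "high"),
            ("T3a", 6, 4.0, "high"),
        ],
    )
    def test_rule_table(self, ct, gleason, psa, expected):
        assert damico_classify(ct, gleason, psa) == expected

    def test_unparseable_stage_rejected(self):
        with pytest.raises(ValueError, match="unparseable"):
            damico_classify("stage-?", 6, 5.0)


class TestPCA:
    def test_group_shift_separates_on_pc1(self, rng):
        n = 40
        x = rng.normal(size=(n, 5)) * 0.3
        x[: n // 2, 0] += 4.0
        df = pd.DataFrame(x, columns=[f"g{i}" for i in range(5)])
        scores = pca_projection(df, [f"g{i}" for i in range(5)])
        pc1 = scores["PC1"].to_numpy()
        assert abs(pc1[: n // 2].mean() - pc1[n // 2 :].mean()) > 2.0

    def test_component_variance_ordering_and_shift_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 6)),
                          columns=[f"g{i}" for i in range(6)])
        s1 = pca_projection(df, list(df.columns))
        assert s1["PC1"].var() >= s1["PC2"].var()
        s2 = pca_projection(df + 7.0, list(df.columns))
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)


class TestPatientClustering:
    def test_recovers_opposite_populations(self, rng):
        n = 30
        x = rng.normal(size=(n, 8)) * 0.2
        x[: n // 2] += np.linspace(-2, 2, 8)
        x[n // 2 :] -= np.linspace(-2, 2, 8)
        df = pd.DataFrame(x, columns=[f"g{i}" for i in range(8)])
        labels = cluster_patients(df, list(df.columns))
        assert len(set(labels[: n // 2])) == 1
        assert labels[0] != labels[-1]

    def test_missing_genes_warn(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="absent"):
            cluster_patients(df, ["a", "b", "zzz"])


class TestMultivariateAdjustment:
    def _cohort(self, confounded, seed):
        from chromsig.simulate import simulate_cohort

        cohort, truth = simulate_cohort(
            n_patients=600, n_genes=10, n_signature=2,
            beta_range=(0.8, 1.0), censoring_rate=0.3,
            clinical_model="confounded" if confounded else "independent",
            seed=seed,
        )
        return cohort, truth

    def test_independent_pi_keeps_marginal_effect(self):
        cohort, truth = self._cohort(False, 0)
        pi = truth.linear_predictor
        marginal = cox_fit(pi, cohort.time, cohort.event)
        adjusted = multivariate_adjustment(
            pi, cohort.clinical, cohort.time, cohort.event
        )
        assert adjusted.coef[0] == pytest.approx(marginal.coef[0], abs=0.1)

    def test_confounded_pi_shrinks(self):
        cohort, truth = self._cohort(True, 1)
        # a PI that is a pure function of Gleason: its adjusted effect
        # must shrink toward zero once Gleason is in the model
        gleason = cohort.clinical["gleason"].to_numpy(float)
        pi = gleason - gleason.mean()
        marginal = cox_fit(pi, cohort.time, cohort.event)
        adjusted = multivariate_adjustment(
            pi, cohort.clinical, cohort.time, cohort.event
        )
        assert abs(adjusted.coef[0]) < abs(marginal.coef[0])

    def test_constant_clinical_rejected(self):
        cohort, truth = self._cohort(False, 2)
        clin = cohort.clinical.copy()
        clin["gleason"] = 7
        clin["pT"] = "T2a"
        clin["pN"] = 0
        clin["psa"] = 10.0
        with pytest.raises(ValueError, match="constant"):
            multivariate_adjustment(
                truth.linear_predictor, clin, cohort.time, cohort.event
            )

    def test_clinical_encoding(self):
        clin = pd.DataFrame(
            {"gleason": [6, 8], "pT": ["T2a", "T3b"], "pN": [0, 1],
             "psa": [8.0, 16.0]}
        )
        enc = encode_clinical(clin)
        assert enc["t_stage"].iloc[1] > enc["t_stage"].iloc[0]
        assert enc["node_positive"].tolist() == [0.0, 1.0]
        assert enc["log2_psa"].iloc[1] - enc["log2_psa"].iloc[0] == (
            pytest.approx(1.0)
        )
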