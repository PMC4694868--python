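"""Cox score, Kaplan-Meier, log-rank, and risk stratification."""

import numpy as np
import pandas as pd
import pytest
from _oracles import brute_cox, brute_km, brute_logrank
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from ertarget.survival import (
    Cohort,
    cox_score,
    cox_scores,
    km_estimate,
    kmeans2_risk_groups,
    logrank_test,
    median_split,
    select_genes_by_cox,
    single_gene_km,
    subgroup,
)
from conftest import survival_data


def make_cohort(rng, n=60, n_genes=5, er=None, her2=None, time=None, event=None):
    if time is None:
        time, event = survival_data(rng, n)
    expr = pd.DataFrame(
        rng.normal(size=(n, n_genes)),
        index=[f"P{i}" for i in range(n)],
        columns=[f"G{i}" for i in range(n_genes)],
    )
    return Cohort(
        patient_ids=list(expr.index),
        expr=expr,
        er_status=np.array(er if er is not None else ["positive"] * n, dtype=object),
        her2_status=np.array(her2 if her2 is not None else ["negative"] * n, dtype=object),
        time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=np.int64),
    )


class TestCoxScore:
    def test_constant_expression_is_degenerate_zero(self, rng):
        time, event = survival_data(rng, 20)
        res = cox_score(np.ones(20), time, event)
        assert res.score == 0.0 and res.degenerate

    def test_permutation_invariance(self, rng):
        time, event = survival_data(rng, 40)
        x = rng.normal(size=40)
        s0 = cox_score(x, time, event).score
        perm = rng.permutation(40)
        assert cox_score(x[perm], time[perm], event[perm]).score == pytest.approx(s0, abs=1e-12)

    def test_sign_flips_with_negated_expression(self, rng):
        time, event = survival_data(rng, 50)
        x = rng.normal(size=50)
        assert cox_score(-x, time, event).score == pytest.approx(
            -cox_score(x, time, event).score, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        time, event = survival_data(rng, n, censor_rate=0.05)
        if rng.uniform() < 0.5:  # exercise Breslow tie handling
            time = np.ceil(time * 3) / 3
        x = rng.normal(size=n)
        assert cox_score(x, time, event).score == pytest.approx(
            brute_cox(x, time, event), abs=1e-10
        )

    def test_matches_partial_likelihood_score_gradient(self, rng):
        """U and I agree with numerical derivatives of the Breslow partial
        log-likelihood at β = 0 — an independent route to the same statistic."""
        n = 50
        time, event = survival_data(rng, n)
        x = rng.normal(size=n)

        def pll(beta):
            ll = 0.0
            for i in range(n):
                if event[i] == 1:
                    risk = time >= time[i]
                    ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        h = 1e-5
        U_num = (pll(h) - pll(-h)) / (2 * h)
        I_num = -(pll(h) - 2 * pll(0.0) + pll(-h)) / h**2
        assert cox_score(x, time, event).score == pytest.approx(
            U_num / np.sqrt(I_num), rel=1e-5
        )

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            cox_score([1.0, 2.0], [1.0, 2.0], [0, 0])

    def test_score_grows_with_sqrt_events_under_planted_hazard(self):
        """Mean score across replicates ≈ β·√D under proportional hazards."""
        beta = 0.5
        means = {}
        for n in (100, 400):
            scores, events = [], []
            for s in range(40):
                rng = np.random.default_rng(1000 + 7 * n + s)
                x = rng.normal(size=n)
                z = (x - x.mean()) / x.std()
                t = rng.exponential(1.0 / (0.1 * np.exp(beta * z)))
                e = np.ones(n, dtype=int)
                scores.append(cox_score(z, t, e).score)
                events.append(n)
            means[n] = np.mean(scores) / np.sqrt(np.mean(events))
        # the normalized mean (score per √events) is stable across n and ≈ β
        assert means[100] == pytest.approx(beta, rel=0.25)
        assert means[400] == pytest.approx(beta, rel=0.25)


class TestSelectGenesByCox:
    def test_null_pass_fraction_matches_normal_tail(self, rng):
        n, g = 300, 5000
        time, event = survival_data(rng, n, censor_rate=0.03)
        X = rng.normal(size=(g, n))
        s, _ = cox_scores(X, time, event)
        frac = np.mean(np.abs(s) >= 2.39)
        assert 0.010 <= frac <= 0.025  # two-tailed normal at 2.39 ≈ 0.0169

    def test_planted_gene_selected_with_high_power(self):
        hits = 0
        n_sims = 60
        for s in range(n_sims):
            rng = np.random.default_rng(5000 + s)
            n = 570
            x = rng.normal(size=n)
            z = (x - x.mean()) / x.std()
            t = rng.exponential(1.0 / (0.1 * np.exp(0.2 * z)))
            cens = rng.exponential(1.0 / 0.043, size=n)
            time, event = np.minimum(t, cens), (t <= cens).astype(int)
            cohort = make_cohort(rng, n=n, n_genes=1, time=time, event=event)
            cohort.expr["G0"] = x
            if len(select_genes_by_cox(cohort, ["G0"], cutoff=2.39)):
                hits += 1
        assert hits / n_sims >= 0.90

    def test_cutoff_zero_returns_all_ranked(self, rng):
        cohort = make_cohort(rng, n=80, n_genes=10)
        out = select_genes_by_cox(cohort, cutoff=0.0)
        assert len(out) == 10
        assert list(out["abs_score"]) == sorted(out["abs_score"], reverse=True)


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        assert list(median_split([1, 2, 2, 3])) == ["low", "low", "low", "high"]

    def test_odd_length_distinct_values(self, rng):
        x = rng.permutation(np.arange(31, dtype=float))
        labels = median_split(x)
        assert (labels == "low").sum() == 16  # (n+1)/2 for distinct values

    def test_constant_vector_degenerate(self):
        with pytest.raises(ValueError):
            median_split([2.0, 2.0, 2.0])


class TestKmeans2RiskGroups:
    def test_recovers_well_separated_clusters(self, rng):
        n = 60
        centers = np.array([0.0, 6.0])  # 6 SD separation
        assign = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 3)) + centers[assign][:, None]
        time, event = survival_data(rng, n)
        labels = kmeans2_risk_groups(pd.DataFrame(X), time, event, seed=0)
        # recovered partition equals planted partition (up to label swap)
        a = labels == labels[0]
        b = assign == assign[0]
        assert np.array_equal(a, b) or np.array_equal(a, ~b)

    def test_duplicating_patients_keeps_partition(self, rng):
        n = 30
        X = rng.normal(size=(n, 2)) + np.array([0.0, 5.0])[rng.integers(0, 2, n)][:, None]
        time, event = survival_data(rng, n)
        l1 = kmeans2_risk_groups(pd.DataFrame(X), time, event, seed=1)
        X2 = np.vstack([X, X])
        l2 = kmeans2_risk_groups(
            pd.DataFrame(X2), np.concatenate([time, time]), np.concatenate([event, event]), seed=1
        )
        same = np.array_equal(l2[:n] == "high_risk", l1 == "high_risk")
        assert same

    def test_single_gene_panel_is_a_threshold_rule(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 25), rng.normal(6, 0.5, 25)])
        time, event = survival_data(rng, 50)
        labels = kmeans2_risk_groups(pd.DataFrame(x[:, None]), time, event, seed=0)
        one = x[labels == labels[0]]
        other = x[labels != labels[0]]
        assert max(one.max(), other.max()) == x.max()
        assert one.max() < other.min() or other.max() < one.min()

    def test_high_risk_cluster_has_lower_terminal_survival(self, rng):
        n = 80
        assign = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 2)) + np.array([0.0, 6.0])[assign][:, None]
        # cluster 1 has much higher hazard
        t = rng.exponential(1.0 / np.where(assign == 1, 1.0, 0.05))
        e = np.ones(n, dtype=int)
        labels = kmeans2_risk_groups(pd.DataFrame(X), t, e, seed=0)
        assert (labels[assign == 1] == "high_risk").all()

    def test_identical_profiles_degenerate(self):
        with pytest.raises(ValueError):
            kmeans2_risk_groups(pd.DataFrame(np.ones((5, 2))), np.ones(5), np.ones(5, int))


class TestKMEstimate:
    def test_all_censored_flat_curve(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.times.size == 0

    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3, 4, 5], [1, 1, 0, 1, 0])
        assert list(curve.times) == [1, 2, 4]
        assert curve.survival == pytest.approx([4 / 5, 3 / 5, 3 / 10])
        assert list(curve.at_risk) == [5, 4, 2]

    def test_survival_monotone_nonincreasing(self, rng):
        time, event = survival_data(rng, 200, censor_rate=0.08)
        curve = km_estimate(time, event)
        assert np.all(np.diff(curve.survival) <= 0) and curve.survival[0] <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines_reference(self, seed):
        rng = np.random.default_rng(300 + seed)
        time, event = survival_data(rng, 150, censor_rate=0.08)
        time = np.ceil(time * 4) / 4  # force ties
        curve = km_estimate(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        ref = kmf.survival_function_at_times(curve.times).to_numpy()
        assert curve.survival == pytest.approx(ref, abs=1e-12)
        oracle = brute_km(time, event)
        assert curve.survival == pytest.approx([s for _, s, _, _ in oracle], abs=1e-12)

    def test_time_scaling_invariance(self, rng):
        time, event = survival_data(rng, 100)
        c1 = km_estimate(time, event)
        c2 = km_estimate(time * 3.5, event)
        assert c2.times == pytest.approx(c1.times * 3.5)
        assert c2.survival == pytest.approx(c1.survival)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null(self):
        time = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        groups = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        comp = logrank_test(time, event, groups)
        assert comp.statistic == pytest.approx(0.0, abs=1e-12) and comp.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_hypergeometric_oracle_and_lifelines(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(20, 200))
        time, event = survival_data(rng, n, censor_rate=0.05)
        if seed % 2:
            time = np.ceil(time)  # ties across groups
        groups = np.where(rng.uniform(size=n) < 0.5, "g1", "g2").astype(object)
        if len(set(groups)) < 2:
            groups[0] = "g1" if groups[1] == "g2" else "g2"
        comp = logrank_test(time, event, groups)
        assert comp.statistic == pytest.approx(
            brute_logrank(time, event, groups == "g1"), abs=1e-10
        )
        ref = ll_logrank(time[groups == "g1"], time[groups == "g2"],
                         event[groups == "g1"], event[groups == "g2"])
        assert comp.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
        assert comp.pvalue == pytest.approx(ref.p_value, abs=1e-10)

    def test_label_swap_invariance(self, rng):
        time, event = survival_data(rng, 80)
        groups = np.where(rng.uniform(size=80) < 0.4, "x", "y").astype(object)
        swapped = np.where(groups == "x", "y", "x").astype(object)
        assert logrank_test(time, event, groups).statistic == pytest.approx(
            logrank_test(time, event, swapped).statistic, abs=1e-12
        )

    def test_null_rejection_rate_calibrated(self):
        rejections = 0
        reps = 400
        for s in range(reps):
            rng = np.random.default_rng(7000 + s)
            time, event = survival_data(rng, 200, censor_rate=0.03)
            groups = np.where(rng.uniform(size=200) < 0.5, "a", "b").astype(object)
            if logrank_test(time, event, groups).pvalue < 0.05:
                rejections += 1
        assert 0.025 <= rejections / reps <= 0.075

    def test_one_group_rejected(self, rng):
        time, event = survival_data(rng, 10)
        with pytest.raises(ValueError):
            logrank_test(time, event, np.array(["a"] * 10, dtype=object))


class TestSubgroup:
    def test_unknown_status_excluded_from_constrained_axis(self, rng):
        cohort = make_cohort(rng, n=4, er=["positive"] * 4,
                             her2=["positive", "negative", "unknown", "positive"])
        sub = subgroup(cohort, er="positive", her2="positive")
        assert sub.n == 2

    def test_any_any_is_identity(self, rng):
        cohort = make_cohort(rng, n=10)
        assert subgroup(cohort).n == 10

    def test_planted_status_counts_recovered(self, rng):
        er = ["positive"] * 570
        her2 = ["positive"] * 88 + ["negative"] * 318 + ["unknown"] * 164
        cohort = make_cohort(rng, n=570, er=er, her2=her2)
        assert subgroup(cohort, er="positive", her2="positive").n == 88
        assert subgroup(cohort, er="positive", her2="negative").n == 318
        assert subgroup(cohort, er="positive").n == 570

    def test_empty_subgroup_warns(self, rng):
        cohort = make_cohort(rng, n=5, er=["negative"] * 5)
        with pytest.warns(UserWarning):
            sub = subgroup(cohort, er="positive")
        assert sub.n == 0


class TestSingleGeneKM:
    def test_deterministic_composition(self, rng):
        cohort = make_cohort(rng, n=100)
        a = single_gene_km(cohort, "G0")
        b = single_gene_km(cohort, "G0")
        assert a.statistic == b.statistic and a.pvalue == b.pvalue
        assert set(a.curves) == {"high", "low"}

    def test_protective_gene_high_expression_survives_better(self):
        wins = 0
        for s in range(40):
            rng = np.random.default_rng(9000 + s)
            n = 400
            x = rng.normal(size=n)
            z = (x - x.mean()) / x.std()
            t = rng.exponential(1.0 / (0.1 * np.exp(-0.5 * z)))
            cens = rng.exponential(1.0 / 0.043, size=n)
            time, event = np.minimum(t, cens), (t <= cens).astype(int)
            cohort = make_cohort(rng, n=n, n_genes=2, time=np.maximum(time, 1e-9), event=event)
            cohort.expr["G0"] = x
            comp = single_gene_km(cohort, "G0")
            t_mid = np.median(time)
            if comp.curves["high"].survival_at(t_mid) > comp.curves["low"].survival_at(t_mid):
                wins += 1
        assert wins / 40 >= 0.95

    def test_absent_gene_raises(self, rng):
        with pytest.raises(KeyError):
            single_gene_km(make_cohort(rng), "NOPE")
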