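"""Logistic filter, AUC, bagged-tree evaluation and the selection firewall."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from serumrna.signature import (
    FeatureFilterCriteria,
    evaluate_panels,
    logistic_fit,
    logistic_wald,
    roc_auc,
    select_signature,
    train_and_oob,
)
from serumrna.simulate import CohortConfig, default_aml_effects, simulate_cohort
from serumrna.de import run_de


class TestLogistic:
    def test_constant_feature_is_null(self):
        coef, p, sep = logistic_wald(np.full(10, 3.0),
                                     np.array([0, 1] * 5))
        assert coef == 0.0 and p == 1.0 and not sep

    def test_perfect_separation_flagged(self):
        x = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        coef, p, sep = logistic_wald(x, y)
        assert sep and p < 1e-300

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            logistic_wald(np.arange(5.0), np.zeros(5))

    def test_matches_newton_raphson_oracle(self):
        """statsmodels Logit (independent Newton solver) to 1e-4, including
        an 8-point toy arrangement."""
        rng = np.random.default_rng(0)
        datasets = [(np.arange(1.0, 9.0),
                     np.array([0, 0, 0, 1, 0, 1, 1, 1]))]
        while len(datasets) < 20:
            x = rng.normal(size=30)
            y = (rng.random(30) < 1 / (1 + np.exp(-1.2 * x))).astype(int)
            if 0 < y.sum() < 30:
                datasets.append((x, y))
        for x, y in datasets:
            coef, p, sep = logistic_wald(x, y)
            if sep:
                continue
            fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
            assert coef == pytest.approx(fit.params[1], abs=1e-4)
            assert p == pytest.approx(fit.pvalues[1], abs=1e-4)

    def test_lrt_is_monotone_where_wald_collapses(self):
        """Near-separation: the LRT p stays tiny while the Wald p inflates."""
        x = np.array([1, 2, 3, 4, 4.5, 10, 11, 12, 13, 14], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 0, 1, 1, 1, 1])
        res = logistic_fit(x, y)
        assert res.p_lrt < 0.05


class TestAUC:
    @pytest.mark.parametrize("scores,labels,expected", [
        ((0.1, 0.2, 0.8, 0.9), (0, 0, 1, 1), 1.0),
        ((0.9, 0.8, 0.2, 0.1), (0, 0, 1, 1), 0.0),
        ((0.9, 0.8, 0.7, 0.6), (1, 0, 1, 0), 0.75),
        ((0.5, 0.5, 0.5, 0.5), (0, 1, 0, 1), 0.5),
    ])
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        base = roc_auc(scores, labels)
        for f in (np.exp, np.tanh, lambda s: 3 * s + 7):
            assert roc_auc(f(scores), labels) == pytest.approx(base)

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            scores = rng.choice(np.linspace(0, 1, 11), size=16)
            labels = rng.integers(0, 2, size=16)
            if labels.sum() in (0, 16):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert roc_auc(scores, labels) == pytest.approx(
                wins / (len(pos) * len(neg)))

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestEnsemble:
    def test_separable_panel_has_low_oob_error(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 20 + [1] * 20)
        x = y * 5 + rng.normal(0, 0.3, size=40)
        X = pd.DataFrame({"f1": x, "f2": x})
        _, oob_error, _ = train_and_oob(X, y, n_trees=200, seed=0)
        assert oob_error <= 0.05

    def test_shuffled_labels_are_chance_level(self):
        rng = np.random.default_rng(4)
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame({"f1": y * 5 + rng.normal(0, 0.3, 40)})
        errs = []
        for seed in range(3):
            perm = np.random.default_rng(seed).permutation(y)
            _, oob_error, _ = train_and_oob(X, perm, n_trees=200, seed=seed)
            errs.append(oob_error)
        assert 0.3 <= np.mean(errs) <= 0.7

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        _, e1, s1 = train_and_oob(X, y, n_trees=100, seed=9)
        _, e2, s2 = train_and_oob(X, y, n_trees=100, seed=9)
        assert e1 == e2 and np.array_equal(s1, s2)

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            train_and_oob(pd.DataFrame(index=[0, 1]), np.array([0, 1]))


class TestSelection:
    def _toy(self):
        cols = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
        labels = pd.Series(["AML"] * 6 + ["control"] * 6, index=cols)
        rng = np.random.default_rng(6)
        idx = ["strong", "low_rpm", "not_de"] + [f"bg{i}" for i in range(30)]
        counts = pd.DataFrame(rng.poisson(500, size=(33, 12)), columns=cols,
                              index=idx)
        counts.loc["strong", labels == "AML"] += 2000
        counts.loc["low_rpm"] = rng.poisson(0.2, size=12)  # below 10 RPM
        counts.loc["not_de", labels == "AML"] += 2000      # DE flag withheld
        meta = pd.DataFrame({"category": ["tsRNA"] * 33}, index=idx)
        de = pd.DataFrame({"significant": [True, True] + [False] * 31},
                          index=idx)
        return counts, labels, meta, de

    def test_conjunction_of_criteria(self):
        counts, labels, meta, de = self._toy()
        panel = select_signature(counts, de, labels, "tsRNA", meta)
        assert panel == ["strong"]

    def test_empty_selection_is_not_an_error(self):
        counts, labels, meta, de = self._toy()
        de["significant"] = False
        assert select_signature(counts, de, labels, "tsRNA", meta) == []

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            FeatureFilterCriteria(min_mean_expression=-1)
        with pytest.raises(ValueError):
            FeatureFilterCriteria(logreg_alpha=1.5)


@pytest.fixture(scope="module")
def small_cohorts(ref, mixture):
    disc = simulate_cohort(CohortConfig(
        n_control=6, n_aml=8, de_effects=default_aml_effects(),
        library_size_range=(30_000, 40_000), seed=21), mixture, ref)
    val = simulate_cohort(CohortConfig(
        n_control=4, n_aml=6, de_effects=default_aml_effects(),
        library_size_range=(30_000, 40_000), seed=22), mixture, ref)
    dc = disc.counts.drop(index="cel-miR-39")
    vc = val.counts.drop(index="cel-miR-39")
    vc.columns = [f"V-{c}" for c in vc.columns]
    vl = pd.Series(val.samples["group"].to_numpy(), index=vc.columns)
    de = run_de(dc, disc.samples["group"], feature_meta=disc.features)
    return disc, dc, de, vc, vl


class TestEvaluatePanels:
    def test_overlapping_cohorts_rejected(self, small_cohorts):
        disc, dc, de, vc, vl = small_cohorts
        with pytest.raises(ValueError, match="share sample ids"):
            evaluate_panels(dc, disc.samples["group"], de, disc.features,
                            dc, disc.samples["group"], n_trees=10)

    def test_validation_labels_do_not_leak(self, small_cohorts):
        """Firewall: mutating validation labels changes no panel, model
        importance or validation score input."""
        disc, dc, de, vc, vl = small_cohorts
        r1 = evaluate_panels(dc, disc.samples["group"], de, disc.features,
                             vc, vl, n_trees=50, seed=1)
        flipped = vl.map({"AML": "control", "control": "AML"})
        r2 = evaluate_panels(dc, disc.samples["group"], de, disc.features,
                             vc, flipped, n_trees=50, seed=1)
        for cat in r1:
            assert r1[cat].panel == r2[cat].panel
            assert r1[cat].importances == r2[cat].importances
            assert r1[cat].auc_discovery == r2[cat].auc_discovery
            # labels flipped -> validation AUC mirrors
            assert r1[cat].auc_validation == pytest.approx(
                1.0 - r2[cat].auc_validation, abs=1e-9)

    def test_planted_markers_rank_top_importance(self, small_cohorts):
        disc, dc, de, vc, vl = small_cohorts
        reports = evaluate_panels(dc, disc.samples["group"], de,
                                  disc.features, vc, vl, n_trees=100, seed=2)
        ts = reports["tsRNA"]
        assert set(ts.panel) <= set(default_aml_effects())
        assert all(v > 0 for v in ts.importances.values())

    def test_no_effect_simulation_is_chance_level(self, ref, mixture):
        disc = simulate_cohort(CohortConfig(n_control=6, n_aml=8, seed=31),
                               mixture, ref)
        val = simulate_cohort(CohortConfig(n_control=4, n_aml=6, seed=32),
                              mixture, ref)
        dc = disc.counts.drop(index="cel-miR-39")
        vc = val.counts.drop(index="cel-miR-39")
        vc.columns = [f"V-{c}" for c in vc.columns]
        vl = pd.Series(val.samples["group"].to_numpy(), index=vc.columns)
        de = run_de(dc, disc.samples["group"], feature_meta=disc.features)
        reports = evaluate_panels(dc, disc.samples["group"], de,
                                  disc.features, vc, vl, n_trees=50, seed=3)
        for rep in reports.values():
            assert 0.3 <= rep.auc_validation <= 0.7
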