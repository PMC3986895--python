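"""Classification layer: jackknife LDA against an independent scikit-learn
oracle, stepwise selection behaviour, confusion collapse arithmetic, and the
nested permuted DFA's design validation and p-value rules."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import barkit as bk
from barkit.classify import ClassificationResult


def sklearn_loo_assignments(X, y):
    """Independent oracle: refit an equal-prior sklearn LDA for every
    held-out call."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    priors = np.full(len(classes), 1.0 / len(classes))
    out = []
    for i in range(len(X)):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        lda = LinearDiscriminantAnalysis(priors=priors).fit(X[mask], y[mask])
        out.append(lda.predict(X[i:i + 1])[0])
    return np.array(out)


def small_table(seed=21):
    """30 calls, 3 populations, the five profile features."""
    design = {pop: (3, 10) for pop in bk.POPULATIONS}
    ds = bk.sample_feature_table(design=design, calls_per_male=4, seed=seed)
    X = ds.features[list(bk.FEATURE_NAMES)]
    return X, ds.features["population"].to_numpy(), ds.features["male_id"].to_numpy()


class TestJackknifeLDA:
    def test_matches_sklearn_refit_oracle(self):
        X, y, _ = small_table()
        jack = bk.JackknifeLDA().fit(X, y)
        np.testing.assert_array_equal(
            jack.assignments_, sklearn_loo_assignments(X, y))

    def test_perfectly_separated_groups_score_100(self, rng):
        X = np.r_[rng.normal(0, 1, (20, 2)), rng.normal(100, 1, (20, 2))]
        y = np.array(["a"] * 20 + ["b"] * 20)
        res = bk.lda_fit_loo(X, y)
        assert res.accuracy == 100.0
        assert np.trace(res.confusion_counts.to_numpy()) == 40

    def test_confusion_row_sums_and_percent(self):
        X, y, _ = small_table()
        res = bk.lda_fit_loo(X, y)
        counts = res.confusion_counts
        assert list(counts.index) == sorted(np.unique(y))
        for g in counts.index:
            assert counts.loc[g].sum() == int((y == g).sum())
        np.testing.assert_allclose(res.confusion_percent.sum(axis=1), 100.0)
        assert res.accuracy == pytest.approx(
            100.0 * np.trace(counts.to_numpy()) / len(y))

    def test_discriminant_variance_and_loadings_shape(self):
        X, y, _ = small_table()
        jack = bk.JackknifeLDA().fit(X, y)
        ev = jack.explained_variance_ratio_
        assert len(ev) == 2                      # 3 groups -> 2 discriminants
        assert np.sum(ev) == pytest.approx(1.0)
        assert ev[0] >= ev[1] >= 0
        assert jack.standardized_loadings_.shape == (5, 2)
        assert list(jack.standardized_loadings_.index) == list(bk.FEATURE_NAMES)

    def test_deterministic_and_sklearn_api(self):
        X, y, _ = small_table()
        a = bk.JackknifeLDA().fit(X, y)
        b = bk.JackknifeLDA().fit(X, y)
        np.testing.assert_array_equal(a.assignments_, b.assignments_)
        assert set(a.predict(X)) <= set(np.unique(y))
        assert bk.JackknifeLDA(store_loadings=False).get_params() == \
            {"store_loadings": False}

    def test_validation_errors(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="two groups"):
            bk.lda_fit_loo(X, np.array(["a"] * 10))
        with pytest.raises(ValueError, match="at least two calls"):
            bk.lda_fit_loo(X, np.array(["a"] * 9 + ["b"]))
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            bk.lda_fit_loo(Xn, np.array(["a"] * 5 + ["b"] * 5))
        Xc = np.c_[X[:, 0], X[:, 0]]
        with pytest.raises(ValueError, match="collinear"):
            bk.lda_fit_loo(Xc, np.array(["a"] * 5 + ["b"] * 5))


class TestStepwiseSelection:
    def test_single_informative_feature_found(self):
        rng = np.random.default_rng(42)
        n = 20
        y = np.repeat(["a", "b", "c"], n)
        signal = np.concatenate([rng.normal(m, 1, n) for m in (0, 4, 8)])
        X = pd.DataFrame({
            "noise1": rng.normal(size=3 * n),
            "signal": signal,
            "noise2": rng.normal(size=3 * n),
        })
        selected = bk.stepwise_select(X, y)
        assert selected[0] == "signal"
        sel = bk.StepwiseLDASelector().fit(X, y)
        assert sel.loo_score_ > 0.9
        assert sel.transform(X).shape[1] == len(selected)

    def test_information_free_features_yield_empty_selection_with_warning(self):
        # constant features carry no group information: nothing beats chance
        X = pd.DataFrame(np.ones((40, 3)), columns=list("abc"))
        y = np.array(["g1"] * 20 + ["g2"] * 20)
        with pytest.warns(UserWarning, match="no feature improving"):
            sel = bk.StepwiseLDASelector().fit(X, y)
        assert sel.selected_features_ == []
        assert not sel.get_support().any()

    @pytest.mark.filterwarnings("ignore::scipy.linalg.LinAlgWarning")
    def test_deterministic_name_order_tiebreak(self):
        # two identical copies of the informative feature: the name-sorted
        # first one must win, every run
        rng = np.random.default_rng(7)
        n = 15
        y = np.repeat(["a", "b"], n)
        signal = np.concatenate([rng.normal(m, 1, n) for m in (0, 5)])
        X = pd.DataFrame({"zz_sig": signal, "aa_sig": signal + rng.normal(0, 1e-9, 2 * n)})
        selected = bk.stepwise_select(X, y)
        assert selected[0] == "aa_sig"


class TestCollapseConfusion:
    def test_population_to_species_arithmetic(self):
        counts = pd.DataFrame(
            [[113, 4, 3], [1, 94, 25], [4, 25, 83]],
            index=["green_monkey", "south_vervet", "east_vervet"],
            columns=["green_monkey", "south_vervet", "east_vervet"],
        )
        result = ClassificationResult(
            classes=np.asarray(counts.index),
            selected_features=["f"],
            confusion_counts=counts,
            confusion_percent=counts.div(counts.sum(axis=1), axis=0) * 100,
            accuracy=100.0 * 290 / 352,
            assignments=np.asarray(counts.columns.repeat(1)),
        )
        species = bk.collapse_confusion(result, bk.SPECIES_MAP)
        assert list(species.classes) == ["green_monkey", "vervet"]
        assert species.confusion_counts.loc["green_monkey", "vervet"] == 7
        assert species.confusion_counts.loc["vervet", "green_monkey"] == 5
        assert species.confusion_counts.loc["vervet", "vervet"] == 227
        assert species.accuracy == pytest.approx(100.0 * 340 / 352)

    def test_incomplete_mapping_rejected(self):
        X, y, _ = small_table()
        res = bk.lda_fit_loo(X, y)
        with pytest.raises(ValueError, match="does not cover"):
            bk.collapse_confusion(res, {"green_monkey": "green_monkey"})


class TestNestedPermutedDFA:
    def make_nested(self, delta, n_units=8, calls=3, seed=0):
        rng = np.random.default_rng(seed)
        X, y, g = [], [], []
        for c, mu in enumerate((0.0, delta)):
            for u in range(n_units):
                offset = rng.normal(0, 1, 2)
                X.append(mu + offset + rng.normal(0, 1, (calls, 2)))
                y += [f"g{c}"] * calls
                g += [f"g{c}_u{u}"] * calls
        return np.concatenate(X), np.array(y), np.array(g)

    def test_strong_separation_significant_add_one_rule(self):
        X, y, g = self.make_nested(delta=50.0)
        res = bk.pdfa_nested(X, y, g, n_permutations=99, seed=5,
                             n_subset_draws=5)
        assert res.observed_accuracy == 100.0
        assert len(res.permuted_accuracies) == 99
        # add-one rule: a permutation that happens to reproduce the true
        # male grouping (or its complement) also scores 100 and counts
        expected = (1 + np.sum(
            res.permuted_accuracies >= res.observed_accuracy - 1e-12)) / 100.0
        assert res.p_value == pytest.approx(expected)
        assert res.p_value <= 0.05

    def test_null_data_not_significant(self):
        X, y, g = self.make_nested(delta=0.0, seed=1)
        res = bk.pdfa_nested(X, y, g, n_permutations=99, seed=2,
                             n_subset_draws=5)
        assert res.p_value > 0.05

    def test_zero_permutations_reports_statistic_only(self):
        """With no male-level variance the nested statistic estimates the
        same quantity as the call-level LOO accuracy."""
        design = {pop: (6, 60) for pop in bk.POPULATIONS}
        ds = bk.sample_feature_table(design=design, rho_male=0.0, seed=11)
        X = ds.features[list(bk.FEATURE_NAMES)]
        y = ds.features["population"].to_numpy()
        g = ds.features["male_id"].to_numpy()
        res = bk.pdfa_nested(X, y, g, n_permutations=0, seed=0,
                             n_subset_draws=50)
        loo = bk.lda_fit_loo(X, y).accuracy
        assert res.p_value == 1.0
        assert res.observed_accuracy == pytest.approx(loo, abs=6.0)

    def test_unit_spanning_groups_rejected(self):
        X, y, g = self.make_nested(delta=1.0)
        g[0] = g[-1]  # one male appearing in both groups
        with pytest.raises(ValueError, match="design violation"):
            bk.pdfa_nested(X, y, g, n_permutations=1)

    def test_single_unit_group_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        y = np.array(["a"] * 6 + ["b"] * 6)
        g = np.array(["a_u1"] * 6 + ["b_u1"] * 3 + ["b_u2"] * 3)
        with pytest.raises(ValueError, match="two nesting units"):
            bk.pdfa_nested(X, y, g, n_permutations=1)

    def test_seeded_runs_identical(self):
        X, y, g = self.make_nested(delta=2.0)
        a = bk.pdfa_nested(X, y, g, n_permutations=19, seed=9, n_subset_draws=4)
        b = bk.pdfa_nested(X, y, g, n_permutations=19, seed=9, n_subset_draws=4)
        assert a.observed_accuracy == b.observed_accuracy
        np.testing.assert_array_equal(a.permuted_accuracies, b.permuted_accuracies)
        assert a.p_value == b.p_value
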