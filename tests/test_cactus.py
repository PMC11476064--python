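"""Flip abstraction, margin-error filtration and product-cost classification,
checked against closed forms and an independent brute-force oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort
from gradesig import simulate_expression, strong_signal_config
from gradesig.cactus import (
    CactusConfig,
    CactusModel,
    CactusResults,
    abstract_flips,
    cactus_classify,
    cactus_select,
    fit_significance,
    margin_error,
    roc_cutoff,
)
from gradesig.classify_eval import (
    SplitSpec,
    balanced_accuracy,
    confusion_from_predictions,
    sensitivity,
    specificity,
    split_train_test,
)
from gradesig.core_io import ExpressionMatrix, PhenotypeTable, GRADE2, GRADE3


class TestRocCutoff:
    def test_separable_midpoint(self):
        cut, acc = roc_cutoff(np.array([1.0, 2.0, 4.0, 5.0]), np.array(["A", "A", "B", "B"]))
        assert cut == 3.0 and acc == 1.0

    def test_constant_values_majority_accuracy(self):
        cut, acc = roc_cutoff(np.array([2.0] * 5), np.array(["A", "A", "B", "B", "B"]))
        assert acc == pytest.approx(3 / 5)

    def test_label_swap_same_cut_and_accuracy(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12)
        labels = np.array(["A", "B"] * 6)
        swapped = np.where(labels == "A", "B", "A")
        assert roc_cutoff(values, labels) == roc_cutoff(values, swapped)

    def test_matches_exhaustive_search(self):
        # oracle: try every midpoint and orientation by brute force
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = np.round(rng.normal(size=9), 1)
            labels = rng.choice(["A", "B"], size=9)
            if len(np.unique(labels)) < 2:
                continue
            pos = labels == np.unique(labels)[1]
            distinct = np.unique(values)
            cands = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2, [np.inf]))
            best = max(
                max(np.mean((values > c) == pos), np.mean((values <= c) == pos))
                for c in cands
            )
            _, acc = roc_cutoff(values, labels)
            assert acc == pytest.approx(best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_cutoff(np.array([1.0, 2.0]), np.array(["A", "A"]))


class TestAbstractFlips:
    def test_boundary_value_is_down(self):
        m = ExpressionMatrix(["g"], ["s1", "s2"], [[1.0, 2.0]])
        flips = abstract_flips(m, {"g": 1.0})
        assert list(flips.codes[0]) == ["D", "U"]  # strictly-above contract

    def test_monotone_transform_with_transformed_cutoff(self):
        m = ExpressionMatrix(["g"], ["a", "b", "c"], [[1.0, 3.0, 5.0]])
        f1 = abstract_flips(m, {"g": 2.0})
        m2 = ExpressionMatrix(["g"], ["a", "b", "c"], [[2.0, 6.0, 10.0]])
        f2 = abstract_flips(m2, {"g": 4.0})
        np.testing.assert_array_equal(f1.codes, f2.codes)

    def test_all_above_is_all_up(self):
        m = ExpressionMatrix(["g"], ["a", "b"], [[5.0, 6.0]])
        assert list(abstract_flips(m, {"g": 0.0}).codes[0]) == ["U", "U"]

    def test_missing_cutoff_fatal(self):
        m = ExpressionMatrix(["g"], ["a"], [[1.0]])
        with pytest.raises(KeyError):
            abstract_flips(m, {})


class TestMarginError:
    def test_closed_forms(self):
        assert margin_error(5, 0.5, 100) == pytest.approx(0.25)
        assert margin_error(3.3, 1.0, 17) == 0.0
        assert margin_error(5, 0.9, 10096) == pytest.approx(5 * math.sqrt(0.09 / 10096))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            margin_error(5, 0.5, 0)
        with pytest.raises(ValueError):
            margin_error(5, 1.5, 10)


class TestCactusSelect:
    def test_single_gene_always_kept(self):
        assert list(cactus_select(np.array([0.51]), CactusConfig())) == [0]

    def test_equal_accuracies_all_kept(self):
        assert len(cactus_select(np.array([0.7] * 8), CactusConfig())) == 8

    def test_band_hand_example_wide_and_narrow(self):
        p = np.array([0.95, 0.90, 0.60])
        assert list(cactus_select(p, CactusConfig(z=5.0), n=3)) == [0, 1, 2]
        assert list(cactus_select(p, CactusConfig(z=0.1), n=3)) == [0]

    def test_above_half_rule(self):
        p = np.array([0.9, 0.52, 0.5])
        cfg = CactusConfig(z=1.0, selection_rule="above_half")
        kept = cactus_select(p, cfg, n=100)
        assert 0 in kept and 2 not in kept


class TestFitSignificance:
    def _flips(self, codes, samples, grades):
        fm_expr = ExpressionMatrix(["g"], samples, np.zeros((1, len(samples))))
        flips = abstract_flips(fm_expr, {"g": 1.0})
        flips.codes = np.array([list(codes)])
        pheno = PhenotypeTable(pd.DataFrame({"sample_id": samples, "grade": grades}))
        return flips, pheno

    def test_balanced_counts_give_half(self):
        samples = [f"s{i}" for i in range(12)]
        flips, pheno = self._flips("UUUUUDDDDDUD", samples, [GRADE2] * 10 + [GRADE3] * 2)
        model = fit_significance(flips, pheno, ["g"], smoothing=1.0)
        assert model.sigma[GRADE2]["g"]["U"] == pytest.approx(6 / 12)

    def test_all_up_with_smoothing(self):
        samples = [f"s{i}" for i in range(12)]
        flips, pheno = self._flips("U" * 10 + "DD", samples, [GRADE2] * 10 + [GRADE3] * 2)
        model = fit_significance(flips, pheno, ["g"], smoothing=1.0)
        assert model.sigma[GRADE2]["g"]["U"] == pytest.approx(11 / 12)

    def test_sigma_normalised_per_gene_and_class(self):
        expr, pheno = make_cohort(4, 20, seed=1)
        grades = pheno.grades_for(expr.sample_ids)
        cutoffs = {g: float(np.median(expr.values[i])) for i, g in enumerate(expr.gene_ids)}
        flips = abstract_flips(expr, cutoffs)
        model = fit_significance(flips, pheno, expr.gene_ids, smoothing=1.0)
        for grade in (GRADE2, GRADE3):
            for g in expr.gene_ids:
                assert model.sigma[grade][g]["U"] + model.sigma[grade][g]["D"] == pytest.approx(1.0)
                assert 0 < model.sigma[grade][g]["U"] < 1


def brute_force_cost(model: CactusResults, sample_flips: dict) -> tuple[str, dict]:
    """Direct product of sigmas (no logs) with the same tie conventions."""
    costs = {}
    for grade in (GRADE2, GRADE3):
        c = 1.0
        for gene in model.selected:
            c *= model.sigma[grade][gene][sample_flips[gene]]
        costs[grade] = c
    if costs[GRADE2] == costs[GRADE3]:
        pred = GRADE3 if model.priors[GRADE3] > model.priors[GRADE2] else GRADE2
    else:
        pred = max(costs, key=costs.get)
    return pred, costs


class TestCactusClassify:
    def _random_model(self, n_genes: int, rng) -> CactusResults:
        genes = [f"g{i}" for i in range(n_genes)]
        sigma = {}
        for grade in (GRADE2, GRADE3):
            sigma[grade] = {}
            for g in genes:
                s_up = rng.uniform(0.05, 0.95)
                sigma[grade][g] = {"U": s_up, "D": 1 - s_up}
        priors = {GRADE2: 0.6, GRADE3: 0.4}
        return CactusResults(
            selected=genes, cutoffs={g: 0.0 for g in genes}, sigma=sigma,
            priors=priors, accuracy={}, n_features=n_genes, smoothing=1.0,
        )

    def test_matches_product_oracle_exhaustively(self):
        # every flip pattern for 1..4 genes, several sigma draws, 8 virtual samples
        rng = np.random.default_rng(12)
        for n_genes in range(1, 5):
            for _ in range(8):
                model = self._random_model(n_genes, rng)
                for pattern in itertools.product("UD", repeat=n_genes):
                    flips = dict(zip(model.selected, pattern))
                    pred, log_costs = cactus_classify(model, flips)
                    oracle_pred, costs = brute_force_cost(model, flips)
                    assert pred == oracle_pred
                    for grade in (GRADE2, GRADE3):
                        assert math.exp(log_costs[grade]) == pytest.approx(
                            costs[grade], rel=1e-12
                        )

    def test_zero_smoothing_unseen_flip_gives_minus_inf(self):
        samples = [f"s{i}" for i in range(8)]
        expr = ExpressionMatrix(["g"], samples, [[2.0] * 4 + [0.0] * 4])
        pheno = PhenotypeTable(pd.DataFrame({
            "sample_id": samples, "grade": [GRADE2] * 4 + [GRADE3] * 4,
        }))
        flips = abstract_flips(expr, {"g": 1.0})
        model = fit_significance(flips, pheno, ["g"], smoothing=0.0)
        _, log_costs = cactus_classify(model, {"g": "D"})
        assert log_costs[GRADE2] == -math.inf

    def test_identical_sigmas_tie_to_majority_prior(self):
        rng = np.random.default_rng(1)
        model = self._random_model(2, rng)
        model.sigma[GRADE3] = {g: dict(model.sigma[GRADE2][g]) for g in model.selected}
        model.priors = {GRADE2: 0.3, GRADE3: 0.7}
        pred, _ = cactus_classify(model, {g: "U" for g in model.selected})
        assert pred == GRADE3
        model.priors = {GRADE2: 0.5, GRADE3: 0.5}
        pred, _ = cactus_classify(model, {g: "U" for g in model.selected})
        assert pred == GRADE2  # equal priors fall back to grade2

    def test_gene_order_irrelevant(self):
        rng = np.random.default_rng(2)
        model = self._random_model(4, rng)
        flips = {g: rng.choice(["U", "D"]) for g in model.selected}
        _, costs1 = cactus_classify(model, flips)
        model.selected = model.selected[::-1]
        _, costs2 = cactus_classify(model, flips)
        assert costs1 == pytest.approx(costs2)

    def test_missing_flip_fatal(self):
        model = self._random_model(2, np.random.default_rng(3))
        with pytest.raises(KeyError):
            cactus_classify(model, {"g0": "U"})


class TestCactusModelEndToEnd:
    def test_single_separable_gene_perfect_training_accuracy(self):
        expr, pheno = make_cohort(30, 40, seed=6, separating=1, shift=4.0, noise=0.1)
        results = CactusModel(expr, pheno).fit()
        assert "G000" in results.selected
        preds = results.predict(expr)
        assert np.mean(preds == pheno.grades_for(expr.sample_ids)) == 1.0

    def test_strong_signal_test_ba_and_precision(self):
        bas, precisions = [], []
        for seed in range(5):
            expr, pheno, truth = simulate_expression(strong_signal_config(seed=seed))
            train, test = split_train_test(pheno, SplitSpec(seed=seed))
            results = CactusModel(expr.subset_samples(train), pheno.subset(train)).fit()
            conf = confusion_from_predictions(
                pheno.grades_for(test), results.predict(expr.subset_samples(test))
            )
            bas.append(balanced_accuracy(sensitivity(conf), specificity(conf)))
            planted = set(truth.signature_gene_ids)
            precisions.append(len(set(results.selected) & planted) / len(results.selected))
        assert min(bas) >= 0.9
        assert min(precisions) >= 0.8

    def test_summary_and_json_round_trip(self, tmp_path):
        expr, pheno = make_cohort(10, 30, seed=8, separating=2)
        results = CactusModel(expr, pheno).fit()
        summary = results.summary()
        assert {"gene_id", "cutoff", "single_feature_accuracy"} <= set(summary.columns)
        path = tmp_path / "model.json"
        results.to_json(path)
        back = CactusResults.from_json(path)
        assert back.selected == results.selected
        assert back.sigma == results.sigma
        np.testing.assert_array_equal(back.predict(expr), results.predict(expr))
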