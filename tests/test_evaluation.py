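"""Metrics, kappa, cross-validation, grid search, LOGO, iterative harness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score

import genestatus as gs
from genestatus.categories import DEFAULT_CATEGORIES
from genestatus.evaluation import assign_folds, confusion_matrix, make_report

C = gs.StatusCategory


def brute_force_kappa(a, b):
    """Independent kappa oracle via an explicit confusion table."""
    labels = sorted(set(a) | set(b), key=str)
    n = len(a)
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[labels.index(x), labels.index(y)] += 1
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0))) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


class MajorityTrainer:
    """Degenerate trainer predicting the most frequent training label."""

    def __call__(self, instances, cfg):
        labels = [l for _, l in instances]
        majority = max(set(labels), key=lambda l: (labels.count(l), -l.ordinal))
        class M:
            def predict(self, vectors, _m=majority):
                return [_m] * len(vectors)
        return M()


class TestAccuracy:
    def test_perfect_predictions(self):
        labels = [C.DRUG] * 5 + [C.OTHERS] * 5
        assert gs.accuracy(labels, labels) == 1.0

    def test_three_of_four(self):
        gold = [C.DRUG, C.DRUG, C.OTHERS, C.OTHERS]
        preds = [C.DRUG, C.DRUG, C.OTHERS, C.DRUG]
        assert gs.accuracy(preds, gold) == 0.75

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            gs.accuracy([], [])

    @given(st.lists(st.tuples(st.integers(0, 4), st.integers(0, 4)),
                    min_size=1, max_size=50))
    def test_equals_micro_averaged_recall(self, pairs):
        gold = [g for g, _ in pairs]
        preds = [p for _, p in pairs]
        cats = sorted(set(gold) | set(preds))
        # micro recall = sum of per-category correct / sum of gold counts
        correct = sum(sum(p == g == c for p, g in zip(preds, gold)) for c in cats)
        assert gs.accuracy(preds, gold) == pytest.approx(correct / len(gold))

    def test_equals_trace_over_total_on_confusion(self, top8_featurized):
        sample = top8_featurized[:300]
        model = gs.train_two_stage(top8_featurized, gs.ClassifierConfig())
        preds = model.predict([v for v, _ in sample])
        gold = [l for _, l in sample]
        report = make_report(preds, gold, DEFAULT_CATEGORIES)
        conf = report.confusion
        assert report.accuracy == np.trace(conf.values) / conf.values.sum()


class TestPrecisionRecallF:
    @pytest.mark.parametrize("p,r,expected_f", [
        (0.754, 0.920, 0.829),   # lesion detected, cascade
        (0.667, 0.160, 0.258),   # gene only, cascade
        (0.784, 0.894, 0.835),   # lesion detected, flat baseline
    ])
    def test_f_is_harmonic_mean(self, p, r, expected_f):
        assert round(gs.f_score(p, r), 3) == expected_f

    def test_perfect_category(self):
        gold = [C.DRUG, C.OTHERS, C.DRUG]
        prf = gs.precision_recall_f(gold, gold, C.DRUG)
        assert (prf.precision, prf.recall, prf.f) == (1.0, 1.0, 1.0)

    def test_counting_definition(self):
        gold = [C.DRUG, C.DRUG, C.OTHERS, C.OTHERS, C.DRUG]
        preds = [C.DRUG, C.OTHERS, C.DRUG, C.OTHERS, C.DRUG]
        prf = gs.precision_recall_f(preds, gold, C.DRUG)
        assert prf.precision == pytest.approx(2 / 3)
        assert prf.recall == pytest.approx(2 / 3)

    def test_undefined_precision_flagged_as_zero(self):
        gold = [C.DRUG, C.OTHERS]
        preds = [C.OTHERS, C.OTHERS]
        prf = gs.precision_recall_f(preds, gold, C.DRUG)
        assert prf.precision == 0.0 and not prf.precision_defined
        assert prf.f == 0.0

    def test_category_outside_enabled_set_errors(self):
        with pytest.raises(ValueError):
            gs.precision_recall_f([C.DRUG], [C.DRUG],
                                  C.GENETIC_LESION_DETECTED_OR_NOT,
                                  categories=DEFAULT_CATEGORIES)


class TestMacroAverage:
    def test_per_gene_accuracy_column_averages(self):
        gene_specific = [88.2, 85.4, 82.5, 75.9, 87.5, 93.0, 73.9, 83.5]
        gene_neutral = [68.6, 85.4, 78.0, 74.5, 87.0, 73.5, 78.3, 65.0]
        assert round(gs.macro_average(gene_specific), 1) == 83.7
        assert round(gs.macro_average(gene_neutral), 1) == 76.3

    def test_single_value(self):
        assert gs.macro_average([0.5]) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gs.macro_average([])


class TestCohensKappa:
    def test_identical_sequences(self):
        assert gs.cohens_kappa(["x", "y", "x"], ["x", "y", "x"]) == 1.0

    def test_perfect_disagreement(self):
        assert gs.cohens_kappa(list("xxyy"), list("yyxx")) == -1.0

    def test_partial_agreement(self):
        assert gs.cohens_kappa(list("xxxy"), list("xxyy")) == pytest.approx(0.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gs.cohens_kappa([], [])

    def test_constant_annotators(self):
        assert gs.cohens_kappa(["x"] * 5, ["x"] * 5) == 1.0

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 50))
        k = int(rng.integers(2, 8))
        a = rng.integers(0, k, size=n).tolist()
        b = rng.integers(0, k, size=n).tolist()
        ours = gs.cohens_kappa(a, b)
        assert ours == pytest.approx(brute_force_kappa(a, b), abs=1e-12)
        if len(set(a) | set(b)) > 1:
            assert ours == pytest.approx(cohen_kappa_score(a, b), abs=1e-9)


class TestCrossValidation:
    def test_every_instance_predicted_once(self, top8_featurized):
        report = gs.cross_validate_pooled(
            top8_featurized, gs.train_two_stage, gs.ClassifierConfig(seed=0),
            k=5, seed=0)
        assert report.n == len(top8_featurized)
        assert len(report.predictions) == len(top8_featurized)
        assert len(report.per_fold_accuracies) == 5

    def test_stratification_within_one_instance(self, top8_featurized):
        labels = [l for _, l in top8_featurized]
        folds = assign_folds(labels, k=5, seed=3)
        for cat in DEFAULT_CATEGORIES:
            total = sum(l is cat for l in labels)
            if total < 5:
                continue
            per_fold = [sum(1 for l, f in zip(labels, folds) if l is cat and f == fi)
                        for fi in range(5)]
            assert max(per_fold) - min(per_fold) <= 1

    def test_fewer_instances_than_folds_errors(self):
        insts = [({"a": 1.0}, C.DRUG), ({"b": 1.0}, C.OTHERS)]
        with pytest.raises(ValueError):
            gs.cross_validate_pooled(insts, gs.train_single_stage,
                                     gs.ClassifierConfig(), k=5)

    def test_majority_trainer_pooled_equals_majority_share(self):
        # with a label-independent trainer, pooled CV accuracy must equal the
        # majority-class share exactly (each instance predicted once)
        insts = ([({"a": 1.0}, C.DRUG)] * 30 + [({"b": 1.0}, C.OTHERS)] * 10)
        report = gs.cross_validate_pooled(insts, MajorityTrainer(),
                                          gs.ClassifierConfig(), k=5, seed=0)
        assert report.accuracy == pytest.approx(30 / 40)


class TestGridSearch:
    def test_single_combination_returned(self, top8_featurized):
        subset = frozenset({"context", "section"})
        fams, cfg, table = gs.grid_search(
            top8_featurized[:200], [subset], [{"kernel": "linear", "C": 1.0}],
            gs.train_single_stage, gs.ClassifierConfig(), k=3, seed=0)
        assert fams == subset
        assert cfg.C == 1.0
        assert len(table) == 1

    def test_negation_family_wins_when_it_carries_the_label(self):
        # corpus where the only signal separating not-detected from detected
        # is the negation indicator
        rng = np.random.default_rng(0)
        insts = []
        for i in range(60):
            neg = i % 2 == 0
            vec = {f"ctx:word=w{rng.integers(5)}": 1.0, "sec:eligibility": 1.0}
            if neg:
                vec["neg:present"] = 1.0
            insts.append((vec, C.GENETIC_LESION_NOT_DETECTED if neg
                          else C.GENETIC_LESION_DETECTED))
        subsets = [frozenset({"context", "section"}),
                   frozenset({"context", "negation", "section"})]
        fams, _, table = gs.grid_search(
            insts, subsets, [{"kernel": "linear", "C": 1.0}],
            gs.train_single_stage, gs.ClassifierConfig(), k=5, seed=0)
        assert "negation" in fams
        assert len(table) == 2

    def test_score_table_row_count(self, top8_featurized):
        subsets = [frozenset({"section"}), frozenset({"context", "section"})]
        grid = [{"kernel": "linear", "C": 0.1}, {"kernel": "linear", "C": 1.0},
                {"kernel": "rbf", "C": 1.0, "gamma": 0.1}]
        _, _, table = gs.grid_search(
            top8_featurized[:150], subsets, grid,
            gs.train_single_stage, gs.ClassifierConfig(), k=3, seed=0)
        assert len(table) == len(subsets) * len(grid)


class TestLeaveOneGeneOut:
    def _groups(self, corpus, featurized):
        groups = {}
        for inst, pair in zip(corpus.instances, featurized):
            groups.setdefault(inst.mention.gene_symbol, []).append(pair)
        return groups

    def test_one_report_per_gene_and_train_sizes(self, top8_corpus, top8_featurized):
        _, corpus = top8_corpus
        groups = self._groups(corpus, top8_featurized)
        reports, macro = gs.leave_one_gene_out(
            groups, gs.train_two_stage, gs.ClassifierConfig(),
            categories=DEFAULT_CATEGORIES)
        assert set(reports) == set(groups)
        total = sum(len(v) for v in groups.values())
        for gene, report in reports.items():
            assert report.descriptor["train_size"] == total - len(groups[gene])
            assert report.n == len(groups[gene])
        assert macro == pytest.approx(
            gs.macro_average([r.accuracy for r in reports.values()]))

    def test_shared_cues_generalize_across_genes(self, top8_corpus, top8_featurized):
        _, corpus = top8_corpus
        groups = self._groups(corpus, top8_featurized)
        _, macro = gs.leave_one_gene_out(groups, gs.train_two_stage,
                                         gs.ClassifierConfig(),
                                         categories=DEFAULT_CATEGORIES)
        assert macro >= 0.9

    def test_empty_group_errors(self):
        groups = {"A": [({"x": 1.0}, C.DRUG)], "B": []}
        with pytest.raises(ValueError, match="zero instances"):
            gs.leave_one_gene_out(groups, gs.train_single_stage,
                                  gs.ClassifierConfig())

    def test_merged_report_is_order_invariant(self, top8_corpus, top8_featurized):
        # per-category metrics on the concatenation of per-gene prediction
        # sequences must not depend on concatenation order
        _, corpus = top8_corpus
        groups = self._groups(corpus, top8_featurized)
        reports, _ = gs.leave_one_gene_out(groups, gs.train_two_stage,
                                           gs.ClassifierConfig(),
                                           categories=DEFAULT_CATEGORIES)
        orders = [sorted(reports), sorted(reports, reverse=True)]
        merged = []
        for order in orders:
            preds = [p for g in order for p in reports[g].predictions]
            gold = [l for g in order for l in reports[g].gold]
            merged.append(make_report(preds, gold, DEFAULT_CATEGORIES))
        assert merged[0].accuracy == merged[1].accuracy
        for cat in DEFAULT_CATEGORIES:
            assert merged[0].per_category[cat] == merged[1].per_category[cat]


class TestIterativeRetraining:
    def _dummy_batch(self, size, label=C.DRUG):
        alt = C.OTHERS if label is C.DRUG else C.DRUG
        return ([({"a": 1.0}, label)] * (size - size // 4)
                + [({"b": 1.0}, alt)] * (size // 4))

    def test_cumulative_sizes(self):
        initial = self._dummy_batch(1143)
        batches = [self._dummy_batch(s) for s in (759, 585, 792, 1053, 842)]
        results = gs.iterative_retraining(initial, batches, MajorityTrainer(),
                                          gs.ClassifierConfig())
        assert results[2].cumulative_training_size == 3279
        assert results[-1].cumulative_training_size - len(initial) == 4031

    def test_empty_batch_skipped_with_flag(self):
        initial = self._dummy_batch(20)
        results = gs.iterative_retraining(
            initial, [self._dummy_batch(10), [], self._dummy_batch(5)],
            MajorityTrainer(), gs.ClassifierConfig())
        assert results[1].skipped and results[1].accuracy is None
        assert results[1].cumulative_training_size == 30
        assert results[2].cumulative_training_size == 35

    def test_new_category_enters_pool_for_next_iteration(self):
        initial = self._dummy_batch(40)
        novel = [({"c": 1.0}, C.GENETIC_LESION_DETECTED_OR_NOT)] * 30
        probe = [({"c": 1.0}, C.GENETIC_LESION_DETECTED_OR_NOT)] * 5

        def trainer(insts, cfg):
            return gs.train_single_stage(insts, cfg)

        results = gs.iterative_retraining(initial, [novel, probe], trainer,
                                          gs.ClassifierConfig())
        # first sight of the category scores 0; after absorption it is learnable
        assert results[0].accuracy == 0.0
        assert results[1].accuracy == 1.0

    def test_batch_scored_before_absorption(self):
        initial = [({"a": 1.0}, C.DRUG)] * 6 + [({"b": 1.0}, C.OTHERS)] * 2
        flipped = [({"a": 1.0}, C.OTHERS)] * 10
        results = gs.iterative_retraining(initial, [flipped], MajorityTrainer(),
                                          gs.ClassifierConfig())
        # majority of the initial pool is DRUG, so the flipped batch scores 0
        assert results[0].accuracy == 0.0
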