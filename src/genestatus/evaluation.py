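"""Metrics and experiment designs.

Accuracy is the primary measure (correct predictions over total instances,
pooled over all cross-validation test folds). Per-category precision, recall
and F = 2PR/(P+R) are reported on merged predictions because individual
genes may have only a handful of instances in a category. Macro averages
are unweighted means across genes. Cohen's kappa quantifies chance-corrected
inter-annotator agreement.

Three experiment harnesses mirror the study designs this package supports:

* pooled stratified k-fold cross-validation (gene-specific evaluation),
* leave-one-gene-out (gene-neutral generalization to an unseen gene),
* iterative retraining (score a batch with the current model, fold the
  batch's corrected labels into the training pool, retrain, repeat).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .categories import StatusCategory
from .classification import ClassifierConfig, Instance
from .feature_extraction import FeatureVector, restrict_to_families

#: A trainer maps (instances, config) to a model exposing .predict(vectors).
Trainer = Callable[[Sequence[Instance], ClassifierConfig], object]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def accuracy(preds: Sequence, gold: Sequence) -> float:
    """Fraction of instances whose predicted label equals the gold label."""
    if len(preds) != len(gold):
        raise ValueError("preds and gold must be aligned")
    if not gold:
        raise ValueError("cannot compute accuracy on empty input")
    return sum(p == g for p, g in zip(preds, gold)) / len(gold)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f: float
    #: False when no instance was predicted in the category (P defined as 0).
    precision_defined: bool = True


def precision_recall_f(
    preds: Sequence, gold: Sequence, category,
    categories: Optional[Sequence] = None,
) -> PRF:
    """Per-category precision, recall and F on aligned label sequences.

    An undefined precision (no predictions in the category) is reported as 0
    with ``precision_defined=False`` so that F stays defined.
    """
    if len(preds) != len(gold):
        raise ValueError("preds and gold must be aligned")
    if categories is not None and category not in categories:
        raise ValueError(f"category {category} not in the enabled set")
    pred_n = sum(p == category for p in preds)
    gold_n = sum(g == category for g in gold)
    correct = sum(p == g == category for p, g in zip(preds, gold))
    defined = pred_n > 0
    p = correct / pred_n if defined else 0.0
    r = correct / gold_n if gold_n else 0.0
    return PRF(precision=p, recall=r, f=f_score(p, r), precision_defined=defined)


def macro_average(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-group proportions."""
    if len(values) == 0:
        raise ValueError("cannot average an empty sequence")
    return float(np.mean(values))


def cohens_kappa(ann1: Sequence, ann2: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    Expected agreement p_e comes from the product of the two annotators'
    marginal label distributions. When p_e = 1 (both annotators constant),
    returns 1.0 for identical sequences.
    """
    if len(ann1) != len(ann2):
        raise ValueError("annotation sequences must be aligned")
    n = len(ann1)
    if n == 0:
        raise ValueError("cannot compute kappa on empty input")
    p_o = sum(a == b for a, b in zip(ann1, ann2)) / n
    labels = set(ann1) | set(ann2)
    p_e = sum(
        (sum(a == l for a in ann1) / n) * (sum(b == l for b in ann2) / n)
        for l in labels
    )
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def confusion_matrix(preds: Sequence, gold: Sequence,
                     categories: Sequence) -> pd.DataFrame:
    """Square count table, rows = gold, columns = predicted."""
    names = [getattr(c, "name", str(c)) for c in categories]
    table = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for p, g in zip(preds, gold):
        table.loc[getattr(g, "name", str(g)), getattr(p, "name", str(p))] += 1
    return table


@dataclass
class EvaluationReport:
    """Metrics for one experiment: accuracy, per-category PRF, confusion."""

    accuracy: float
    per_category: dict
    confusion: pd.DataFrame
    n: int
    descriptor: dict = field(default_factory=dict)
    per_fold_accuracies: Optional[list[float]] = None
    predictions: Optional[list] = None
    gold: Optional[list] = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n": self.n,
            "per_category": {
                getattr(c, "name", str(c)): {
                    "precision": prf.precision, "recall": prf.recall, "f": prf.f,
                    "precision_defined": prf.precision_defined,
                }
                for c, prf in self.per_category.items()
            },
            "confusion": self.confusion.to_dict(),
            "descriptor": self.descriptor,
            "per_fold_accuracies": self.per_fold_accuracies,
        }

    def to_table(self) -> str:
        """Aligned-text per-category table (percent P / R / F)."""
        rows = [f"{'Category':<36}{'Precision':>10}{'Recall':>10}{'F-score':>10}"]
        for c, prf in self.per_category.items():
            name = getattr(c, "value", str(c))
            rows.append(f"{name:<36}{prf.precision:>9.1%}{prf.recall:>9.1%}{prf.f:>9.1%}")
        rows.append(f"{'Overall accuracy':<36}{self.accuracy:>9.1%}")
        return "\n".join(rows)


def make_report(preds: Sequence, gold: Sequence, categories: Sequence,
                descriptor: Optional[dict] = None,
                keep_predictions: bool = False) -> EvaluationReport:
    per_cat = {c: precision_recall_f(preds, gold, c, categories) for c in categories}
    conf = confusion_matrix(preds, gold, categories)
    report = EvaluationReport(
        accuracy=accuracy(preds, gold),
        per_category=per_cat,
        confusion=conf,
        n=len(gold),
        descriptor=descriptor or {},
    )
    if keep_predictions:
        report.predictions = list(preds)
        report.gold = list(gold)
    return report


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def assign_folds(labels: Sequence, k: int, seed: int) -> list[int]:
    """Stratified fold assignment.

    Within each category the (seeded) shuffled instances are dealt
    round-robin to folds with a cursor that carries over between categories,
    so categories with >= k members are stratified to within one instance
    and rarer categories still spread across folds instead of piling into
    fold 0.
    """
    rng = np.random.default_rng(seed)
    by_cat: dict = {}
    for i, label in enumerate(labels):
        by_cat.setdefault(label, []).append(i)
    folds = [0] * len(labels)
    cursor = int(rng.integers(k))
    for label in sorted(by_cat, key=lambda l: getattr(l, "ordinal", 0)):
        idxs = by_cat[label]
        order = rng.permutation(len(idxs))
        for j in order:
            folds[idxs[j]] = cursor
            cursor = (cursor + 1) % k
    return folds


def cross_validate_pooled(
    instances: Sequence[Instance],
    trainer: Trainer,
    cfg: ClassifierConfig,
    k: int = 5,
    seed: int = 0,
    categories: Optional[Sequence] = None,
    descriptor: Optional[dict] = None,
) -> EvaluationReport:
    """Stratified k-fold CV with predictions pooled across test folds.

    Every instance is predicted exactly once, by a model not trained on it;
    the report's accuracy and per-category metrics are computed on the
    pooled predictions, with per-fold accuracies retained for model
    selection.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(instances) < k:
        raise ValueError(f"need at least {k} instances for {k}-fold CV")
    labels = [l for _, l in instances]
    folds = assign_folds(labels, k, seed)
    preds: list = [None] * len(instances)
    per_fold_acc: list[float] = []
    for f in range(k):
        test_idx = [i for i, fi in enumerate(folds) if fi == f]
        train = [instances[i] for i, fi in enumerate(folds) if fi != f]
        model = trainer(train, cfg)
        fold_preds = model.predict([instances[i][0] for i in test_idx])
        for i, p in zip(test_idx, fold_preds):
            preds[i] = p
        per_fold_acc.append(accuracy(fold_preds, [labels[i] for i in test_idx]))
    cats = categories if categories is not None else sorted(
        set(labels), key=lambda c: getattr(c, "ordinal", 0))
    report = make_report(preds, labels, cats, descriptor, keep_predictions=True)
    report.per_fold_accuracies = per_fold_acc
    return report


# ---------------------------------------------------------------------------
# Grid search over feature families and SVM parameters
# ---------------------------------------------------------------------------

def grid_search(
    instances: Sequence[Instance],
    feature_subsets: Sequence[frozenset[str]],
    param_grid: Sequence[dict],
    trainer: Trainer,
    base_cfg: ClassifierConfig,
    k: int = 5,
    seed: int = 0,
) -> tuple[frozenset[str], ClassifierConfig, pd.DataFrame]:
    """Exhaustive search over feature-family subsets x SVM parameters.

    Instances carry fully featured vectors; each candidate subset is
    evaluated by restricting vectors to its families (features are
    namespaced, so restriction is a key filter) and running k-fold CV.
    Selection maximizes the mean of per-fold accuracies; ties break toward
    fewer feature families, then smaller C.
    """
    import dataclasses

    rows = []
    best = None
    for families, params in itertools.product(feature_subsets, param_grid):
        cfg = dataclasses.replace(
            base_cfg,
            feature_config=dataclasses.replace(
                base_cfg.feature_config, enabled_families=frozenset(families)),
            **params,
        )
        restricted = [(restrict_to_families(v, frozenset(families)), l)
                      for v, l in instances]
        report = cross_validate_pooled(restricted, trainer, cfg, k=k, seed=seed)
        mean_fold_acc = float(np.mean(report.per_fold_accuracies))
        rows.append({
            "families": "+".join(sorted(families)),
            **params,
            "mean_fold_accuracy": mean_fold_acc,
            "pooled_accuracy": report.accuracy,
        })
        key = (-mean_fold_acc, len(families), cfg.C)
        if best is None or key < best[0]:
            best = (key, frozenset(families), cfg)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


# ---------------------------------------------------------------------------
# Leave-one-gene-out
# ---------------------------------------------------------------------------

def leave_one_gene_out(
    groups: Mapping[str, Sequence[Instance]],
    trainer: Trainer,
    cfg: ClassifierConfig,
    categories: Optional[Sequence] = None,
) -> tuple[dict[str, EvaluationReport], float]:
    """Gene-neutral evaluation: train on all other genes, test on each gene.

    Returns per-gene reports and the unweighted macro average of per-gene
    accuracies.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 gene groups")
    for gene, insts in groups.items():
        if not insts:
            raise ValueError(f"gene group {gene!r} has zero instances")
    reports: dict[str, EvaluationReport] = {}
    for gene in groups:
        train = [inst for g, insts in groups.items() if g != gene for inst in insts]
        test = groups[gene]
        model = trainer(train, cfg)
        preds = model.predict([v for v, _ in test])
        gold = [l for _, l in test]
        cats = categories if categories is not None else sorted(
            set(gold) | set(preds), key=lambda c: getattr(c, "ordinal", 0))
        reports[gene] = make_report(
            preds, gold, cats,
            descriptor={"design": "leave-one-gene-out", "held_out_gene": gene,
                        "train_size": len(train)},
            keep_predictions=True,
        )
    macro = macro_average([r.accuracy for r in reports.values()])
    return reports, macro


# ---------------------------------------------------------------------------
# Iterative retraining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IterationResult:
    iteration: int
    accuracy: Optional[float]  # None when the batch was empty (skipped)
    batch_size: int
    cumulative_training_size: int
    skipped: bool = False


def iterative_retraining(
    initial: Sequence[Instance],
    batches: Sequence[Sequence[Instance]],
    trainer: Trainer,
    cfg: ClassifierConfig,
) -> list[IterationResult]:
    """Score-then-absorb retraining loop.

    At iteration i the model trained on the initial pool plus batches
    1..i-1 is scored on batch i (its labels playing the corrected gold
    standard), after which batch i joins the pool. Categories that first
    appear in a batch simply enter the training pool and become predictable
    from the next retraining on. Empty batches are skipped with a flag and
    leave the pool unchanged.
    """
    if not batches:
        raise ValueError("need at least one batch")
    pool: list[Instance] = list(initial)
    results: list[IterationResult] = []
    for i, batch in enumerate(batches, start=1):
        if len(batch) == 0:
            results.append(IterationResult(
                iteration=i, accuracy=None, batch_size=0,
                cumulative_training_size=len(pool), skipped=True))
            continue
        model = trainer(pool, cfg)
        preds = model.predict([v for v, _ in batch])
        acc = accuracy(preds, [l for _, l in batch])
        pool.extend(batch)
        results.append(IterationResult(
            iteration=i, accuracy=acc, batch_size=len(batch),
            cumulative_training_size=len(pool)))
    return results
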