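"""Single-stage and two-stage (cascade) SVM classifiers over status categories.

The single-stage model discriminates all enabled leaf categories at once and
serves as the baseline. The cascade first separates the three coarse classes
(Gene-related / Drug / Others) and only consults a second, leaf-level model
when stage 1 says Gene-related — the rationale being that telling a gene
apart from an English word or a drug name is a different (and easier)
problem than grading a lesion status, and excluding non-gene senses removes
noise from the second decision.

Both stages are support-vector machines (libsvm via scikit-learn's ``SVC``)
with the native one-vs-one pairwise decomposition. Labels are encoded by
category ordinal, so pairwise-vote ties resolve toward the lowest ordinal.
Each stage owns a frozen feature vocabulary (a ``DictVectorizer`` fitted at
training time); test-time features outside the vocabulary are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import SVC

from .categories import (
    CATEGORY_ORDER,
    Stage1Label,
    StatusCategory,
    coarsen_label,
)
from .feature_extraction import FeatureConfig, FeatureVector

__all__ = [
    "StatusCategory",
    "Stage1Label",
    "coarsen_label",
    "ClassifierConfig",
    "SingleStageModel",
    "CascadeModel",
    "train_single_stage",
    "train_two_stage",
    "predict_cascade",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class DegenerateTrainingError(ValueError):
    """Training set does not contain enough distinct labels."""


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM hyperparameters shared by both stages.

    ``gamma`` applies only to the RBF kernel; ``"scale"`` uses the standard
    1 / (n_features * Var(X)) heuristic.
    """

    kernel: str = "linear"
    C: float = 1.0
    gamma: float | str = "scale"
    seed: int = 0
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be linear or rbf, got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _make_svc(cfg: ClassifierConfig) -> SVC:
    return SVC(
        kernel=cfg.kernel,
        C=cfg.C,
        gamma=cfg.gamma if cfg.kernel == "rbf" else "scale",
        decision_function_shape="ovo",
        random_state=cfg.seed,
    )


def _int32_csr(X) -> sp.csr_matrix:
    # libsvm requires 32-bit sparse indices
    X = sp.csr_matrix(X)
    return sp.csr_matrix(
        (X.data, X.indices.astype(np.int32), X.indptr.astype(np.int32)),
        shape=X.shape,
    )


def _ordinal(label) -> int:
    if isinstance(label, StatusCategory):
        return CATEGORY_ORDER.index(label)
    return list(Stage1Label).index(label)


@dataclass
class _Stage:
    """One trained SVM stage: frozen vocabulary + fitted estimator."""

    vectorizer: DictVectorizer
    svc: SVC
    labels: list  # ordinal-sorted label objects; svc classes are indices into it

    @classmethod
    def fit(cls, vectors: Sequence[FeatureVector], labels: Sequence, cfg: ClassifierConfig,
            stage_name: str) -> "_Stage":
        distinct = sorted(set(labels), key=_ordinal)
        if len(distinct) < 2:
            raise DegenerateTrainingError(
                f"{stage_name} training set has {len(distinct)} distinct label(s); need >= 2"
            )
        vectorizer = DictVectorizer(sparse=True)
        X = _int32_csr(vectorizer.fit_transform(vectors))
        y = [distinct.index(l) for l in labels]
        svc = _make_svc(cfg)
        svc.fit(X, y)
        return cls(vectorizer=vectorizer, svc=svc, labels=distinct)

    def predict(self, vectors: Sequence[FeatureVector]) -> list:
        X = _int32_csr(self.vectorizer.transform(vectors))  # unseen features dropped
        return [self.labels[i] for i in self.svc.predict(X)]


@dataclass
class SingleStageModel:
    """Baseline: one SVM over all enabled leaf categories."""

    stage: _Stage
    config: ClassifierConfig

    def predict(self, vectors: Sequence[FeatureVector]) -> list[StatusCategory]:
        return self.stage.predict(vectors)

    def predict_one(self, vector: FeatureVector) -> StatusCategory:
        return self.predict([vector])[0]

    @property
    def categories(self) -> list[StatusCategory]:
        return list(self.stage.labels)


@dataclass
class CascadeModel:
    """Two-stage cascade: coarse 3-way model, then a leaf model for Gene-related.

    ``stage2_calls`` counts how many instances reached stage 2, making the
    short-circuit behavior (Drug/Others never consult stage 2) observable.
    """

    stage1: _Stage
    stage2: _Stage
    config: ClassifierConfig
    stage2_calls: int = 0

    def predict_stage1(self, vectors: Sequence[FeatureVector]) -> list[Stage1Label]:
        return self.stage1.predict(vectors)

    def predict(self, vectors: Sequence[FeatureVector]) -> list[StatusCategory]:
        coarse = self.stage1.predict(vectors)
        gene_related_idx = [i for i, c in enumerate(coarse) if c is Stage1Label.GENE_RELATED]
        out: list[Optional[StatusCategory]] = [
            StatusCategory.DRUG if c is Stage1Label.DRUG
            else StatusCategory.OTHERS if c is Stage1Label.OTHERS
            else None
            for c in coarse
        ]
        if gene_related_idx:
            self.stage2_calls += len(gene_related_idx)
            leaf = self.stage2.predict([vectors[i] for i in gene_related_idx])
            for i, cat in zip(gene_related_idx, leaf):
                out[i] = cat
        return out  # type: ignore[return-value]

    def predict_one(self, vector: FeatureVector) -> StatusCategory:
        return self.predict([vector])[0]


Instance = tuple[FeatureVector, StatusCategory]


def train_single_stage(instances: Sequence[Instance], cfg: ClassifierConfig) -> SingleStageModel:
    """Fit the baseline 6-way (or 7-way) SVM on labeled feature vectors."""
    vectors = [v for v, _ in instances]
    labels = [l for _, l in instances]
    return SingleStageModel(stage=_Stage.fit(vectors, labels, cfg, "single-stage"),
                            config=cfg)


def train_two_stage(instances: Sequence[Instance], cfg: ClassifierConfig) -> CascadeModel:
    """Fit the cascade.

    Stage 1 trains on all instances with coarsened labels; stage 2 trains
    only on the gold Gene-related subset with leaf labels (training stage 2
    on gold rather than stage-1 predictions keeps cascade training noise out
    of the leaf model).
    """
    vectors = [v for v, _ in instances]
    leaf_labels = [l for _, l in instances]
    coarse_labels = [coarsen_label(l) for l in leaf_labels]
    gr = [
        (v, l) for v, l in instances
        if coarsen_label(l) is Stage1Label.GENE_RELATED
    ]
    if not gr:
        raise DegenerateTrainingError("no Gene-related instances; stage 2 untrainable")
    stage1 = _Stage.fit(vectors, coarse_labels, cfg, "stage 1")
    stage2 = _Stage.fit([v for v, _ in gr], [l for _, l in gr], cfg, "stage 2")
    return CascadeModel(stage1=stage1, stage2=stage2, config=cfg)


def predict_cascade(model: CascadeModel, vector: FeatureVector) -> StatusCategory:
    """Classify one feature vector through the cascade."""
    return model.predict_one(vector)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: SingleStageModel | CascadeModel, directory: str | Path) -> None:
    """Persist a trained model to a directory with a versioned manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "mode": "two-stage" if isinstance(model, CascadeModel) else "single",
        "kernel": cfg.kernel,
        "C": cfg.C,
        "gamma": cfg.gamma,
        "seed": cfg.seed,
        "feature_config": {
            "context_window": cfg.feature_config.context_window,
            "negation_window": cfg.feature_config.negation_window,
            "enabled_families": sorted(cfg.feature_config.enabled_families),
            "lowercase_lexical": cfg.feature_config.lowercase_lexical,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                             encoding="utf-8")
    if isinstance(model, CascadeModel):
        joblib.dump(model.stage1, directory / "stage1.joblib")
        joblib.dump(model.stage2, directory / "stage2.joblib")
    else:
        joblib.dump(model.stage, directory / "stage.joblib")


def load_model(directory: str | Path) -> SingleStageModel | CascadeModel:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no model manifest in {directory}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    if manifest.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {manifest.get('format_version')}")
    fc = manifest["feature_config"]
    cfg = ClassifierConfig(
        kernel=manifest["kernel"], C=manifest["C"], gamma=manifest["gamma"],
        seed=manifest["seed"],
        feature_config=FeatureConfig(
            context_window=fc["context_window"],
            negation_window=fc["negation_window"],
            enabled_families=frozenset(fc["enabled_families"]),
            lowercase_lexical=fc["lowercase_lexical"],
        ),
    )
    if manifest["mode"] == "two-stage":
        return CascadeModel(
            stage1=joblib.load(directory / "stage1.joblib"),
            stage2=joblib.load(directory / "stage2.joblib"),
            config=cfg,
        )
    return SingleStageModel(stage=joblib.load(directory / "stage.joblib"), config=cfg)
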