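"""Two-stage stacking ensemble with a random-forest meta-learner.

Stage one trains ten CNN base classifiers per encoding, one per
cross-validation fold: each fold model is trained on the other nine folds,
scores its own held-out fold (the out-of-fold prediction) and scores the
independent test set. Stage two merges, per base algorithm, the out-of-fold
scores into a meta cross-validation dataset and the across-fold averaged test
scores into a meta independent-test dataset; a random forest is trained on the
former and evaluated on the latter.

Ensemble variants are named by their base encodings: ``O+Z+W``, ``O+Z+W+E``
and ``O+Z+W+E+EG``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import cnn
from .datasets import SplitPlan
from .encoders import encode
from .metrics import roc_auc
from .windows import PeptideWindow

#: Ensemble variants by base-encoding letters (O=OH, Z=ZSCALE, W=WE, E=EAAC,
#: EG=EGAAC).
VARIANTS: Mapping[str, tuple[str, ...]] = {
    "O+Z+W": ("OH", "ZSCALE", "WE"),
    "O+Z+W+E": ("OH", "ZSCALE", "WE", "EAAC"),
    "O+Z+W+E+EG": ("OH", "ZSCALE", "WE", "EAAC", "EGAAC"),
}

INDEPENDENT = -1  # provenance marker for meta-test rows


@dataclass(frozen=True)
class RFMetaConfig:
    """Random-forest meta-learner hyperparameters (grid-search optimum)."""

    max_depth: int = 8
    max_features: str = "sqrt"
    min_samples_leaf: int = 20
    min_samples_split: int = 300
    n_estimators: int = 100
    seed: int = 0


@dataclass
class MetaDataset:
    """Base-classifier scores as features for the meta-learner.

    ``provenance[i]`` is the CV fold whose model produced row ``i``'s scores,
    or ``INDEPENDENT`` (-1) for averaged independent-test rows.
    """

    features: np.ndarray  # (n_windows, n_algorithms), scores in [0, 1]
    labels: np.ndarray
    algorithms: list[str]
    provenance: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != len(self.algorithms):
            raise ValueError("feature matrix must be (n_windows, n_algorithms)")
        if np.any(self.features < 0) or np.any(self.features > 1):
            raise ValueError("base scores must lie in [0, 1]")
        if len(self.labels) != len(self.features) or \
                len(self.provenance) != len(self.features):
            raise ValueError("labels/provenance length mismatch")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.algorithms)
        df["label"] = self.labels
        df["provenance"] = [
            "independent" if p == INDEPENDENT else int(p) for p in self.provenance
        ]
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def build_meta_dataset(
    cv_fold_scores: Mapping[str, np.ndarray],
    test_fold_scores: Mapping[str, np.ndarray],
    cv_labels: Sequence[int],
    test_labels: Sequence[int],
) -> tuple[MetaDataset, MetaDataset]:
    """Merge per-fold base scores into meta CV and meta test datasets.

    ``cv_fold_scores[alg]`` is an (n_folds, n_cv) array holding each fold
    model's scores on its own held-out fold and NaN elsewhere; every CV window
    must be scored exactly once per algorithm. ``test_fold_scores[alg]`` is an
    (n_folds, n_test) array of every fold model's scores on the independent
    test set; these are averaged across folds.
    """
    algorithms = list(cv_fold_scores)
    if list(test_fold_scores) != algorithms:
        raise ValueError("CV and test score dicts must list the same algorithms")
    cv_labels = np.asarray(cv_labels)
    test_labels = np.asarray(test_labels)
    oof_cols, prov = [], None
    for alg in algorithms:
        S = np.asarray(cv_fold_scores[alg], dtype=float)
        scored = ~np.isnan(S)
        counts = scored.sum(axis=0)
        if np.any(counts != 1):
            bad = int(np.nonzero(counts != 1)[0][0])
            raise ValueError(
                f"algorithm {alg}: window {bad} has {int(counts[bad])} "
                "out-of-fold scores (need exactly 1)"
            )
        fold_of = scored.argmax(axis=0)
        if prov is None:
            prov = fold_of
        elif not np.array_equal(prov, fold_of):
            raise ValueError("algorithms disagree on out-of-fold provenance")
        oof_cols.append(S[fold_of, np.arange(S.shape[1])])
    meta_cv = MetaDataset(
        features=np.column_stack(oof_cols),
        labels=cv_labels,
        algorithms=algorithms,
        provenance=prov,
    )
    test_cols = []
    for alg in algorithms:
        S = np.asarray(test_fold_scores[alg], dtype=float)
        if np.isnan(S).any():
            raise ValueError(f"algorithm {alg}: NaN in independent-test scores")
        test_cols.append(S.mean(axis=0))
    meta_test = MetaDataset(
        features=np.column_stack(test_cols),
        labels=test_labels,
        algorithms=algorithms,
        provenance=np.full(len(test_labels), INDEPENDENT),
    )
    return meta_cv, meta_test


def assert_no_leakage(meta_cv: MetaDataset, window_fold: Sequence[int]) -> None:
    """Check every out-of-fold score came from the window's own held-out fold.

    Fold model ``f`` trains on every CV fold except ``f``; a window assigned
    to fold ``f`` may therefore only be scored by model ``f``.
    """
    window_fold = np.asarray(window_fold)
    if not np.array_equal(meta_cv.provenance, window_fold):
        bad = int(np.nonzero(meta_cv.provenance != window_fold)[0][0])
        raise AssertionError(
            f"window {bad}: scored by fold model {meta_cv.provenance[bad]} "
            f"but assigned to fold {window_fold[bad]} — leakage"
        )


def train_meta(meta_cv: MetaDataset, config: RFMetaConfig | None = None
               ) -> RandomForestClassifier:
    """Fit the random-forest meta-learner on out-of-fold base scores."""
    if config is None:
        config = RFMetaConfig()
    if len(np.unique(meta_cv.labels)) < 2:
        raise ValueError("meta training labels are single-class")
    rf = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        max_features=config.max_features,
        min_samples_leaf=config.min_samples_leaf,
        min_samples_split=config.min_samples_split,
        random_state=config.seed,
    )
    rf.fit(meta_cv.features, meta_cv.labels)
    return rf


def predict_meta(model: RandomForestClassifier, meta: MetaDataset) -> np.ndarray:
    """Meta-classifier probability scores in [0, 1], one per window."""
    if meta.features.shape[1] != model.n_features_in_:
        raise ValueError(
            f"meta model expects {model.n_features_in_} base algorithms, "
            f"got {meta.features.shape[1]}"
        )
    return model.predict_proba(meta.features)[:, 1]


def grid_search_meta(
    meta_cv: MetaDataset,
    param_grid: Mapping[str, Sequence] | None = None,
    cv: int = 5,
    seed: int = 0,
) -> RFMetaConfig:
    """Optional re-optimization of the meta-learner hyperparameters."""
    from sklearn.model_selection import GridSearchCV

    if param_grid is None:
        param_grid = {
            "max_depth": [4, 8, 16],
            "min_samples_leaf": [1, 20],
            "min_samples_split": [2, 300],
        }
    base = RandomForestClassifier(
        n_estimators=100, max_features="sqrt", random_state=seed
    )
    gs = GridSearchCV(base, dict(param_grid), cv=cv, scoring="roc_auc")
    gs.fit(meta_cv.features, meta_cv.labels)
    best = {**RFMetaConfig().__dict__, **gs.best_params_, "seed": seed}
    return RFMetaConfig(**{k: best[k] for k in RFMetaConfig.__dataclass_fields__})


# ---------------------------------------------------------------------------
# End-to-end stacking runner
# ---------------------------------------------------------------------------

@dataclass
class StackingResult:
    """Everything stage one and stage two produced."""

    meta_cv: MetaDataset
    meta_test: MetaDataset
    meta_model: RandomForestClassifier
    meta_test_scores: np.ndarray
    base_fold_models: dict[str, list[cnn.TrainedModel]]
    base_test_auc: dict[str, float]  # AUC of the fold-averaged test scores
    base_fold_test_auc: dict[str, list[float]]  # per fold model
    window_fold: np.ndarray

    @property
    def meta_test_auc(self) -> float:
        return roc_auc(self.meta_test.labels, self.meta_test_scores)


def run_stacking(
    windows: Sequence[PeptideWindow],
    labels: Sequence[int],
    plan: SplitPlan,
    encodings: Sequence[str] = VARIANTS["O+Z+W"],
    base_config: cnn.ModelConfig | None = None,
    rf_config: RFMetaConfig | None = None,
    seed: int = 0,
) -> StackingResult:
    """Run the full two-stage pipeline on a split dataset.

    Base fold models train for a fixed epoch count (no early stopping), so no
    out-of-fold window can influence its own base model even indirectly.
    """
    labels = np.asarray(labels)
    cv_idx = plan.cv_indices
    test_idx = plan.test_indices
    n_folds = len(plan.cv_group_ids)
    pos_in_cv = {int(w): i for i, w in enumerate(cv_idx)}
    window_fold = np.empty(len(cv_idx), dtype=int)
    for f, g in enumerate(plan.cv_group_ids):
        for w in plan.groups[g]:
            window_fold[pos_in_cv[int(w)]] = f

    cv_scores: dict[str, np.ndarray] = {}
    test_scores: dict[str, np.ndarray] = {}
    fold_models: dict[str, list[cnn.TrainedModel]] = {}
    base_fold_auc: dict[str, list[float]] = {}
    for enc in encodings:
        X = encode(windows, enc)
        cfg = cnn.ModelConfig(encoding=enc, patience=None) if base_config is None \
            else replace(base_config, encoding=enc)
        S_cv = np.full((n_folds, len(cv_idx)), np.nan)
        S_test = np.empty((n_folds, len(test_idx)))
        fold_models[enc] = []
        base_fold_auc[enc] = []
        for f, g in enumerate(plan.cv_group_ids):
            held = window_fold == f
            train_rows = cv_idx[~held]
            model = cnn.train(
                replace(cfg, seed=seed * 1000 + f),
                X[train_rows], labels[train_rows],
            )
            S_cv[f, held] = cnn.predict(model, X[cv_idx[held]])
            S_test[f] = cnn.predict(model, X[test_idx])
            base_fold_auc[enc].append(roc_auc(labels[test_idx], S_test[f]))
            fold_models[enc].append(model)
        cv_scores[enc] = S_cv
        test_scores[enc] = S_test

    meta_cv, meta_test = build_meta_dataset(
        cv_scores, test_scores, labels[cv_idx], labels[test_idx]
    )
    assert_no_leakage(meta_cv, window_fold)
    meta_model = train_meta(meta_cv, rf_config or RFMetaConfig(seed=seed))
    meta_scores = predict_meta(meta_model, meta_test)
    base_test_auc = {
        enc: roc_auc(labels[test_idx], test_scores[enc].mean(axis=0))
        for enc in encodings
    }
    return StackingResult(
        meta_cv=meta_cv,
        meta_test=meta_test,
        meta_model=meta_model,
        meta_test_scores=meta_scores,
        base_fold_models=fold_models,
        base_test_auc=base_test_auc,
        base_fold_test_auc=base_fold_auc,
        window_fold=window_fold,
    )
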