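"""Decision-tree workload model: LOSO evaluation, channel subsets, ICA audit.

The classifier is a CART decision tree with grid-searched depth (capped at
10), minimum leaf size and split criterion, trained on one spectral
feature's values over a channel subset. Evaluation is leave-one-subject-out:
every subject's epochs form the validation set exactly once, with the grid
search nested inside each training fold, and per-subject accuracy,
macro precision/recall/F1 and macro one-vs-rest ROC-AUC are reported.
Training is class-weighted because one resting block faces four working
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from ._rng import child_seed
from .ranking import SCHEME_CLASS_ORDER, apply_label_scheme
from .spectral import FeatureTable

__all__ = [
    "ModelConfig",
    "SubjectResult",
    "ModelReport",
    "ICAAuditReport",
    "train_eval_loso",
    "channel_subset_sweep",
    "ica_audit",
]


def _default_tree_grid() -> dict:
    return {
        "max_depth": [3, 5, 7, 10],
        "min_samples_leaf": [1, 5, 20],
        "criterion": ["gini", "entropy"],
    }


@dataclass(frozen=True)
class ModelConfig:
    feature_id: int = 16            # beta + theta + alpha + gamma
    scheme: str = "D"
    max_depth: int = 10
    grid: dict = field(default_factory=_default_tree_grid)
    inner_cv: int = 3
    channels: tuple[str, ...] | str = "all"
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        for d in self.grid.get("max_depth", []):
            if d > self.max_depth:
                raise ValueError(
                    f"grid depth {d} exceeds the max_depth cap {self.max_depth}"
                )


@dataclass
class SubjectResult:
    subject_id: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float
    confusion: np.ndarray
    classes: tuple[str, ...]
    best_params: dict


@dataclass
class ModelReport:
    per_subject: list[SubjectResult]
    channels: tuple[str, ...]
    config: ModelConfig

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.per_subject])

    @property
    def mean_accuracy(self) -> float:
        return float(self.metric("accuracy").mean())

    def summary(self) -> pd.DataFrame:
        rows = {
            m: self.metric(m)
            for m in ("accuracy", "precision", "recall", "f1", "roc_auc")
        }
        df = pd.DataFrame(rows, index=[r.subject_id for r in self.per_subject])
        df.index.name = "subject"
        return df


def _channel_indices(ft: FeatureTable, channels) -> list[int]:
    if isinstance(channels, str):
        if channels != "all":
            channels = (channels,)
        else:
            return list(range(len(ft.channel_labels)))
    idx = []
    for ch in channels:
        if ch not in ft.channel_labels:
            raise ValueError(f"channel {ch!r} not in feature table")
        idx.append(ft.channel_labels.index(ch))
    if not idx:
        raise ValueError("empty channel subset")
    return idx


def train_eval_loso(ft: FeatureTable, config: ModelConfig) -> ModelReport:
    """Leave-one-subject-out evaluation of the decision-tree model."""
    idx = _channel_indices(ft, config.channels)
    X_all = ft.feature(config.feature_id)[:, idx]
    y_all = apply_label_scheme(ft.conditions, config.scheme)
    groups = ft.subject_array
    subjects = list(dict.fromkeys(ft.subjects))  # preserve order
    if len(subjects) < 3:
        raise ValueError("LOSO evaluation needs at least 3 subjects")
    classes = [c for c in SCHEME_CLASS_ORDER[config.scheme]
               if c in set(y_all.tolist())]
    ok = ~np.isnan(X_all).any(axis=1)

    results = []
    for sid in subjects:
        test = (groups == sid) & ok
        train = (groups != sid) & ok
        y_train = y_all[train]
        if np.unique(y_all[test]).size < 2:
            raise ValueError(f"held-out subject {sid} has a single class")
        seed = child_seed(config.seed, sid, "tree") % (2**32)
        tree = DecisionTreeClassifier(class_weight="balanced", random_state=seed)
        gs = GridSearchCV(
            tree, config.grid,
            cv=StratifiedKFold(config.inner_cv, shuffle=True, random_state=seed),
            scoring="accuracy",
        )
        gs.fit(X_all[train], y_train)
        est = gs.best_estimator_
        y_pred = est.predict(X_all[test])
        y_true = y_all[test]
        cm = confusion_matrix(y_true, y_pred, labels=classes)
        accuracy = float(np.trace(cm) / cm.sum())
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=classes, average="macro", zero_division=0
        )
        proba = est.predict_proba(X_all[test])
        # columns of predict_proba follow est.classes_; realign to `classes`
        order = [list(est.classes_).index(c) for c in classes]
        proba = proba[:, order]
        if len(classes) == 2:
            auc = float(roc_auc_score((y_true == classes[1]).astype(int), proba[:, 1]))
        else:
            # roc_auc_score wants lexically ordered labels
            lex = sorted(classes)
            lex_cols = [classes.index(c) for c in lex]
            auc = float(roc_auc_score(y_true, proba[:, lex_cols],
                                      multi_class="ovr", average="macro",
                                      labels=lex))
        results.append(SubjectResult(
            subject_id=sid, accuracy=accuracy, precision=float(prec),
            recall=float(rec), f1=float(f1), roc_auc=auc,
            confusion=cm, classes=tuple(classes), best_params=dict(gs.best_params_),
        ))
    ch_labels = tuple(ft.channel_labels[i] for i in idx)
    return ModelReport(per_subject=results, channels=ch_labels, config=config)


def channel_subset_sweep(
    ft: FeatureTable, subsets, config: ModelConfig
) -> list[ModelReport]:
    """Evaluate several channel subsets with identical folds and seeds."""
    reports = []
    for subset in subsets:
        cfg = ModelConfig(
            feature_id=config.feature_id, scheme=config.scheme,
            max_depth=config.max_depth, grid=config.grid,
            inner_cv=config.inner_cv, channels=tuple(subset), seed=config.seed,
        )
        reports.append(train_eval_loso(ft, cfg))
    return reports


@dataclass
class ICAAuditReport:
    """Per-channel single-channel LOSO accuracy with vs without ICA."""

    table: pd.DataFrame     # index channel; columns acc_with_ica, acc_without_ica, abs_diff
    tolerance: float

    @property
    def stable(self) -> list[str]:
        """Channels whose accuracy moves by at most the tolerance."""
        return [c for c in self.table.index
                if self.table.loc[c, "abs_diff"] <= self.tolerance]


def ica_audit(
    ft_with_ica: FeatureTable,
    ft_without_ica: FeatureTable,
    channels,
    config: ModelConfig,
    tolerance: float = 0.05,
) -> ICAAuditReport:
    """Compare single-channel model accuracy between preprocessing variants.

    Both feature tables must come from the same raw recordings, one
    preprocessed with ICA artifact removal and one without. An empty
    channel list yields an empty report.
    """
    rows = []
    for ch in channels:
        accs = {}
        for name, ft in (("acc_with_ica", ft_with_ica),
                         ("acc_without_ica", ft_without_ica)):
            cfg = ModelConfig(
                feature_id=config.feature_id, scheme=config.scheme,
                max_depth=config.max_depth, grid=config.grid,
                inner_cv=config.inner_cv, channels=(ch,), seed=config.seed,
            )
            accs[name] = train_eval_loso(ft, cfg).mean_accuracy
        rows.append({
            "channel": ch,
            "acc_with_ica": accs["acc_with_ica"],
            "acc_without_ica": accs["acc_without_ica"],
            "abs_diff": abs(accs["acc_with_ica"] - accs["acc_without_ica"]),
        })
    table = pd.DataFrame(rows).set_index("channel") if rows else pd.DataFrame(
        columns=["acc_with_ica", "acc_without_ica", "abs_diff"]
    )
    return ICAAuditReport(table=table, tolerance=tolerance)
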