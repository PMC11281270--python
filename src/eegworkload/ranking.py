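"""SVM feature ranking under the four workload labeling schemes.

Each of the 26 spectral features is scored by grid-searched RBF-SVM
cross-validated accuracy, separately under four labelings of the five
conditions:

    A  resting/working (binary)
    B  0 / medium-low {scn1, scn2} / high {scn3, scn4}
    C  0 / low {scn1} / medium-high {scn2, scn3, scn4}
    D  0 / low {scn1} / medium {scn2} / high {scn3, scn4}

Multiclass problems use the SVM's native one-vs-one voting (argmax vote
aggregation resolves ties toward the lowest class index). Cross-validation
is stratified 5-fold grouped by subject so no subject's epochs straddle a
train/test boundary, and features are z-scored inside each training fold.
The best feature overall is the one with the highest mean accuracy across
the four schemes (ties toward the lower feature id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .montage import CONDITIONS
from .spectral import FeatureTable

__all__ = [
    "SCHEMES",
    "SCHEME_CLASS_ORDER",
    "apply_label_scheme",
    "RankingReport",
    "rank_features",
    "DEFAULT_SVM_GRID",
]

SCHEMES: dict[str, dict[str, str]] = {
    "A": {
        "resting": "resting",
        "scenario1": "working", "scenario2": "working",
        "scenario3": "working", "scenario4": "working",
    },
    "B": {
        "resting": "0",
        "scenario1": "medium-low", "scenario2": "medium-low",
        "scenario3": "high", "scenario4": "high",
    },
    "C": {
        "resting": "0",
        "scenario1": "low",
        "scenario2": "medium-high", "scenario3": "medium-high",
        "scenario4": "medium-high",
    },
    "D": {
        "resting": "0",
        "scenario1": "low",
        "scenario2": "medium",
        "scenario3": "high", "scenario4": "high",
    },
}

#: class labels in increasing-workload order, per scheme
SCHEME_CLASS_ORDER = {
    "A": ("resting", "working"),
    "B": ("0", "medium-low", "high"),
    "C": ("0", "low", "medium-high"),
    "D": ("0", "low", "medium", "high"),
}

DEFAULT_SVM_GRID = {
    "svc__C": [0.1, 1.0, 10.0, 100.0],
    "svc__gamma": list(np.logspace(-3, 1, 5)),
}


def apply_label_scheme(conditions, scheme: str) -> np.ndarray:
    """Map condition names to class labels under scheme A, B, C or D."""
    if scheme not in SCHEMES:
        raise KeyError(f"unknown scheme {scheme!r}; valid: {sorted(SCHEMES)}")
    table = SCHEMES[scheme]
    out = []
    for c in conditions:
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r}")
        out.append(table[c])
    return np.asarray(out)


@dataclass
class RankingReport:
    accuracy: pd.DataFrame          # index: feature id; columns: scheme
    best_per_scheme: dict[str, int]
    best_overall: int
    best_params: dict = field(default_factory=dict)  # (feature, scheme) -> params

    def mean_accuracy(self) -> pd.Series:
        return self.accuracy.mean(axis=1)


def _score_one(X, y, groups, grid, n_splits, seed) -> tuple[float, dict]:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("single-class labeling; cannot rank")
    n_groups = np.unique(groups).size
    cv = StratifiedGroupKFold(n_splits=min(n_splits, n_groups), shuffle=True,
                              random_state=seed % (2**32))
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", cache_size=100)),
    ])
    gs = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy", n_jobs=None,
                      refit=False)
    gs.fit(X, y, groups=groups)
    return float(gs.best_score_), dict(gs.best_params_)


def rank_features(
    ft: FeatureTable,
    schemes=("A", "B", "C", "D"),
    grid: dict | None = None,
    n_splits: int = 5,
    seed: int = 0,
) -> RankingReport:
    """Cross-validated SVM accuracy per (feature, scheme).

    The per-epoch predictor for a feature is the vector of that feature's
    values across all channels. Epochs with any NaN feature value are
    dropped for that feature.
    """
    grid = grid or DEFAULT_SVM_GRID
    groups = ft.subject_array
    conditions = ft.conditions
    acc = pd.DataFrame(index=list(ft.feature_ids), columns=list(schemes),
                       dtype=float)
    best_params: dict = {}
    for fid in ft.feature_ids:
        X = ft.feature(fid)
        ok = ~np.isnan(X).any(axis=1)
        for scheme in schemes:
            y = apply_label_scheme(conditions[ok], scheme)
            score, params = _score_one(X[ok], y, groups[ok], grid, n_splits, seed)
            acc.loc[fid, scheme] = score
            best_params[(fid, scheme)] = params
    best_per_scheme = {s: int(acc[s].idxmax()) for s in schemes}
    mean_acc = acc.mean(axis=1)
    # idxmax returns the first (lowest id) on ties
    best_overall = int(mean_acc.idxmax())
    return RankingReport(
        accuracy=acc,
        best_per_scheme=best_per_scheme,
        best_overall=best_overall,
        best_params=best_params,
    )
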