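"""SVM group classification over electrophysiological and behavioral features.

A soft-margin support vector machine with a third-degree polynomial
kernel ``K(x, y) = (0.25 x'y + 1)^3`` separates the two groups; the
penalty constant C is grid-searched over the integers 1..10 inside each
training fold.  Model selection and accuracy are assessed with 10
stratified Monte-Carlo splits using 75% of the subjects for training
and 25% for testing; feature standardization is fitted on the training
portion only, so no information leaks into the test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureSet",
    "CVReport",
    "svm_classify",
    "build_feature_sets",
    "repeat_cv",
]

logger = logging.getLogger(__name__)

C_GRID = list(range(1, 11))
GAMMA = 0.25
DEGREE = 3
COEF0 = 1.0


@dataclass
class FeatureSet:
    """A subjects x features matrix with two-level group labels."""

    name: str
    band: str
    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.matrix.shape[0] != self.labels.size:
            raise ValueError("one label per subject required")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains NaN")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 subjects")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.matrix.shape[1])]


@dataclass
class CVReport:
    """Cross-validated classification outcome."""

    fold_accuracies: np.ndarray
    selected_C: list[int]
    kernel: str
    seed: int
    feature_set: str

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))


def _make_estimator(inner_seed: int, n_inner: int = 3) -> GridSearchCV:
    svc = SVC(
        kernel="poly", degree=DEGREE, gamma=GAMMA, coef0=COEF0,
        class_weight="balanced",
    )
    pipe = Pipeline([("scale", StandardScaler()), ("svm", svc)])
    inner = StratifiedKFold(
        n_splits=n_inner, shuffle=True, random_state=inner_seed
    )
    return GridSearchCV(
        pipe, {"svm__C": C_GRID}, cv=inner, scoring="accuracy", n_jobs=1
    )


def svm_classify(
    features: FeatureSet,
    seed: int = 0,
    n_splits: int = 10,
    test_size: float = 0.25,
    scheme: str = "monte_carlo",
) -> CVReport:
    """Cross-validated SVM accuracy for one feature set.

    ``scheme="monte_carlo"`` (default) draws ``n_splits`` stratified
    75/25 train/test splits; ``scheme="kfold"`` runs classic stratified
    10-fold CV instead.  C selection is nested: a 3-fold grid search
    runs inside each training portion.
    """
    X, y = features.matrix, features.labels
    if scheme == "monte_carlo":
        splitter = StratifiedShuffleSplit(
            n_splits=n_splits, test_size=test_size, random_state=seed
        )
    elif scheme == "kfold":
        splitter = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=seed
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    accs, cs = [], []
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                "a class is absent from a training fold; use stratification "
                "or more data"
            )
        min_class = int(np.unique(y[tr], return_counts=True)[1].min())
        if min_class >= 2:
            est = _make_estimator(
                inner_seed=(seed * 1000 + k) % (2**31 - 1),
                n_inner=min(3, min_class),
            )
            est.fit(X[tr], y[tr])
            accs.append(est.score(X[te], y[te]))
            cs.append(int(est.best_params_["svm__C"]))
        else:  # too few subjects for nested selection; fixed C
            pipe = Pipeline([
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="poly", degree=DEGREE, gamma=GAMMA,
                            coef0=COEF0, class_weight="balanced", C=1)),
            ])
            pipe.fit(X[tr], y[tr])
            accs.append(pipe.score(X[te], y[te]))
            cs.append(1)
    return CVReport(
        fold_accuracies=np.asarray(accs),
        selected_C=cs,
        kernel=f"poly deg={DEGREE} gamma={GAMMA} coef0={COEF0}",
        seed=seed,
        feature_set=f"{features.name}:{features.band}",
    )


def build_feature_sets(
    dataset: pd.DataFrame,
    bands: tuple[str, ...] = ("mu", "beta"),
    label_col: str = "group",
) -> list[FeatureSet]:
    """Expand a subject table into the classification feature menu.

    ``dataset`` holds one row per subject with a ``group`` column and
    per-band feature columns whose names start with ``<band>_power``,
    ``<band>_coherence``, ``<band>_connectivity`` (plus optional
    behavioral columns ``hit_rate`` and ``fa_rate``).  Emits per band
    each parameter family alone and the all-parameters set, plus the
    union over both bands when both are requested; sets whose columns
    are missing are skipped with a warning.
    """
    if dataset.empty:
        raise ValueError("dataset is empty")
    labels = dataset[label_col].to_numpy()
    families = ("power", "coherence", "connectivity")
    sets: list[FeatureSet] = []

    def _family_cols(band: str, fam: str) -> list[str]:
        return [c for c in dataset.columns if c.startswith(f"{band}_{fam}")]

    def _try(name: str, band: str, cols: list[str]) -> None:
        if not cols:
            logger.warning("feature set %s:%s skipped; no matching columns",
                           name, band)
            return
        sets.append(
            FeatureSet(
                name=name, band=band,
                matrix=dataset[cols].to_numpy(dtype=float),
                labels=labels, feature_names=cols,
            )
        )

    if {"hit_rate", "fa_rate"} <= set(dataset.columns):
        _try("behavior", "none", ["hit_rate", "fa_rate"])
    for band in bands:
        for fam in families:
            _try(fam, band, _family_cols(band, fam))
        _try(
            "all", band,
            [c for fam in families for c in _family_cols(band, fam)],
        )
    if len(bands) > 1:
        _try(
            "all", "+".join(bands),
            [c for b in bands for fam in families for c in _family_cols(b, fam)],
        )
    return sets


def repeat_cv(
    features: FeatureSet,
    n_repeats: int = 3,
    seeds: list[int] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Repeat the CV analysis with distinct seeds; one row per repeat.

    Reports each run's mean and SD of fold accuracies — the spread shown
    when accuracies are compared across testing samples.
    """
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    rows = []
    for s in seeds:
        rep = svm_classify(features, seed=s, **kwargs)
        rows.append(
            {
                "feature_set": rep.feature_set,
                "seed": s,
                "mean_accuracy": rep.mean_accuracy,
                "sd_accuracy": rep.sd_accuracy,
            }
        )
    return pd.DataFrame(rows)
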