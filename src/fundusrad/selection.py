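"""MM-related feature mining: z-score, MI and t-test filters, SFFS wrapper.

The cascade mirrors the study design: features are z-scored with training
statistics, screened by a mutual-information filter (plug-in estimator,
10 equal-frequency bins, bits, threshold 0.2) intersected with a pooled
two-sample t-test (p < 0.05), and the surviving candidates enter Sequential
Floating Forward Selection scored by the mean ROC AUC of a random-forest
classifier under stratified 5-fold cross-validation.  The final cardinality
is chosen by a rise-plateau rule on the CV score curve, and the decision
model is a 100-tree random forest on the chosen subset.

The filters and the wrapper are exposed both as scikit-learn selector
estimators (``MutualInfoFilter``, ``TTestFilter``, ``SFFSSelector``) and as
thin module-level functions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import sklearn
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y

from .imaging import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "SelectionTrace",
    "ZScoreScaler",
    "zscore_normalize",
    "MutualInfoFilter",
    "TTestFilter",
    "SFFSSelector",
    "mutual_information_filter",
    "ttest_filter",
    "filter_intersection",
    "sffs_select",
    "choose_final_set",
    "fit_decision_model",
]


# ---------------------------------------------------------------------------
# data containers


@dataclass
class FeatureTable:
    """Eyes x features matrix plus labels and train/validation tags."""

    values: pd.DataFrame
    categories: pd.Series
    labels: pd.DataFrame  # indexed like values; columns grade, plus_lesion, severe
    split_tag: pd.Series  # 'train' | 'validation' per eye

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("feature table contains missing values")
        if self.values.columns.duplicated().any():
            raise ValidationError("feature names must be unique")
        y = self.train_y
        if len(np.unique(y)) < 2:
            raise ValidationError("both classes must be present in the training split")

    @property
    def train_mask(self) -> np.ndarray:
        return (self.split_tag == "train").to_numpy()

    @property
    def train_X(self) -> pd.DataFrame:
        return self.values.loc[self.train_mask]

    @property
    def train_y(self) -> np.ndarray:
        return self.labels.loc[self.train_mask, "severe"].to_numpy().astype(int)

    @property
    def validation_X(self) -> pd.DataFrame:
        return self.values.loc[~self.train_mask]

    @property
    def validation_y(self) -> np.ndarray:
        return self.labels.loc[~self.train_mask, "severe"].to_numpy().astype(int)


@dataclass
class SelectionTrace:
    """Best subset, mean CV score and SD recorded at each cardinality."""

    subsets: dict[int, tuple[str, ...]] = field(default_factory=dict)
    means: dict[int, float] = field(default_factory=dict)
    sds: dict[int, float] = field(default_factory=dict)

    def record(self, k: int, subset: Sequence[str], mean: float, sd: float) -> None:
        if k not in self.means or mean > self.means[k]:
            self.subsets[k] = tuple(subset)
            self.means[k] = float(mean)
            self.sds[k] = float(sd)

    @property
    def max_k(self) -> int:
        return max(self.means) if self.means else 0

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.means)
        return pd.DataFrame(
            {
                "k": ks,
                "mean_score": [self.means[k] for k in ks],
                "sd_score": [self.sds[k] for k in ks],
                "members": ["|".join(self.subsets[k]) for k in ks],
            }
        )


# ---------------------------------------------------------------------------
# z-score normalization


@dataclass
class ZScoreScaler:
    """Train-fitted per-feature standardizer (population SD)."""

    mean: pd.Series
    sd: pd.Series
    zero_variance: tuple[str, ...]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        sd = self.sd.replace(0.0, 1.0)
        out = (X - self.mean) / sd
        # zero-variance features map to 0 everywhere
        for col in self.zero_variance:
            if col in out.columns:
                out[col] = 0.0
        return out


def zscore_normalize(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[list[pd.DataFrame], ZScoreScaler]:
    """Z-score features with training statistics; apply to all tables."""
    if len(train) == 0:
        raise ValidationError("empty training table")
    mean = train.mean()
    sd = train.std(ddof=0)
    zero = tuple(sd.index[sd == 0.0])
    if zero:
        logger.warning("%d zero-variance features mapped to 0: %s",
                       len(zero), list(zero)[:5])
    scaler = ZScoreScaler(mean, sd, zero)
    return [scaler.transform(t) for t in (train, *others)], scaler


# ---------------------------------------------------------------------------
# filters


def _plugin_mi_bits(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in mutual information (bits) between a feature and binary labels.

    The feature is discretized into ``n_bins`` equal-frequency bins
    (duplicate quantile edges merged); the plug-in estimate is computed from
    the joint histogram.
    """
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.digitize(x, edges)
    n = len(x)
    mi = 0.0
    for b in np.unique(bins):
        for c in (0, 1):
            pxy = np.mean((bins == b) & (y == c))
            if pxy == 0:
                continue
            px = np.mean(bins == b)
            py = np.mean(y == c)
            mi += pxy * np.log2(pxy / (px * py))
    return float(max(mi, 0.0))


class MutualInfoFilter(SelectorMixin, BaseEstimator):
    """Keep features whose plug-in MI with the binary label exceeds a threshold.

    Parameters
    ----------
    threshold : float, default 0.2
        Retention threshold in bits (MI strictly greater passes).
    n_bins : int, default 10
        Number of equal-frequency bins for the feature discretization.
    """

    def __init__(self, threshold: float = 0.2, n_bins: int = 10):
        self.threshold = threshold
        self.n_bins = n_bins

    def fit(self, X, y):
        X_arr, y_arr = check_X_y(X, y)
        if len(np.unique(y_arr)) < 2:
            raise ValidationError("MI filter needs both classes present")
        self.feature_names_in_ = (
            np.asarray(X.columns) if hasattr(X, "columns")
            else np.array([f"x{i}" for i in range(X_arr.shape[1])])
        )
        self.n_features_in_ = X_arr.shape[1]
        self.mi_scores_ = np.array(
            [_plugin_mi_bits(X_arr[:, j], y_arr, self.n_bins) for j in range(X_arr.shape[1])]
        )
        return self

    def _get_support_mask(self):
        return self.mi_scores_ > self.threshold


class TTestFilter(SelectorMixin, BaseEstimator):
    """Keep features whose pooled two-sample t-test has p < alpha.

    Zero-pooled-variance features are retained when the class means differ
    (p treated as 0) and dropped when they are equal (p treated as 1).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X_arr, y_arr = check_X_y(X, y)
        classes = np.unique(y_arr)
        if len(classes) < 2:
            raise ValidationError("t-test filter needs both classes present")
        g0 = X_arr[y_arr == classes[0]]
        g1 = X_arr[y_arr == classes[1]]
        if len(g0) < 2 or len(g1) < 2:
            raise ValidationError("each class needs at least 2 eyes")
        self.feature_names_in_ = (
            np.asarray(X.columns) if hasattr(X, "columns")
            else np.array([f"x{i}" for i in range(X_arr.shape[1])])
        )
        self.n_features_in_ = X_arr.shape[1]
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = stats.ttest_ind(g0, g1, equal_var=True)
        degenerate = ~np.isfinite(p)
        means_differ = np.abs(g0.mean(axis=0) - g1.mean(axis=0)) > 0
        p = np.where(degenerate, np.where(means_differ, 0.0, 1.0), p)
        self.pvalues_ = p
        self.statistics_ = np.where(np.isfinite(t), t, 0.0)
        return self

    def _get_support_mask(self):
        return self.pvalues_ < self.alpha


def mutual_information_filter(
    X: pd.DataFrame, y: Sequence[int], threshold: float = 0.2, n_bins: int = 10
) -> list[str]:
    """Names of the features passing the mutual-information filter."""
    f = MutualInfoFilter(threshold=threshold, n_bins=n_bins).fit(X, np.asarray(y))
    return [n for n, keep in zip(f.feature_names_in_, f._get_support_mask()) if keep]


def ttest_filter(
    X: pd.DataFrame, y: Sequence[int], alpha: float = 0.05
) -> list[str]:
    """Names of the features passing the pooled two-sample t-test filter."""
    f = TTestFilter(alpha=alpha).fit(X, np.asarray(y))
    return [n for n, keep in zip(f.feature_names_in_, f._get_support_mask()) if keep]


def filter_intersection(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Set intersection of two feature subsets, in first-argument order."""
    bset = set(b)
    out = [n for n in a if n in bset]
    if not out:
        logger.warning("filter intersection is empty")
    return out


# ---------------------------------------------------------------------------
# fast random-forest CV criterion


def _bagged_forest_proba(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    n_trees: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Class-1 probability from a bagged random forest (max_features sqrt)."""
    n = len(ytr)
    proba = np.zeros(len(Xte))
    uniform = np.full(n, 1.0 / n)
    for _ in range(n_trees):
        w = rng.multinomial(n, uniform).astype(np.float64)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(Xtr, ytr, sample_weight=w, check_input=False)
        proba += tree.predict_proba(Xte, check_input=False)[:, -1]
    return proba / n_trees


def _cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    cols: Sequence[int],
    folds: list[tuple[np.ndarray, np.ndarray]],
    n_trees: int,
    seed_seq: list[int],
) -> tuple[float, float]:
    """Mean and SD of ROC AUC over precomputed stratified folds."""
    aucs = []
    rng = np.random.default_rng(seed_seq)
    sub = np.ascontiguousarray(X[:, list(cols)])
    for tr, te in folds:
        proba = _bagged_forest_proba(sub[tr], y[tr], sub[te], n_trees, rng)
        aucs.append(roc_auc_score(y[te], proba))
    return float(np.mean(aucs)), float(np.std(aucs))


# ---------------------------------------------------------------------------
# SFFS


class SFFSSelector(SelectorMixin, BaseEstimator):
    """Sequential Floating Forward Selection scored by random-forest CV AUC.

    Classic SFFS: repeatedly add the candidate that maximizes the criterion,
    then conditionally remove any included feature (other than the one just
    added) whose removal strictly improves on the best score recorded at the
    smaller cardinality.  The criterion is the mean ROC AUC of a bagged
    random forest over stratified ``folds``-fold CV, with a single seed
    governing folds, bootstrap draws and tree randomness.  After the search,
    the final cardinality is picked by the rise-plateau rule
    (:func:`choose_final_set`).

    Parameters
    ----------
    max_k : int, default 30
        Largest subset cardinality explored (clamped to the candidate count).
    folds : int, default 5
        Stratified CV folds for the wrapper criterion.
    tol : float, default 0.005
        Plateau tolerance of the stopping rule.
    n_trees : int, default 100
        Trees in the criterion forest.
    seed : int, default 0
        Governs fold shuffling and all forest randomness.
    """

    def __init__(
        self,
        max_k: int = 30,
        folds: int = 5,
        tol: float = 0.005,
        n_trees: int = 100,
        seed: int = 0,
    ):
        self.max_k = max_k
        self.folds = folds
        self.tol = tol
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        X_arr, y_arr = check_X_y(X, y)
        names = (
            list(X.columns) if hasattr(X, "columns")
            else [f"x{i}" for i in range(X_arr.shape[1])]
        )
        self.feature_names_in_ = np.asarray(names)
        self.n_features_in_ = X_arr.shape[1]
        self.trace_ = _run_sffs(
            X_arr, y_arr, names, list(range(len(names))),
            self.max_k, self.folds, self.n_trees, self.seed,
        )
        chosen = choose_final_set(self.trace_, tol=self.tol)
        self.selected_features_ = list(chosen)
        self.chosen_k_ = len(chosen)
        return self

    def _get_support_mask(self):
        sel = set(self.selected_features_)
        return np.array([n in sel for n in self.feature_names_in_])


def _run_sffs(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    candidate_idx: list[int],
    max_k: int,
    folds: int,
    n_trees: int,
    seed: int,
) -> SelectionTrace:
    if len(candidate_idx) == 0:
        raise ValidationError("SFFS needs at least one candidate feature")
    if len(np.unique(y)) < 2:
        raise ValidationError("SFFS needs both classes present")
    if max_k > len(candidate_idx):
        logger.warning(
            "max_k=%d exceeds the %d candidates; clamping", max_k, len(candidate_idx)
        )
        max_k = len(candidate_idx)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_list = [(tr, te) for tr, te in skf.split(X[:, :1], y)]
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    cache: dict[frozenset, tuple[float, float]] = {}

    def J(subset: tuple[int, ...]) -> tuple[float, float]:
        key = frozenset(subset)
        if key not in cache:
            # deterministic per-subset randomness derived from the seed
            cache[key] = _cv_auc(
                X32, y, sorted(subset), fold_list, n_trees,
                [seed] + sorted(subset),
            )
        return cache[key]

    trace = SelectionTrace()
    included: list[int] = []
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        while len(included) < max_k:
            remaining = [c for c in candidate_idx if c not in included]
            if not remaining:
                break
            scores = [J(tuple(included + [c])) for c in remaining]
            best_i = int(np.argmax([s[0] for s in scores]))  # ties -> column order
            just_added = remaining[best_i]
            included.append(just_added)
            mean, sd = scores[best_i]
            trace.record(len(included), [names[i] for i in included], mean, sd)

            # conditional (floating) removal
            while len(included) > 2:
                removable = [i for i in included if i != just_added]
                rm_scores = [
                    J(tuple(x for x in included if x != r)) for r in removable
                ]
                ri = int(np.argmax([s[0] for s in rm_scores]))
                k_minus = len(included) - 1
                if rm_scores[ri][0] > trace.means.get(k_minus, -np.inf):
                    included.remove(removable[ri])
                    trace.record(
                        k_minus, [names[i] for i in included], *rm_scores[ri]
                    )
                    just_added = -1  # after one removal, any feature may leave
                else:
                    break
    for k, m in trace.means.items():
        if not np.isfinite(m):
            raise ValidationError("non-finite SFFS criterion")
    return trace


def sffs_select(
    X: pd.DataFrame,
    y: Sequence[int],
    candidates: Optional[Sequence[str]] = None,
    max_k: int = 30,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> SelectionTrace:
    """Run SFFS over ``candidates`` (default: all columns); return the trace."""
    y_arr = np.asarray(y).astype(int)
    names = list(X.columns)
    if candidates is None:
        candidates = names
    name_to_idx = {n: i for i, n in enumerate(names)}
    unknown = [c for c in candidates if c not in name_to_idx]
    if unknown:
        raise ValidationError(f"unknown candidate features {unknown[:5]}")
    cand_idx = [name_to_idx[c] for c in candidates]
    return _run_sffs(
        X.to_numpy(dtype=np.float64), y_arr, names, cand_idx,
        max_k, folds, n_trees, seed,
    )


def choose_final_set(trace: SelectionTrace, tol: float = 0.005) -> tuple[str, ...]:
    """Rise-plateau rule: smallest k that no larger k beats by more than tol."""
    ks = sorted(trace.means)
    if not ks:
        raise ValidationError("empty selection trace")
    for k in ks:
        later = [trace.means[k2] for k2 in ks if k2 > k]
        if not later or max(later) <= trace.means[k] + tol:
            return trace.subsets[k]
    return trace.subsets[ks[-1]]


# ---------------------------------------------------------------------------
# decision model


def fit_decision_model(
    X: pd.DataFrame,
    y: Sequence[int],
    features: Sequence[str],
    seed: int = 0,
    n_trees: int = 100,
) -> RandomForestClassifier:
    """Fit the final random-forest decision model on a feature subset.

    The returned classifier carries ``selected_features_`` so callers can
    score any table with the same columns via :func:`predict_scores`.
    """
    features = list(features)
    if not features:
        raise ValidationError("decision model needs a nonempty feature set")
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValidationError(f"unknown feature names {missing[:5]}")
    y_arr = np.asarray(y).astype(int)
    if len(np.unique(y_arr)) < 2:
        raise ValidationError("decision model needs both classes present")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X[features].to_numpy(), y_arr)
    clf.selected_features_ = features
    return clf


def predict_scores(clf: RandomForestClassifier, X: pd.DataFrame) -> np.ndarray:
    """Per-eye class-1 probability from a fitted decision model."""
    return clf.predict_proba(X[clf.selected_features_].to_numpy())[:, 1]
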