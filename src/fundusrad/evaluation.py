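"""Severity grouping, splits, ROC/AUC, correlation and subclass profiles.

Severity follows the META-PM-based grouping: eyes graded MDCA, C3 or C4, or
carrying plus lesions (lacquer cracks, myopic CNV, Fuchs' spot), form the
severe myopic-maculopathy group; C0, C1 and PDCA eyes form the
without-severe group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .imaging import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GRADES",
    "SEVERE_GRADES",
    "assign_severity_group",
    "severity_flags",
    "split_70_30",
    "roc_auc",
    "univariate_auc_cv",
    "pearson_correlation_matrix",
    "subclass_profile_analysis",
    "group_counts",
    "EvalReport",
]

GRADES = ("C0", "C1", "PDCA", "MDCA", "C3", "C4")
SEVERE_GRADES = frozenset({"MDCA", "C3", "C4"})


def assign_severity_group(grade: str, plus_lesion: bool | int = False) -> str:
    """Return ``'severe'`` or ``'without'`` for one eye.

    Severe = grade >= MDCA in META-PM order, or any plus lesion present.
    """
    if grade not in GRADES:
        raise ValidationError(f"unknown MM grade {grade!r}")
    return "severe" if (grade in SEVERE_GRADES or bool(plus_lesion)) else "without"


def severity_flags(labels: pd.DataFrame) -> pd.Series:
    """Vectorized 0/1 severe flag for a labels table."""
    plus = labels.get("plus_lesion", pd.Series(0, index=labels.index))
    return pd.Series(
        [
            int(assign_severity_group(g, p) == "severe")
            for g, p in zip(labels["grade"], plus.fillna(0))
        ],
        index=labels.index,
        name="severe",
    )


def split_70_30(
    labels: pd.DataFrame, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Severity-stratified 70/30 split; validation size is ``ceil(0.3 n)``.

    Returns (train index array, validation index array) into ``labels``.
    """
    n = len(labels)
    if n < 10:
        raise ValidationError("need at least 10 eyes to split")
    severe = severity_flags(labels).to_numpy()
    if len(np.unique(severe)) < 2:
        raise ValidationError("both severity classes must be present")
    for attempt in range(10):
        sss = StratifiedShuffleSplit(
            n_splits=1, test_size=0.3, random_state=seed + attempt
        )
        tr, va = next(sss.split(np.zeros((n, 1)), severe))
        if len(np.unique(severe[tr])) == 2 and len(np.unique(severe[va])) == 2:
            return labels.index.to_numpy()[tr], labels.index.to_numpy()[va]
    raise ValidationError("could not produce a split with both classes on each side")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoidal ROC AUC (equals the Mann-Whitney U statistic with ties ½)."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def univariate_auc_cv(
    feature: Sequence[float],
    labels: Sequence[int],
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of held-out AUC of a single-covariate logistic model.

    Stratified ``folds``-fold CV: the logistic regression is fit on each
    training fold and scored by ROC AUC on the held-out fold.
    """
    x = np.asarray(feature, dtype=float).reshape(-1, 1)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(x, y):
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValidationError("degenerate fold without both classes")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lr = LogisticRegression(max_iter=1000)
            lr.fit(x[tr], y[tr])
            s = lr.decision_function(x[te])
        aucs.append(roc_auc_score(y[te], s))
    return float(np.mean(aucs)), float(np.std(aucs))


def pearson_correlation_matrix(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r, two-sided p (t transform, n-2 df) and star labels.

    Stars: ``*`` p < 0.05, ``**`` p < 0.01, ``***`` p < 0.001.  A
    zero-variance column yields r = 0 (flagged by p = 1).
    """
    if len(a) < 3 or len(a) != len(b):
        raise ValidationError("need >= 3 eyes and aligned tables")
    r = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    p = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        xa = a[ca].to_numpy(dtype=float)
        for cb in b.columns:
            xb = b[cb].to_numpy(dtype=float)
            if xa.std() == 0 or xb.std() == 0:
                logger.warning("zero-variance column in correlation: %s/%s", ca, cb)
                r.loc[ca, cb], p.loc[ca, cb] = 0.0, 1.0
                continue
            rr, pp = stats.pearsonr(xa, xb)
            r.loc[ca, cb], p.loc[ca, cb] = float(rr), float(pp)

    def star(pv: float) -> str:
        if pv < 0.001:
            return "***"
        if pv < 0.01:
            return "**"
        if pv < 0.05:
            return "*"
        return ""

    stars = p.map(star)
    return r, p, stars


@dataclass
class ProfileReport:
    """Per-grade mean/SD profiles and adjacent-grade change flags."""

    profile_mean: pd.DataFrame  # features x grades
    profile_sd: pd.DataFrame
    transition_p: pd.DataFrame  # features x adjacent transitions
    marked: pd.DataFrame  # bool, p < threshold
    features: list[str]


def subclass_profile_analysis(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    auc_floor: float = 0.75,
    p_threshold: float = 0.01,
    folds: int = 5,
    seed: int = 0,
    feature_subset: Optional[Sequence[str]] = None,
) -> ProfileReport:
    """Mean±SD per META-PM subclass with adjacent-grade Welch tests.

    Features are first screened by univariate CV AUC (> ``auc_floor``)
    against the severity label, unless an explicit ``feature_subset`` is
    given; each retained feature is profiled per grade C0..C4 and adjacent
    grades are compared by Welch's t-test, flagging transitions with
    p < ``p_threshold`` as marked changes.
    """
    severe = severity_flags(labels).to_numpy()
    if feature_subset is None:
        kept = []
        for col in features.columns:
            try:
                mean_auc, _ = univariate_auc_cv(features[col], severe, folds, seed)
            except ValidationError:
                continue
            if mean_auc > auc_floor:
                kept.append(col)
    else:
        kept = [c for c in feature_subset if c in features.columns]
    grades = labels["grade"].to_numpy()
    present = [g for g in GRADES if (grades == g).sum() > 0]
    if len(present) < 2:
        logger.warning("fewer than two grades present; empty profile comparison")
    transitions = [f"{a}->{b}" for a, b in zip(GRADES[:-1], GRADES[1:])]
    pm = pd.DataFrame(index=kept, columns=list(GRADES), dtype=float)
    ps = pd.DataFrame(index=kept, columns=list(GRADES), dtype=float)
    tp = pd.DataFrame(np.nan, index=kept, columns=transitions, dtype=float)
    for col in kept:
        x = features[col].to_numpy(dtype=float)
        for g in GRADES:
            sel = grades == g
            pm.loc[col, g] = float(x[sel].mean()) if sel.any() else np.nan
            ps.loc[col, g] = float(x[sel].std()) if sel.any() else np.nan
        for a, b in zip(GRADES[:-1], GRADES[1:]):
            xa, xb = x[grades == a], x[grades == b]
            if len(xa) < 2 or len(xb) < 2:
                logger.warning("transition %s->%s skipped (empty subclass)", a, b)
                continue
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, pv = stats.ttest_ind(xa, xb, equal_var=False)
            tp.loc[col, f"{a}->{b}"] = float(pv) if np.isfinite(pv) else 1.0
    marked = tp < p_threshold
    return ProfileReport(pm, ps, tp, marked, kept)


def _round_half_up(x: float, decimals: int = 1) -> float:
    f = 10**decimals
    return float(np.floor(x * f + 0.5) / f)


def group_counts(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-grade eye counts with percentages, plus severity-group totals.

    Percentages are rounded half-up to one decimal, matching the cohort
    table style; a missing plus-lesion column counts as all false.
    """
    if len(labels) == 0:
        raise ValidationError("empty labels table")
    n = len(labels)
    severe = severity_flags(labels)
    rows = []
    for g in GRADES:
        cnt = int((labels["grade"] == g).sum())
        rows.append({"group": g, "count": cnt, "percent": _round_half_up(100.0 * cnt / n)})
    n_severe = int(severe.sum())
    rows.append({"group": "without_severe", "count": n - n_severe,
                 "percent": _round_half_up(100.0 * (n - n_severe) / n)})
    rows.append({"group": "severe", "count": n_severe,
                 "percent": _round_half_up(100.0 * n_severe / n)})
    rows.append({"group": "total", "count": n, "percent": 100.0})
    return pd.DataFrame(rows).set_index("group")


@dataclass
class EvalReport:
    """Evaluation battery outputs for one pipeline run."""

    set_aucs: dict[str, float]
    univariate: pd.DataFrame  # feature, set, mean_auc, sd_auc
    corr_r: pd.DataFrame
    corr_p: pd.DataFrame
    corr_stars: pd.DataFrame
    profiles: ProfileReport
    counts: pd.DataFrame
    selected_features: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "set_aucs": self.set_aucs,
            "selected_features": list(self.selected_features),
            "univariate": self.univariate.to_dict(orient="records"),
            "counts": self.counts.reset_index().to_dict(orient="records"),
            "marked_transitions": {
                feat: [t for t, m in row.items() if bool(m)]
                for feat, row in self.profiles.marked.iterrows()
            },
        }
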