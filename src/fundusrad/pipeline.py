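"""End-to-end orchestration: extract -> split -> filter -> SFFS -> evaluate."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import selection as sel
from .imaging import FundusImage, RoiSet, canonicalize_orientation
from .synthetic import Cohort, PhantomConfig, generate_cohort
from .texture import CLINIC_FEATURE_NAMES, extract_feature_vector

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "extract_cohort", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """All pipeline tunables; the defaults reproduce the study settings."""

    output_dir: Optional[str] = None
    mi_threshold: float = 0.2
    t_alpha: float = 0.05
    max_k: int = 30
    folds: int = 5
    n_gray_levels: int = 32
    sffs_trees: int = 100
    model_trees: int = 100
    stop_tol: float = 0.005
    auc_floor: float = 0.75
    seed: int = 0
    save_figures: bool = False


def extract_cohort(
    images: Sequence[FundusImage],
    roisets: Sequence[RoiSet],
    labels: pd.DataFrame,
    n_levels: int = 32,
) -> tuple[pd.DataFrame, pd.Series]:
    """Canonicalize every eye and extract the 322-column feature table."""
    rows = []
    cats = None
    for img, rois in zip(images, roisets):
        cimg, crois = canonicalize_orientation(img, rois)
        fv = extract_feature_vector(cimg, crois, n_levels)
        rows.append(fv.values)
        cats = fv.categories
    table = pd.DataFrame(rows)
    table.index = labels.index
    return table, cats


@dataclass
class PipelineResult:
    features: pd.DataFrame
    categories: pd.Series
    labels: pd.DataFrame
    train_idx: np.ndarray
    val_idx: np.ndarray
    mi_pass: list[str]
    t_pass: list[str]
    candidates: list[str]
    trace: sel.SelectionTrace
    selected: list[str]
    report: ev.EvalReport
    counts_line: str = ""


def run_pipeline(
    cohort: Cohort,
    cfg: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run the full mining-and-evaluation cascade on a cohort.

    Stages: canonicalize + extract the 322-feature table; severity-stratified
    70/30 split; train-fitted z-score; MI and t-test filters and their
    intersection; SFFS with random-forest CV; rise-plateau cardinality
    choice; final 100-tree decision model; evaluation battery (new / clinic /
    union set AUCs on validation, univariate CV AUCs, Pearson correlation of
    new vs clinic features, subclass profiles, group counts).
    """
    labels = cohort.labels.copy()
    labels["severe"] = ev.severity_flags(labels)
    features, cats = extract_cohort(
        cohort.images, cohort.roisets, labels, cfg.n_gray_levels
    )

    train_idx, val_idx = ev.split_70_30(labels, seed=cfg.seed)
    split_tag = pd.Series("validation", index=labels.index)
    split_tag.loc[train_idx] = "train"

    (train_z, val_z), scaler = sel.zscore_normalize(
        features.loc[train_idx], features.loc[val_idx]
    )
    y_train = labels.loc[train_idx, "severe"].to_numpy().astype(int)
    y_val = labels.loc[val_idx, "severe"].to_numpy().astype(int)

    mi_pass = sel.mutual_information_filter(train_z, y_train, cfg.mi_threshold)
    t_pass = sel.ttest_filter(train_z, y_train, cfg.t_alpha)
    candidates = sel.filter_intersection(mi_pass, t_pass)
    if not candidates:
        raise sel.ValidationError("no features survived the filter phase")

    trace = sel.sffs_select(
        train_z, y_train, candidates,
        max_k=cfg.max_k, folds=cfg.folds, seed=cfg.seed, n_trees=cfg.sffs_trees,
    )
    selected = list(sel.choose_final_set(trace, tol=cfg.stop_tol))

    counts_line = (
        f"features: {features.shape[1]}→{len(mi_pass)}→{len(t_pass)}"
        f"→{len(candidates)}→{len(selected)}"
    )
    logger.info(counts_line)

    # set-level AUCs on the validation split
    new_set = [f for f in selected if f not in CLINIC_FEATURE_NAMES]
    if not new_set:
        new_set = selected
    union_set = list(dict.fromkeys(selected + CLINIC_FEATURE_NAMES))
    set_aucs = {}
    for name, feats_set in (
        ("new", new_set), ("clinic", CLINIC_FEATURE_NAMES), ("union", union_set)
    ):
        clf = sel.fit_decision_model(
            train_z, y_train, feats_set, seed=cfg.seed, n_trees=cfg.model_trees
        )
        scores = sel.predict_scores(clf, val_z)
        set_aucs[name] = ev.roc_auc(scores, y_val)

    # univariate CV AUC of selected + clinic features on the whole cohort
    whole_z = scaler.transform(features)
    y_all = labels["severe"].to_numpy().astype(int)
    uni_rows = []
    for f in dict.fromkeys(new_set + CLINIC_FEATURE_NAMES):
        mean_auc, sd_auc = ev.univariate_auc_cv(
            whole_z[f], y_all, folds=cfg.folds, seed=cfg.seed
        )
        uni_rows.append(
            {
                "feature": f,
                "set": "clinic" if f in CLINIC_FEATURE_NAMES else "new",
                "mean_auc": mean_auc,
                "sd_auc": sd_auc,
            }
        )
    univariate = pd.DataFrame(uni_rows)

    corr_r, corr_p, corr_stars = ev.pearson_correlation_matrix(
        features[new_set], features[CLINIC_FEATURE_NAMES]
    )
    high_auc = univariate.loc[univariate.mean_auc > cfg.auc_floor, "feature"].tolist()
    profiles = ev.subclass_profile_analysis(
        features, labels, auc_floor=cfg.auc_floor,
        seed=cfg.seed, feature_subset=high_auc,
    )
    counts = ev.group_counts(labels)
    report = ev.EvalReport(
        set_aucs, univariate, corr_r, corr_p, corr_stars, profiles, counts,
        selected_features=selected,
    )

    result = PipelineResult(
        features, cats, labels, train_idx, val_idx,
        mi_pass, t_pass, candidates, trace, selected, report, counts_line,
    )
    if cfg.output_dir:
        _write_artifacts(result, cfg)
    return result


def _write_artifacts(res: PipelineResult, cfg: RunConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    feat = res.features.copy()
    feat.insert(0, "eye_id", res.labels["eye_id"].values)
    feat.to_csv(out / "features.csv", index=False)
    pd.DataFrame(
        {"feature": res.features.columns, "category": res.categories.values}
    ).to_csv(out / "feature_categories.csv", index=False)
    from .texture import feature_metadata

    with open(out / "feature_metadata.json", "w") as fh:
        json.dump(feature_metadata(), fh, indent=1)
    res.trace.to_frame().to_csv(out / "selection_trace.csv", index=False)
    (out / "selected_features.txt").write_text("\n".join(res.selected) + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump(
            {
                **res.report.to_json_dict(),
                "bookkeeping": {
                    "total": int(res.features.shape[1]),
                    "mi_pass": len(res.mi_pass),
                    "t_pass": len(res.t_pass),
                    "intersection": len(res.candidates),
                    "selected": len(res.selected),
                },
            },
            fh,
            indent=2,
        )
    res.report.univariate.to_csv(out / "univariate_auc.csv", index=False)
    res.report.corr_r.to_csv(out / "correlation_r.csv")
    res.report.counts.to_csv(out / "group_counts.csv")
    if cfg.save_figures:
        from . import plotting

        plotting.save_all_figures(res, out)
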