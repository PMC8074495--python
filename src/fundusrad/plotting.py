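"""Figure outputs: ROC curves, boxplots, correlation heatmap, profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import GRADES


def plot_sffs_trace(trace, ax=None):
    """Mean ± SD of the wrapper CV score against subset cardinality."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    df = trace.to_frame()
    ax.errorbar(df["k"], df["mean_score"], yerr=df["sd_score"], marker="o", lw=1)
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("mean CV score")
    return ax


def plot_roc_curves(result, ax=None):
    """Validation ROC curves of the new / clinic / union feature sets."""
    from sklearn.metrics import roc_curve

    from . import selection as sel
    from .texture import CLINIC_FEATURE_NAMES

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    labels = result.labels
    y_tr = labels.loc[result.train_idx, "severe"].astype(int)
    y_va = labels.loc[result.val_idx, "severe"].astype(int)
    (tr_z, va_z), _ = sel.zscore_normalize(
        result.features.loc[result.train_idx], result.features.loc[result.val_idx]
    )
    new_set = [f for f in result.selected if f not in CLINIC_FEATURE_NAMES] or result.selected
    union = list(dict.fromkeys(result.selected + CLINIC_FEATURE_NAMES))
    for name, feats in (("new", new_set), ("clinic", CLINIC_FEATURE_NAMES), ("union", union)):
        clf = sel.fit_decision_model(tr_z, y_tr, feats)
        s = sel.predict_scores(clf, va_z)
        fpr, tpr, _ = roc_curve(y_va, s)
        ax.plot(fpr, tpr, label=f"{name} (AUC={result.report.set_aucs[name]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    return ax


def plot_feature_boxplots(result, features=None, path=None):
    """Per-severity-group boxplots of the selected and clinic features."""
    feats = features or list(result.report.univariate["feature"])
    sev = result.labels["severe"].astype(bool).to_numpy()
    n = len(feats)
    ncol = min(4, n)
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    for ax, f in zip(axes.ravel(), feats):
        vals = result.features[f].to_numpy()
        ax.boxplot([vals[~sev], vals[sev]], tick_labels=["without", "severe"])
        ax.set_title(f, fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_correlation_heatmap(report, ax=None):
    """Pearson r of new vs clinic features with significance stars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    r = report.corr_r.astype(float)
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(r.shape[0]), r.index, fontsize=7)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            txt = f"{r.iloc[i, j]:.2f}{report.corr_stars.iloc[i, j]}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=6)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_subclass_profiles(report, path=None):
    """Mean ± SD of the high-AUC features across META-PM subclasses."""
    prof = report.profiles
    n = len(prof.features)
    if n == 0:
        return None
    fig, axes = plt.subplots(1, n, figsize=(2.8 * n, 2.8), squeeze=False)
    xs = np.arange(len(GRADES))
    for ax, f in zip(axes.ravel(), prof.features):
        m = prof.profile_mean.loc[f].to_numpy(dtype=float)
        s = prof.profile_sd.loc[f].to_numpy(dtype=float)
        ax.errorbar(xs, m, yerr=s, marker="o", lw=1)
        ax.set_xticks(xs, GRADES, rotation=45, fontsize=7)
        ax.set_title(f, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def save_all_figures(result, outdir) -> None:
    outdir = Path(outdir)
    ax = plot_sffs_trace(result.trace)
    ax.figure.savefig(outdir / "sffs_trace.png", dpi=120)
    plt.close(ax.figure)
    ax = plot_roc_curves(result)
    ax.figure.savefig(outdir / "roc_curves.png", dpi=120)
    plt.close(ax.figure)
    plot_feature_boxplots(result, path=outdir / "feature_boxplots.png")
    ax = plot_correlation_heatmap(result.report)
    ax.figure.savefig(outdir / "correlation_heatmap.png", dpi=120)
    plt.close(ax.figure)
    plot_subclass_profiles(result.report, path=outdir / "subclass_profiles.png")
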