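"""Figure exports: PLS-DA score plot, volcano, VIP bars, EML strip plot,
ROC curve, UpSet diagram and the enrichment bubble plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def score_plot(model, X, labels, path) -> None:
    scores = model._pls.transform(np.asarray(X, float))
    if scores.shape[1] < 2:  # 1-component model: spread the second axis
        rng = np.random.default_rng(0)
        scores = np.column_stack([scores[:, 0], rng.uniform(-1, 1, len(scores))])
        ylab = "jitter"
    else:
        ylab = "LV2"
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color in zip(model.classes_, ("tab:blue", "tab:red")):
        mask = np.asarray(labels) == cls
        ax.scatter(scores[mask, 0], scores[mask, 1], s=14, label=str(cls), color=color)
    ax.set_xlabel("LV1")
    ax.set_ylabel(ylab)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def volcano_plot(vol: pd.DataFrame, path, alpha: float = 0.05) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = np.where(vol["significant"], "tab:red", "0.6")
    ax.scatter(vol["log2_fc"], -np.log10(vol["p"]), s=10, c=colors)
    ax.axhline(-np.log10(alpha), ls="--", c="0.4", lw=0.8)
    for v in (-1, 1):
        ax.axvline(v, ls="--", c="0.4", lw=0.8)
    ax.set_xlabel("log2 fold change (CTRL / CRC)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vip_plot(vip: pd.Series, path, threshold: float = 2.0, top: int = 20) -> None:
    v = vip.sort_values(ascending=False).head(top)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.barh(range(len(v)), v.to_numpy()[::-1], color="tab:blue")
    ax.set_yticks(range(len(v)), v.index[::-1], fontsize=7)
    ax.axvline(threshold, ls="--", c="tab:red", lw=0.8)
    ax.set_xlabel("VIP")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def eml_strip_plot(scores: pd.Series, labels: pd.Series, cutoff: float, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    for i, (cls, color) in enumerate((("CTRL", "tab:blue"), ("CRC", "tab:red"))):
        vals = scores[np.asarray(labels) == cls]
        ax.scatter(
            np.full(len(vals), i) + rng.uniform(-0.12, 0.12, len(vals)),
            vals, s=14, color=color,
        )
    ax.axhline(cutoff, ls="--", c="red", lw=1.0)
    ax.set_xticks([0, 1], ["CTRL", "CRC"])
    ax.set_ylabel("EML score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_plot(roc_df: pd.DataFrame, auc: float, path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.plot(roc_df["fpr"], roc_df["tpr"], color="tab:red")
    ax.plot([0, 1], [0, 1], ls=":", c="0.5", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {auc:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def upset_plot(counts: pd.Series, path, top: int = 15) -> None:
    """Minimal UpSet rendering: bars for the largest membership patterns,
    dot matrix below."""
    c = counts[counts > 0].head(top)
    names = sorted({n for combo in c.index for n in combo})
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4, 0.45 * len(c)), 4.5),
        height_ratios=[2, 1], sharex=True,
    )
    xs = np.arange(len(c))
    ax_bar.bar(xs, c.to_numpy(), color="0.25")
    ax_bar.set_ylabel("intersection size")
    for x, combo in zip(xs, c.index):
        for yi, name in enumerate(names):
            inside = name in combo
            ax_dot.scatter(x, yi, s=30, color="0.15" if inside else "0.85")
    ax_dot.set_yticks(range(len(names)), names, fontsize=7)
    ax_dot.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def enrichment_bubble(enr: pd.DataFrame, path) -> None:
    """Bubble plot: x = impact, y = -log10 p, size = distance from the
    origin, colour = match ratio."""
    x = enr["impact"].to_numpy()
    y = -np.log10(np.maximum(enr["p_hyper"].to_numpy(), 1e-300))
    size = 40 + 160 * np.hypot(x, y / max(y.max(), 1e-9))
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(x, y, s=size, c=enr["match_ratio"], cmap="YlOrRd",
                    edgecolor="0.3", lw=0.5)
    fig.colorbar(sc, label="match ratio")
    ax.set_xlabel("pathway impact")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def export_all(outdir, fm, labels, vol, pls_model, eml_result, y_test, roc_df, auc) -> None:
    out = Path(outdir) / "figures"
    out.mkdir(exist_ok=True)
    train_rows = fm.rows("train")
    score_plot(pls_model, train_rows, labels.loc[train_rows.index], out / "plsda_scores.png")
    volcano_plot(vol, out / "volcano.png")
    vip = pd.Series(pls_model.vip_, index=fm.feature_ids)
    vip_plot(vip, out / "vip.png")
    eml_strip_plot(eml_result.scores, y_test, eml_result.cutoff, out / "eml_scores.png")
    roc_plot(roc_df, auc, out / "roc.png")
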