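"""Minimal figure helpers: EAA box/density plots, ROC and PR curves.

These are convenience outputs for the CLI; all statistics live in the
analysis modules."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def eaa_boxplot(eaa: pd.DataFrame, sheet: pd.DataFrame, path) -> None:
    tissues = [t for t in sheet["tissue"].unique()]
    n = len(eaa.columns)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 4), squeeze=False)
    for ax, clock in zip(axes[0], eaa.columns):
        data = [eaa.loc[sheet.index[sheet["tissue"] == t], clock].dropna() for t in tissues]
        ax.boxplot(data, tick_labels=tissues)
        ax.set_title(clock)
        ax.tick_params(axis="x", rotation=45)
    fig.suptitle("EAA by tissue type")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def eaa_density(eaa: pd.DataFrame, sheet: pd.DataFrame, path) -> None:
    n = len(eaa.columns)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3.2), squeeze=False)
    for ax, clock in zip(axes[0], eaa.columns):
        for t in sheet["tissue"].unique():
            vals = eaa.loc[sheet.index[sheet["tissue"] == t], clock].dropna()
            if len(vals) > 1:
                vals.plot.kde(ax=ax, label=t)
        ax.set_title(clock)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def roc_plot(roc: pd.DataFrame, auc: float, path, ci: Optional[tuple] = None) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    label = f"ROC-AUC = {auc:.3f}"
    if ci:
        label += f" [{ci[0]:.3f}, {ci[1]:.3f}]"
    ax.plot(roc["fpr"], roc["tpr"], label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pr_plot(pr: pd.DataFrame, pr_auc: float, prevalence: float, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(pr["recall"], pr["precision"], label=f"PR-AUC = {pr_auc:.3f}")
    ax.axhline(prevalence, color="k", ls="--", lw=0.8,
               label=f"no-skill precision = {prevalence:.2f}")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
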