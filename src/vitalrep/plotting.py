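"""Matplotlib figures: ROC curves, correlation heat map, CNN training curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_roc(report, path=None):
    """Overlayed ROC curves for every (representation, classifier) in a report."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for (rep, name), roc in report.roc_curves.items():
        ax.plot(roc["fpr"], roc["tpr"], label=f"{rep}/{name} (AUC={roc['auc']:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_correlation_heatmap(corr, path=None):
    """Feature-feature Pearson correlation heat map."""
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(corr.to_numpy(), cmap="viridis", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(f"correlation of {corr.shape[0]} features")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_training_curves(history, path=None):
    """CNN loss and accuracy per epoch, train vs validation."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(history["train_loss"], label="train")
    if history.get("val_loss"):
        ax1.plot(history["val_loss"], label="validation")
    ax1.set_xlabel("epoch"), ax1.set_ylabel("cross-entropy loss"), ax1.legend()
    ax2.plot(history["train_acc"], label="train")
    if history.get("val_acc"):
        ax2.plot(history["val_acc"], label="validation")
    ax2.set_xlabel("epoch"), ax2.set_ylabel("accuracy"), ax2.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
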