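"""Report writers: CSV/JSON metric tables and PNG plots."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import MetricReport, round2

__all__ = ["write_json", "write_csv", "plot_curves", "plot_confusion"]

_COLUMNS = ("accuracy", "precision", "recall", "specificity", "f1")


def write_json(report: MetricReport, path: Path) -> None:
    Path(path).write_text(json.dumps(report.as_dict(), indent=2) + "\n")


def write_csv(report: MetricReport, path: Path) -> None:
    """Per-class rows plus the macro-average row, percentages to 2 decimals."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", *_COLUMNS])
        for name, m in zip(report.class_names, report.per_class):
            d = m.as_dict()
            writer.writerow([name, *[f"{d[c]:.2f}" for c in _COLUMNS]])
        avg = report.macro.as_dict()
        writer.writerow(["average", *[f"{avg[c]:.2f}" for c in _COLUMNS]])


def plot_curves(report: MetricReport, out_dir: Path) -> list[Path]:
    """PR and ROC curve panels; returns the written file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if report.pr:
        fig, ax = plt.subplots(figsize=(5, 4))
        for name in report.class_names:
            curve = report.pr.get(name)
            if curve is None or curve.degenerate:
                continue
            ax.plot(curve.x, curve.y, label=f"{name} (BEP {curve.bep:.2f})", lw=1)
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title("PR curves")
        ax.legend(fontsize=6)
        path = out_dir / "pr_curves.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    if report.roc:
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, curve in report.roc.items():
            if curve.degenerate:
                continue
            style = "--" if name in ("macro", "micro") else "-"
            ax.plot(curve.x, curve.y, style, label=f"{name} (AUC {curve.auc:.3f})", lw=1)
        ax.plot([0, 1], [0, 1], ":", color="gray", lw=0.8)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.set_title("ROC curves")
        ax.legend(fontsize=6)
        path = out_dir / "roc_curves.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def plot_confusion(report: MetricReport, path: Path) -> Path:
    counts = report.cm.counts
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(counts, cmap="Blues")
    k = len(report.class_names)
    ax.set_xticks(range(k), report.class_names, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(k), report.class_names, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    thresh = counts.max() / 2 if counts.max() else 0.5
    for i in range(k):
        for j in range(k):
            ax.text(
                j,
                i,
                str(counts[i, j]),
                ha="center",
                va="center",
                fontsize=7,
                color="white" if counts[i, j] > thresh else "black",
            )
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
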