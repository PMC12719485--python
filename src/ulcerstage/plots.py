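"""Report figures: confusion heatmap, ROC curves, AUC bars, reliability diagrams."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import CalibrationReport, MetricsReport, RocResult  # noqa: E402
from .taxonomy import ClassTaxonomy, DEFAULT_TAXONOMY  # noqa: E402


def plot_confusion(report: MetricsReport, path, taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY):
    fig, ax = plt.subplots(figsize=(5.5, 4.8))
    im = ax.imshow(report.confusion_normalized, cmap="Blues", vmin=0, vmax=1)
    ax.set_xticks(range(6), taxonomy.labels)
    ax.set_yticks(range(6), taxonomy.labels)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    ax.set_title("Normalized confusion matrix")
    for i in range(6):
        for j in range(6):
            v = report.confusion_normalized[i, j]
            ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                    color="white" if v > 0.5 else "black", fontsize=8)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_roc_per_class(roc: RocResult, path):
    fig, axes = plt.subplots(2, 3, figsize=(11, 7))
    for ax, (lab, res) in zip(axes.ravel(), roc.per_class.items()):
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        if res.get("auc") is not None:
            ax.plot(res["fpr"], res["tpr"], lw=1.5)
            ax.set_title(f"{lab}: AUC={res['auc']:.4f}", fontsize=10)
        else:
            ax.set_title(f"{lab}: undefined", fontsize=10)
        ax.set_xlabel("FPR", fontsize=8)
        ax.set_ylabel("TPR", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_roc_combined(roc: RocResult, path):
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    for lab, res in roc.per_class.items():
        if res.get("auc") is not None:
            ax.plot(res["fpr"], res["tpr"], lw=1.2, label=f"{lab} ({res['auc']:.3f})")
    mf, mt = roc.micro_curve
    ax.plot(mf, mt, ":", lw=1.6, label=f"micro ({roc.micro_auc:.3f})")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"One-vs-rest ROC (macro AUC {roc.macro_auc:.4f})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_auc_bars(roc: RocResult, path):
    labs = [lab for lab, r in roc.per_class.items() if r.get("auc") is not None]
    vals = [roc.per_class[lab]["auc"] for lab in labs]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar([*labs, "macro"], [*vals, roc.macro_auc], color="steelblue")
    ax.axhline(0.95, color="red", ls="--", lw=0.8)
    ax.axhline(0.90, color="orange", ls="--", lw=0.8)
    ax.set_ylim(0.0, 1.05)
    ax.set_ylabel("AUC")
    ax.set_title("AUC by class")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_reliability(cal: CalibrationReport, path):
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    for lab, res in cal.per_class.items():
        pts = [(b["confidence"], b["accuracy"]) for b in res["bins"] if b["count"]]
        if pts:
            xs, ys = zip(*pts)
            ax.plot(xs, ys, "o-", lw=1.0, ms=3, label=f"{lab} (ECE {res['ece']:.3f})")
    ax.set_xlabel("Predicted probability")
    ax.set_ylabel("Observed frequency")
    ax.set_title(f"Reliability diagram (overall ECE {cal.overall_ece:.4f}, "
                 f"{cal.overall_grade})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_all_reports(report: MetricsReport, roc: RocResult, cal: CalibrationReport,
                      out_dir) -> list[str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plot_confusion(report, out / "confusion.png")
    plot_roc_per_class(roc, out / "roc_per_class.png")
    plot_roc_combined(roc, out / "roc_combined.png")
    plot_auc_bars(roc, out / "auc_bars.png")
    plot_reliability(cal, out / "reliability.png")
    return ["confusion.png", "roc_per_class.png", "roc_combined.png",
            "auc_bars.png", "reliability.png"]
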