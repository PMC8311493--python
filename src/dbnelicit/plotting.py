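"""Optional matplotlib rendering of evaluation artifacts."""

from __future__ import annotations

from pathlib import Path

from .evaluation import EvalReport


def plot_roc_curves(report: EvalReport, path: "str | Path", title: str = "ROC") -> Path:
    """Write the per-class one-vs-rest ROC family to a PNG.

    Requires matplotlib (the ``plot`` extra); everything else in the
    package works without it.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, curve in sorted(report.roc_curves.items()):
        fpr = [p[1] for p in curve.points]
        tpr = [p[2] for p in curve.points]
        ax.plot(fpr, tpr, label=f"{label} (AUC {curve.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    ax.legend(fontsize=8)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
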