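"""Figure files for the pipeline reports (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def attribution_bar(r2_by_tag: dict, path) -> None:
    tags = sorted(r2_by_tag, key=r2_by_tag.get, reverse=True)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(tags, [r2_by_tag[t] for t in tags], color="#4878a8")
    ax.set_ylabel("explained variance $R^2$")
    ax.set_xticklabels(tags, rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def drift_box(p_values, path, label="candidate") -> None:
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.boxplot([p_values], tick_labels=[label], whis=(5, 95))
    ax.set_ylabel("two-sample KS P value")
    ax.axhline(0.01, ls="--", color="crimson", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_panel(aucs: dict, path) -> None:
    fig, axes = plt.subplots(1, len(aucs), figsize=(3.2 * len(aucs), 3.2))
    for ax, (cls, r) in zip(np.atleast_1d(axes), aucs.items()):
        ax.plot(r.fpr, r.tpr, color="#4878a8")
        ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=0.8)
        ax.set_title(f"{cls}\nAUC {r.auc:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]",
                     fontsize=9)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def calibration_plot(cal, path) -> None:
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.plot([0, 1], [0, 1], ls=":", color="gray")
    ax.plot(cal.mean_pred, cal.frac_pos, "o-", color="#4878a8")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed frequency")
    ax.set_title(f"ECE = {cal.ece:.3f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def kappa_heatmap(matrix, path) -> None:
    fig, ax = plt.subplots(figsize=(3.8, 3.2))
    im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for i in range(len(matrix)):
        for j in range(len(matrix)):
            ax.text(j, i, f"{matrix.iat[i, j]:.2f}", ha="center", va="center",
                    color="white", fontsize=7)
    fig.colorbar(im, label="Cohen $\\kappa$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def saliency_overlay(image, saliency_map, tip_xy, path) -> None:
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.imshow(image, cmap="gray")
    ax.imshow(saliency_map, cmap="inferno", alpha=0.45)
    ax.plot(tip_xy[1], tip_xy[0], "c+", ms=12, mew=2)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_all(report: dict, cal, aucs: dict, out_dir) -> None:
    out = Path(out_dir)
    attribution_bar(report["stages"]["attribute"]["r2"], out / "fig_attribution.png")
    pvals = [b["p"] for b in report["stages"]["drift"]["per_batch"]]
    drift_box(pvals, out / "fig_drift.png")
    roc_panel(aucs, out / "fig_roc.png")
    calibration_plot(cal, out / "fig_calibration.png")
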