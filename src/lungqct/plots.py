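"""Plot helpers: lung histogram, ROC curves, Kaplan-Meier curves.

Vector (SVG/PDF) output; purely presentational — no number reported
anywhere in the pipeline depends on these.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_lung_histogram(volume, mask, path, *, bin_width_hu: float = 10.0) -> None:
    """Attenuation histogram of the masked voxels (display binning only)."""
    values = volume.voxels[mask.mask]
    bins = np.arange(-1024.0, -199.0, bin_width_hu)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(values, bins=bins, color="steelblue")
    ax.set_xlabel("attenuation (HU)")
    ax.set_ylabel("voxels")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(records, variable: str, path, *, event_col: str = "deceased") -> None:
    """Empirical ROC curve of one variable against the deceased flag."""
    import pandas as pd

    from .records import records_to_frame
    from .survival import roc_cutoff

    df = records_to_frame(records)
    cut = roc_cutoff(df, variable, event_col=event_col)
    sub = df[[variable, event_col]].apply(pd.to_numeric, errors="coerce").dropna()
    x = sub[variable].to_numpy(float)
    y = sub[event_col].to_numpy(int)
    dead, alive = x[y == 1], x[y == 0]
    pts = []
    for t in np.concatenate([[-np.inf], np.unique(x), [np.inf]]):
        if cut.direction == "le":
            sens = np.mean(dead <= t)
            fpr = np.mean(alive <= t)
        else:
            sens = np.mean(dead >= t)
            fpr = np.mean(alive >= t)
        pts.append((fpr, sens))
    pts = np.array(sorted(pts))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(pts[:, 0], pts[:, 1], drawstyle="steps-post", color="firebrick")
    ax.plot([0, 1], [0, 1], ls=":", color="gray")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{variable}: AUC {cut.auc:.3f}, cut-off {cut.threshold:g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_km(stratification, path) -> None:
    """Step plot of the two strata with the log-rank p annotated."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, color in ((stratification.predicted_death, "firebrick"),
                         (stratification.predicted_survival, "steelblue")):
        ax.step(curve.times, curve.survival, where="post", label=curve.label, color=color)
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.legend(loc="lower left", fontsize=8)
    ax.set_title(f"log-rank p = {stratification.logrank_p:.3g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
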