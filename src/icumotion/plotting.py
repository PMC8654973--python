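"""Figure emitters: ROC / PR / calibration curves, significance heatmaps,
monitor traces.  All functions draw on a provided or fresh Axes and can
save straight to PNG/SVG."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt


def _finish(fig, ax, title, out):
    ax.set_title(title)
    if out is not None:
        fig.savefig(out, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return ax


def plot_roc(probabilities, labels, out=None, ax=None, title="ROC"):
    """Empirical ROC curve with the no-discrimination diagonal."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    order = np.argsort(-p, kind="stable")
    tpr = np.concatenate([[0.0], np.cumsum(y[order]) / max(y.sum(), 1)])
    fpr = np.concatenate([[0.0], np.cumsum(1 - y[order]) / max((1 - y).sum(), 1)])
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, lw=1.5)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    return _finish(fig, ax, title, out)


def plot_pr(pr_result, out=None, ax=None, title="Precision-recall"):
    """Curve from :func:`icumotion.evaluation.pr_curve_average_precision`."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(4, 4))
    ax.plot(pr_result["recall"], pr_result["precision"], lw=1.5)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.02)
    return _finish(fig, ax, f"{title} (AP={pr_result['ap']:.2f})", out)


def plot_calibration(cal_result, out=None, ax=None, title="Calibration"):
    """Flexible calibration curve against the identity."""
    p = cal_result["curve_p"]
    order = np.argsort(p)
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(4, 4))
    ax.plot(p[order], cal_result["curve"][order], lw=1.5)
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed proportion")
    return _finish(fig, ax,
                   f"{title} (ICI={cal_result['ICI']:.2f}, "
                   f"Emax={cal_result['E_max']:.2f})", out)


def plot_significance(sig, out=None, ax=None, title="Feature significance"):
    """Heatmap of the 6 x 8 sensor-feature significance matrix."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(6, 4))
    m = sig.mean
    im = ax.imshow(m.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(m.shape[1]), m.columns)
    ax.set_yticks(range(m.shape[0]), m.index)
    fig.colorbar(im, ax=ax, label="mean significance")
    return _finish(fig, ax, title, out)


def plot_monitor(trace, out=None, ax=None, gcsm_boundary=4,
                 title="Sliding-window detection"):
    """Short/long probability traces with intervals and clinical markers."""
    f = trace.frame
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(8, 3))
    th = f.time_s / 3600.0
    for tag, color in (("short", "tab:red"), ("long", "tab:blue")):
        ax.plot(th, f[f"prob_{tag}"], color=color, lw=1.2, label=tag)
        ax.fill_between(th, f[f"lo_{tag}"], f[f"hi_{tag}"], color=color, alpha=0.2)
    ax.axhline(0.5, ls="--", color="grey", lw=0.8)
    for t, s in trace.gcsm_events:
        marker = "^" if s > gcsm_boundary else "v"
        ax.plot(t / 3600.0, 1.03, marker, color="black", clip_on=False)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("P(GCSm > 4)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="center left", fontsize=8)
    return _finish(fig, ax, title, out)
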