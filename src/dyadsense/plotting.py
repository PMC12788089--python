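"""Report figures mirroring the standard panel layout of this analysis:
a per-feature time trace with shaded significance plus a summary boxplot,
a per-axis PSD triptych (normalized difference / p-values / decisions),
and a gaze scatter with concentration ellipses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.patches import Ellipse  # noqa: E402

from .streams import IMU_AXES  # noqa: E402

COND_COLORS = {"in_person": "tab:blue", "virtual": "tab:red"}


def feature_panel(per_cond: dict, report, ax_trace=None, ax_box=None):
    """Trace +/- SD per condition with significant windows shaded, plus a
    boxplot of per-participant task means annotated with the summary p."""
    if ax_trace is None or ax_box is None:
        fig, (ax_trace, ax_box) = plt.subplots(
            1, 2, figsize=(9, 3), gridspec_kw={"width_ratios": [3, 1]}
        )
    else:
        fig = ax_trace.figure
    t = report.window_end_times
    for cond, wf in per_cond.items():
        m = np.nanmean(wf.values, axis=0)
        s = np.nanstd(wf.values, axis=0)
        ax_trace.plot(t, m, color=COND_COLORS[cond], label=cond.replace("_", "-"))
        ax_trace.fill_between(t, m - s, m + s, color=COND_COLORS[cond], alpha=0.2)
    sig = np.where(np.nan_to_num(report.significant))[0]
    ylim = ax_trace.get_ylim()
    for j in sig:
        ax_trace.axvspan(t[j] - 2.5, t[j] + 2.5, color="yellow", alpha=0.3, lw=0)
    ax_trace.set_ylim(ylim)
    ax_trace.set_xlabel("window end time (s)")
    ax_trace.set_ylabel(report.feature_name)
    ax_trace.legend(fontsize=8)

    means = [report.summary_means[c] for c in ("in_person", "virtual")]
    means = [m[~np.isnan(m)] for m in means]
    ax_box.boxplot(means, tick_labels=["in-person", "virtual"])
    ax_box.set_title(f"p = {report.summary_p:.3g}", fontsize=9)
    fig.suptitle(f"{report.feature_name} ({report.task})", fontsize=10)
    fig.tight_layout()
    return fig


def psd_triptych(spectra: dict, task: str):
    """Normalized difference, adjusted p, and BH decisions per IMU axis."""
    fig, axes = plt.subplots(3, 1, figsize=(8, 8), sharex=True)
    for ax_name in IMU_AXES:
        sc = spectra.get((task, ax_name))
        if sc is None:
            continue
        axes[0].plot(sc.frequencies, sc.normalized_difference, label=ax_name)
        axes[1].semilogy(sc.frequencies, sc.p_adjusted, label=ax_name)
        axes[2].plot(sc.frequencies, sc.rejected.astype(int), label=ax_name, alpha=0.7)
    axes[0].axhline(0, color="k", lw=0.5)
    axes[0].set_ylabel("normalized PSD difference")
    axes[1].axhline(0.05, color="k", lw=0.5, ls="--")
    axes[1].set_ylabel("BH-adjusted p")
    axes[2].set_ylabel("significant")
    axes[2].set_xlabel("frequency (Hz)")
    axes[0].legend(fontsize=7, ncol=3)
    fig.suptitle(f"head-movement PSD comparison ({task})", fontsize=10)
    fig.tight_layout()
    return fig


def gaze_scatter(gaze_points: dict, ellipses: dict, task: str):
    """Window-average gaze positions with the concentration ellipse per
    condition."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for cond in ("in_person", "virtual"):
        pts = gaze_points.get((task, cond))
        if pts is None:
            continue
        ax.scatter(pts[:, 0], pts[:, 1], s=4, alpha=0.3, color=COND_COLORS[cond],
                   label=cond.replace("_", "-"))
        e = ellipses[(task, cond)]
        ax.add_patch(
            Ellipse(
                e.center,
                2 * e.semi_axes[0],
                2 * e.semi_axes[1],
                angle=np.degrees(e.angle_rad),
                fill=False,
                color=COND_COLORS[cond],
                lw=1.5,
            )
        )
    ax.set_xlabel("horizontal gaze")
    ax.set_ylabel("vertical gaze")
    ax.legend(fontsize=8)
    ax.set_title(f"window-average gaze position ({task})", fontsize=10)
    fig.tight_layout()
    return fig


def render_report_figures(result, out: Path) -> list[str]:
    """Write all figures for a study result as SVG; returns filenames."""
    out = Path(out)
    written = []
    for (task, feat), rep in result.reports.items():
        fig = feature_panel(result.features[(task, feat)], rep)
        name = f"fig_{task}_{feat}.svg"
        fig.savefig(out / name)
        plt.close(fig)
        written.append(name)
    tasks_with_psd = {t for (t, _) in result.spectra}
    for task in sorted(tasks_with_psd):
        fig = psd_triptych(result.spectra, task)
        name = f"fig_{task}_head_psd.svg"
        fig.savefig(out / name)
        plt.close(fig)
        written.append(name)
    for task in sorted({t for (t, _) in result.ellipses}):
        fig = gaze_scatter(result.gaze_points, result.ellipses, task)
        name = f"fig_{task}_gaze_ellipse.svg"
        fig.savefig(out / name)
        plt.close(fig)
        written.append(name)
    return written
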