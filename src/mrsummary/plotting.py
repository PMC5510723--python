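"""Static diagnostic plot of outcome against exposure associations."""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .data import SummaryData, orient_to_exposure_increasing, validate_summary_data
from .estimators import mr_egger, mr_ivw
from .median import BootstrapConfig, mr_median

__all__ = ["PlotResult", "plot_static"]


@dataclass(frozen=True)
class PlotResult:
    """Metadata of a rendered scatter plot."""

    path: str
    n_points: int
    lines: dict  # line label -> (intercept, slope)


def plot_static(
    data: SummaryData,
    path,
    lines=("ivw",),
    orientate: bool = False,
    error_bars: bool = True,
    alpha: float = 0.05,
    annotate: bool = False,
    seed: int = 0,
) -> PlotResult:
    """Scatter ``by`` against ``bx`` with optional error bars and fit lines.

    Error bars span the per-variant ``1 - alpha`` confidence intervals of
    each association. ``lines`` selects causal-estimate lines to overlay:
    ``"ivw"`` and ``"median"`` pass through the origin, ``"egger"`` carries
    its pleiotropy intercept. With ``orientate=True`` all variants are first
    re-oriented to the exposure-increasing allele (as the MR-Egger method
    does internally), so every plotted ``bx`` is nonnegative. ``annotate``
    writes the variant label next to each point — the static stand-in for an
    interactive mouse-over.
    """
    validate_summary_data(data)
    plotted = orient_to_exposure_increasing(data) if orientate else data
    fitted: dict[str, tuple[float, float]] = {}
    for name in lines:
        if name == "ivw":
            fitted["IVW"] = (0.0, mr_ivw(data).estimate)
        elif name == "egger":
            est = mr_egger(data)
            fitted["MR-Egger"] = (est.intercept.estimate, est.estimate)
        elif name == "median":
            est = mr_median(data, "weighted",
                            bootstrap=BootstrapConfig(n_iterations=200, seed=seed))
            fitted["Weighted median"] = (0.0, est.estimate)
        else:
            raise ValueError(f"unknown line {name!r} (choose from ivw, egger, median)")

    fig, ax = plt.subplots(figsize=(6, 5))
    if error_bars:
        q = stats.norm.ppf(1 - alpha / 2)
        ax.errorbar(
            plotted.bx, plotted.by,
            xerr=q * plotted.bxse, yerr=q * plotted.byse,
            fmt="o", ms=4, color="#33557a", ecolor="#99aec7",
            elinewidth=0.8, capsize=0, zorder=3,
        )
    else:
        ax.plot(plotted.bx, plotted.by, "o", ms=4, color="#33557a", zorder=3)
    if annotate:
        for lab, px, py in zip(plotted.labels(), plotted.bx, plotted.by):
            ax.annotate(lab, (px, py), fontsize=7,
                        textcoords="offset points", xytext=(4, 3))
    if fitted:
        span = np.array([min(0.0, plotted.bx.min()) - 0.05 * np.ptp(plotted.bx),
                         plotted.bx.max() + 0.05 * np.ptp(plotted.bx)])
        for label, (a, b) in fitted.items():
            ax.plot(span, a + b * span, lw=1.5, label=label, zorder=2)
        ax.legend(frameon=False, fontsize=8)
    ax.axhline(0.0, color="0.8", lw=0.6, zorder=1)
    ax.axvline(0.0, color="0.8", lw=0.6, zorder=1)
    ax.set_xlabel("Genetic association with exposure (bx)")
    ax.set_ylabel("Genetic association with outcome (by)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return PlotResult(path=str(path), n_points=plotted.n_variants, lines=fitted)
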