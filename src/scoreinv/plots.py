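"""Instability plots: per-level statistic contributions with critical lines."""

from __future__ import annotations

import numpy as np

from .fluctuation import CumulativeProcess, OrdinalGrouping

__all__ = ["instability_plot", "UnsupportedPlotError"]


class UnsupportedPlotError(ValueError):
    """Instability plots exist only for the ordinal/categorical functionals."""


def level_contributions(process: CumulativeProcess, grouping: OrdinalGrouping,
                        functional: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-level contributions (x = level positions, y = statistic pieces).

    For WDMo/maxLMo these are the weighted tie-point values whose maximum is
    the statistic; for LMuo the weighted squared block increments whose sum
    is the statistic.
    """
    B = process.B
    n = grouping.n
    if functional in ("WDMo", "maxLMo"):
        i = grouping.i
        frac = i / n
        rows = B[i]
        if functional == "WDMo":
            y = np.abs(rows).max(axis=1) / np.sqrt(frac * (1 - frac))
        else:
            y = (rows ** 2).sum(axis=1) / (frac * (1 - frac))
        x = np.arange(1, grouping.m)
    elif functional == "LMuo":
        idx = np.concatenate(([0], grouping.i, [n]))
        dt = np.diff(idx) / n
        inc = np.diff(B[idx], axis=0)
        y = (inc ** 2).sum(axis=1) / dt
        x = np.arange(1, grouping.m + 1)
    else:
        raise UnsupportedPlotError(
            f"no instability plot for the continuous functional {functional!r}; "
            "supported: WDMo, maxLMo, LMuo")
    return x, y


def instability_plot(process: CumulativeProcess, grouping: OrdinalGrouping,
                     functional: str, critical_value: float | None = None,
                     path=None, ax=None, level_labels=None):
    """Plot per-level statistic contributions with a dashed critical-value line.

    Saves to ``path`` (format by extension: .svg or .png) when given;
    returns the matplotlib axes.
    """
    x, y = level_contributions(process, grouping, functional)
    if ax is None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ax.plot(x, y, marker="o", color="black")
    if critical_value is not None:
        ax.axhline(critical_value, linestyle="--", color="red")
    if level_labels is not None:
        ax.set_xticks(x)
        ax.set_xticklabels([str(level_labels[i - 1]) for i in x])
    ax.set_xlabel("level of the auxiliary variable")
    ax.set_ylabel(f"{functional} statistic contribution")
    ax.set_title(f"{functional} instability across levels")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        import matplotlib.pyplot as plt
        plt.close(fig)
    return ax
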