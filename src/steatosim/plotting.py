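"""Matplotlib views of virtual populations and sensitivity sweeps."""

from __future__ import annotations

import numpy as np


def plot_population(frame, threshold_pct: float = 5.0, ax=None):
    """Scatter of plasma TG vs liver fat %, NAFLD patients highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    nafld = frame["liver_fat_pct"] > threshold_pct
    ax.scatter(frame.loc[~nafld, "liver_fat_pct"], frame.loc[~nafld, "plasma_tg"],
               s=8, alpha=0.5, label="non-NAFLD")
    ax.scatter(frame.loc[nafld, "liver_fat_pct"], frame.loc[nafld, "plasma_tg"],
               s=8, alpha=0.5, color="crimson", label="NAFLD")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("liver fat (%)")
    ax.set_ylabel("plasma TG (mg/dL)")
    ax.legend()
    return ax


def plot_sweeps(results, ax=None):
    """Mean liver-fat response curves; activation folds drawn on the inverse
    axis (fold f at inhibition coordinate 1 − 1/f) so all four mechanisms
    share one x-axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for r in results:
        if r.mechanism == "vldl_synthesis":
            x = 1.0 - 1.0 / np.asarray(r.grid)
        else:
            x = np.asarray(r.grid)
        ax.plot(x, r.mean_pct_change, marker="o", ms=3, label=r.mechanism)
    ax.set_xlabel("inhibition fraction (activation mapped as 1 − 1/fold)")
    ax.set_ylabel("mean change in liver fat (%)")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.legend()
    return ax
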