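"""Minimal plotting of grid summary tables (requires matplotlib)."""

from __future__ import annotations

import pandas as pd


def plot_measure(summary: pd.DataFrame, measure: str, ax=None):
    """Line plot of one performance measure against total sample size.

    ``summary`` is the frame written by ``run_grid`` (one row per scenario x
    method). The scenario label encodes the design cell; the x-axis uses the
    leading ``n<total>`` token and one line is drawn per method.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = summary.copy()
    frame["n_total"] = (frame["scenario"].str.extract(r"^n(\d+)_")
                        .astype(int))
    for method, grp in frame.groupby("method"):
        grp = grp.sort_values("n_total")
        ax.plot(grp["n_total"], grp[measure], marker="o", label=method)
    ax.set_xscale("log")
    ax.set_xlabel("total participants")
    ax.set_ylabel(measure.replace("_", " "))
    ax.legend(fontsize="small")
    return ax
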