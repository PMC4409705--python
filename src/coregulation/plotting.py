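"""Optional plotting layer over the tidy result tables.

These helpers only draw what the result CSVs already contain — they never
recompute statistics. Matplotlib is imported lazily so headless analysis
runs carry no plotting cost.
"""

from __future__ import annotations

import pandas as pd


def plot_correlation_intervals(frame: pd.DataFrame, parameter: str, ax=None):
    """Forest plot of per-set Spearman CIs for one parameter.

    ``frame`` is the correlation-survey table (columns ``set``,
    ``parameter``, ``rho``, ``ci_low``, ``ci_high``, ``n``).
    """
    import matplotlib.pyplot as plt

    sub = frame[frame["parameter"] == parameter].dropna(subset=["rho"])
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.6 * max(len(sub), 2) + 1))
    y = range(len(sub))
    ax.hlines(y, sub["ci_low"], sub["ci_high"], color="tab:blue")
    ax.plot(sub["rho"], y, "o", color="tab:blue")
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_yticks(list(y))
    ax.set_yticklabels([f"{s} (n={n})" for s, n in zip(sub["set"], sub["n"])])
    ax.set_xlabel(f"Spearman correlation of {parameter} within pairs")
    ax.figure.tight_layout()
    return ax


def plot_fold_change_medians(frame: pd.DataFrame, ax=None):
    """Point-and-interval plot of fold-change medians per set."""
    import matplotlib.pyplot as plt

    sub = frame.dropna(subset=["median_fc"]) if "median_fc" in frame else frame
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.6 * max(len(sub), 2) + 1))
    y = range(len(sub))
    ax.hlines(y, sub["median_ci_low"], sub["median_ci_high"], color="tab:green")
    ax.plot(sub["median_fc"], y, "o", color="tab:green")
    ax.axvline(1.0, color="0.6", lw=0.8)
    ax.set_yticks(list(y))
    ax.set_yticklabels([f"{s} (n={n})" for s, n in zip(sub["set"], sub["n"])])
    ax.set_xlabel("median within-pair fold change")
    ax.figure.tight_layout()
    return ax
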