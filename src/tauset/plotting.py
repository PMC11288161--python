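"""Optional diagnostics plots (matplotlib is imported lazily)."""

from __future__ import annotations

__all__ = ["plot_sliding_window", "plot_calibration"]


def plot_sliding_window(profile, ax=None, set_id: str | None = None):
    """Boxplots of gene-list scores per sliding window down the set ranking.

    ``profile`` is the output of
    :func:`tauset.enrichment.sliding_window_profile`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.boxplot(profile, tick_labels=[f"W{k + 1}" for k in range(len(profile))])
    ax.set_xlabel("window (top of gene set → bottom)")
    ax.set_ylabel("gene-list score")
    if set_id:
        ax.set_title(set_id)
    return ax


def plot_calibration(table, ax=None):
    """Scatter of log10 permutation p versus log10 asymptotic p."""
    import numpy as np
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = table.dropna(subset=["p_permutation"])
    x = np.log10(sub["p_asymptotic"])
    y = np.log10(sub["p_permutation"])
    ax.scatter(x, y, s=8, alpha=0.5)
    lo = min(x.min(), y.min())
    ax.plot([lo, 0], [lo, 0], color="grey", lw=1)
    ax.set_xlabel("log10 p (asymptotic)")
    ax.set_ylabel("log10 p (permutation)")
    return ax
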