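"""Simple trend plots (percent of person-time in treatment per year)."""

from __future__ import annotations

import pandas as pd


def plot_proportions(proportions: pd.DataFrame, units: list[tuple[int, str]],
                     path, dimension: str = "overall", value: str = "all") -> None:
    """Line plot of annual treatment-time percentages for the given units.

    ``units`` is a list of (level, label) pairs; one line each.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for level, label in units:
        sub = proportions[(proportions["dimension"] == dimension)
                          & (proportions["value"] == value)
                          & (proportions["level"] == level)
                          & (proportions["label"] == label)].sort_values("year")
        ax.plot(sub["year"], 100.0 * sub["proportion"], marker="o", ms=3,
                label=f"L{level}: {label}")
    ax.set_xlabel("Year")
    ax.set_ylabel("% of person-time in treatment")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
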