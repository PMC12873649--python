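"""Minimal panel plots of operating characteristics across scenarios."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_operating_characteristics"]

_PANELS = [
    ("mtd_selection_pct", "MTD selection (%)"),
    ("mtd_allocation_pct", "MTD allocation (%)"),
    ("overdose_selection_pct", "Overdose selection (%)"),
    ("overdose_allocation_pct", "Overdose allocation (%)"),
    ("sample_size_reduction_pct", "Sample size reduction (%)"),
    ("mean_duration_weeks", "Trial duration (weeks)"),
]


def plot_operating_characteristics(tables: dict[str, pd.DataFrame], path=None):
    """One line per design across scenarios, one panel per metric.

    ``tables`` maps a design label to the DataFrame returned by
    ``run_operating_characteristics`` (scenario-indexed).
    """
    fig, axes = plt.subplots(3, 2, figsize=(10, 10))
    for ax, (col, title) in zip(axes.ravel(), _PANELS):
        for label, df in tables.items():
            if col in df.columns and df[col].notna().any():
                ax.plot(range(1, len(df) + 1), df[col], marker="o", label=label)
        ax.set_title(title)
        ax.set_xlabel("scenario")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig
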