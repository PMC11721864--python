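"""Box-plot export of per-organ DSC / HD95 distributions by imaging arm."""

from __future__ import annotations

import pandas as pd


def export_boxplots(metric_table: pd.DataFrame, out_path) -> None:
    """Write a two-panel box plot (DSC left, HD95 right) grouped by organ and
    imaging system, matching the study's presentation of metric spread."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = metric_table.dropna(subset=["dsc"])
    organs = sorted(df["organ"].unique())
    arms = ["high_performance", "conventional"]
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    for ax, (col, label) in zip(axes, [("dsc", "DSC"), ("hd95_mm", "HD95 (mm)")]):
        data, positions, colors = [], [], []
        for gi, organ in enumerate(organs):
            for ai, arm in enumerate(arms):
                vals = df[(df["organ"] == organ) & (df["imaging_system"] == arm)][col]
                data.append(vals.to_numpy())
                positions.append(gi * 3 + ai)
                colors.append("tab:blue" if ai == 0 else "tab:orange")
        bp = ax.boxplot(data, positions=positions, widths=0.8, patch_artist=True)
        for patch, c in zip(bp["boxes"], colors):
            patch.set_facecolor(c)
        ax.set_xticks([gi * 3 + 0.5 for gi in range(len(organs))])
        ax.set_xticklabels(organs, rotation=30, ha="right")
        ax.set_ylabel(label)
    fig.suptitle("blue = high-performance, orange = conventional")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
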