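#!/usr/bin/env python
"""Plot the motivation x accuracy cell means of every similarity measure.

Reads the bundle written by 02_run_pipeline.py and draws, per measure, the
group-mean similarity for each motivation cue, split by subsequent memory
(hits vs misses), with standard-error bars.  Saved to
results/figures/cell_means.png.
"""
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cells = pd.read_csv(ROOT / "results" / "bundle" / "similarity_cells.csv")
    measures = sorted(cells["measure"].unique())
    mots = ["remember", "control", "forget"]
    fig, axes = plt.subplots(1, len(measures), figsize=(4 * len(measures), 3.5),
                             sharey=True)
    for ax, m in zip(np.atleast_1d(axes), measures):
        sub = cells[cells["measure"] == m]
        for outcome, offset in (("hit", -0.15), ("miss", 0.15)):
            g = sub[sub.outcome == outcome].groupby("motivation")["mean_score"]
            means = g.mean().reindex(mots)
            sems = (g.std() / np.sqrt(g.count())).reindex(mots)
            ax.bar(np.arange(3) + offset, means, 0.3, yerr=sems,
                   label=outcome, capsize=3)
        ax.set_xticks(range(3), mots, rotation=20)
        ax.set_title(m)
        ax.set_ylabel("similarity")
    axes.flat[0].legend() if hasattr(axes, "flat") else axes.legend()
    fig.tight_layout()
    out = ROOT / "results" / "figures"
    out.mkdir(parents=True, exist_ok=True)
    fig.savefig(out / "cell_means.png", dpi=150)
    print(f"figure written to {out / 'cell_means.png'}")


if __name__ == "__main__":
    main()
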