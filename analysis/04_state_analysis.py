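#!/usr/bin/env python
"""Relate self-reported mental state to online BCI accuracy.

Three analyses on the task-period outcome records:
  1. low/high quantization per state with chi-squared tests;
  2. smoothed actual-vs-expected accuracy curves over normalized ratings
     with a permutation 90% band;
  3. bivariate nearest-500 grids over each state pair, masked at the band,
     with connected significant regions.
Writes tidy CSVs and heatmap figures; prints the headline numbers.
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from bcistate.pipeline import analyze_records
from bcistate.state_analysis import significant_regions
from bcistate.synthetic import STATES
from common import RESULTS, get_config


def main():
    cfg = get_config()
    out = RESULTS / "state_analysis"
    out.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(RESULTS / "online" / "period_records.csv")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ana = analyze_records(cfg, records)

    rows = []
    print("quantized accuracy (low / high) and chi-squared p:")
    for state in STATES:
        q = ana["quantized"][state]
        rows.append({"state": state, "accuracy_low": q.accuracy_low,
                     "accuracy_high": q.accuracy_high,
                     "chi2": q.chi2, "p_value": q.p_value})
        print(f"  {state:12s} {100 * q.accuracy_low:5.1f} / "
              f"{100 * q.accuracy_high:5.1f}   p = {q.p_value:.4f}")
    pd.DataFrame(rows).to_csv(out / "quantized_accuracy.csv", index=False)

    print("\nsmoothed curves (deviation extrema vs 90% band):")
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6), sharey=True)
    for ax, state in zip(axes, STATES):
        c = ana["curves"][state]
        c.to_frame().to_csv(out / f"curve_{state}.csv", index=False)
        dev = c.deviation
        ax.plot(c.ratings, dev, lw=1)
        ax.axhline(c.ci_halfwidth, ls=":", c="k")
        ax.axhline(-c.ci_halfwidth, ls=":", c="k")
        ax.set_title(state)
        ax.set_xlabel("normalized rating")
        print(f"  {state:12s} min {dev.min():+.3f}, max {dev.max():+.3f}, "
              f"band +/-{c.ci_halfwidth:.3f}")
    axes[0].set_ylabel("C_actual - C_expected")
    fig.tight_layout()
    fig.savefig(out / "curves.png", dpi=130)

    print(f"\ngrid band +/-{ana['grid_ci_halfwidth']:.3f}; "
          "largest significant regions:")
    for (sx, sy), sg in ana["grids"].items():
        sg.to_frame().to_csv(out / f"grid_{sx}_{sy}.csv", index=False)
        fig, ax = plt.subplots(figsize=(4.6, 4))
        lim = max(0.1, np.abs(sg.difference).max())
        im = ax.imshow(sg.difference, origin="lower", extent=(0, 1, 0, 1),
                       cmap="RdYlGn", vmin=-lim, vmax=lim)
        masked = np.where(sg.mask, sg.difference, np.nan)
        ax.contour(sg.grid, sg.grid, ~sg.mask, levels=[0.5], colors="k",
                   linewidths=0.7)
        ax.set_xlabel(sx)
        ax.set_ylabel(sy)
        fig.colorbar(im, ax=ax, label="C_actual - C_expected")
        fig.tight_layout()
        fig.savefig(out / f"grid_{sx}_{sy}.png", dpi=130)
        plt.close(fig)
        regions = significant_regions(sg)
        if regions:
            r = regions[0]
            print(f"  {sx} x {sy}: {int(sg.mask.sum())} significant cells; "
                  f"largest {'+' if r.sign > 0 else '-'} region "
                  f"{r.n_cells} cells, centroid ({r.centroid[0]:.2f}, "
                  f"{r.centroid[1]:.2f}), peak {r.peak_difference:+.3f}")
        else:
            print(f"  {sx} x {sy}: no significant cells")
    print(f"wrote tables and figures to {out}")


if __name__ == "__main__":
    main()
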