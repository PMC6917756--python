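#!/usr/bin/env python
"""Figures: normalized variance vs. time per condition, minima annotated.

One panel per condition: the binned trace (points with replicate SD where
available) over the unbinned 30-s trace, the stimulus at t = 0, and detected
minima marked.  PNGs go to results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from nanomotion.io import read_profile, read_trace

ROOT = Path(__file__).resolve().parent.parent
TRACES = ROOT / "results" / "traces"
OUT = ROOT / "results" / "figures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for path in sorted(TRACES.glob("*_aggregate_windows.tsv")):
        trace = read_trace(path)
        condition = trace.condition
        binned = read_trace(TRACES / f"{condition}_aggregate_binned.tsv")
        profile = read_profile(ROOT / "results" / f"{condition}_profile.json")

        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.plot(trace.times / 60, trace.values, lw=0.6, color="0.6",
                label="30-s windows")
        ax.errorbar(
            binned.times / 60, binned.values,
            yerr=None if binned.sd is None else binned.sd,
            fmt="o-", ms=4, lw=1.5, color="C0", label="4-min bins",
        )
        for m in profile.minima:
            ax.annotate(
                f"{m.depth_units:.2f} u",
                xy=(m.t_min / 60, 100 * (1 - m.depth_units)),
                xytext=(m.t_min / 60, 100 * (1 - m.depth_units) - 9),
                ha="center", fontsize=8,
                arrowprops=dict(arrowstyle="-", lw=0.5),
            )
        ax.axvline(0, color="k", ls="--", lw=0.8)
        ax.axhline(100, color="k", ls=":", lw=0.8)
        ax.set_xlabel("time after stimulus (min)")
        ax.set_ylabel("variance (% of baseline)")
        recov = "recovered" if profile.recovered else "not recovered"
        ax.set_title(f"{condition}: {len(profile.minima)} minima, {recov}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(OUT / f"{condition}_trace.png", dpi=150)
        plt.close(fig)
        print(f"{condition}: wrote {condition}_trace.png")


if __name__ == "__main__":
    main()
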