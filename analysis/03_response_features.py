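#!/usr/bin/env python
"""Response profiles: minima depths/times/durations and recovery per condition.

Reads the aggregated unbinned traces from step 02, smooths them (5-window
moving average) to locate troughs, measures depth and timing on the
unsmoothed trace, and assesses recovery on the binned trace.  Writes one
JSON profile per condition and the cross-condition comparison table
results/response_features.tsv.
"""

from pathlib import Path

from nanomotion import assess_recovery, detect_minima, smooth_trace, summarize_profile
from nanomotion.io import read_trace, write_profile

ROOT = Path(__file__).resolve().parent.parent
TRACES = ROOT / "results" / "traces"
OUT = ROOT / "results"


def main() -> None:
    profiles = []
    for path in sorted(TRACES.glob("*_aggregate_windows.tsv")):
        trace = read_trace(path)
        smoothed = smooth_trace(trace)
        profile = detect_minima(smoothed, unsmoothed=trace)
        profile = assess_recovery(trace, profile, bin_width=240.0)
        profiles.append(profile)
        write_profile(profile, OUT / f"{trace.condition}_profile.json")
        minima = "; ".join(
            f"{m.depth_units:.2f} units @ {m.t_min / 60:.1f} min "
            f"(lasting {m.duration / 60:.1f} min)"
            for m in profile.minima
        ) or "none"
        print(
            f"{trace.condition}: minima: {minima}; "
            f"{'recovered' if profile.recovered else 'NOT recovered'} "
            f"(end level {profile.end_level_pct:.1f}%)"
        )
    table = summarize_profile(profiles)
    table.to_csv(OUT / "response_features.tsv", sep="\t", index=False)
    print(f"\nwrote {len(table)}-condition comparison table to "
          f"{OUT / 'response_features.tsv'}")


if __name__ == "__main__":
    main()
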