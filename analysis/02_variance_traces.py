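#!/usr/bin/env python
"""Windowed detrended-variance traces, normalized and aggregated per condition.

For every record from step 01: split into 30-s sets, remove a linear fit per
set, take the residual variance, normalize to the pre-stimulus mean (=100%),
then aggregate the three replicates of each condition on the common window
grid and also average the points into 4-minute bins.  Traces are written
under results/traces/.
"""

from pathlib import Path

from nanomotion import aggregate_replicates, bin_post_stimulus
from nanomotion.io import read_record, write_trace
from nanomotion.workflow import analyze_record

ROOT = Path(__file__).resolve().parent.parent
RECORDS = ROOT / "scratch" / "records"
OUT = ROOT / "results" / "traces"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    by_condition: dict[str, list] = {}
    for path in sorted(RECORDS.glob("*.npy")):
        record = read_record(path)
        trace = analyze_record(record)
        by_condition.setdefault(record.condition, []).append(trace)
        write_trace(trace, OUT / f"{path.stem}_windows.tsv")
    for condition, traces in sorted(by_condition.items()):
        aggregate = aggregate_replicates(traces)
        binned = bin_post_stimulus(aggregate)
        write_trace(aggregate, OUT / f"{condition}_aggregate_windows.tsv")
        write_trace(binned, OUT / f"{condition}_aggregate_binned.tsv")
        post = aggregate.post_stimulus().values
        print(
            f"{condition}: {len(traces)} replicates, baseline "
            f"{aggregate.baseline_mean:.4f} a.u.^2, post-stimulus range "
            f"{post.min():.1f}-{post.max():.1f}% of baseline"
        )
    print(f"\nwrote traces for {len(by_condition)} conditions to {OUT}")


if __name__ == "__main__":
    main()
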