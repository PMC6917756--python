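#!/usr/bin/env python
"""Simulate replicate deflection records for every scenario preset.

Each condition (flat control; endogenous-frataxin control + iron; mild and
strong frataxin overexpression, with and without iron sensitisation) is
simulated as three replicate 65-minute records at 2 kHz: 20 minutes of
pre-stimulus baseline followed by 45 minutes of post-stimulus response, with
the default colored-noise model (AR(1) core, sigma0 = 1 a.u., phi = 0.95,
drift 1e-4 a.u./s).  Records land under scratch/records/ as .npy + JSON
sidecar pairs.
"""

from pathlib import Path

from nanomotion import list_presets, simulate_deflection
from nanomotion.io import write_record

SEEDS = (1, 2, 3)
OUT = Path(__file__).resolve().parent.parent / "scratch" / "records"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for preset in list_presets():
        for seed in SEEDS:
            record = simulate_deflection(
                preset,
                baseline_duration=1200.0,
                post_duration=2700.0,
                sampling_rate=2000.0,
                seed=seed,
            )
            path = write_record(record, OUT / f"{preset.id}_seed{seed}.npy")
            print(
                f"{preset.id} seed {seed}: {record.samples.size:,} samples "
                f"({record.duration / 60:.0f} min) -> {path.name}"
            )
    print(f"\nwrote {len(list_presets()) * len(SEEDS)} records to {OUT}")


if __name__ == "__main__":
    main()
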