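"""End-to-end drivers: simulate -> variance pipeline -> response features.

These are the compositions every entry point (CLI, analysis scripts, tests)
uses, so a scenario is always analyzed the same way: per-record windowed
detrended variance and baseline normalization, replicate aggregation on the
common 30-s grid, smoothing for trough localization, minima detection with
depth/timing read off the unsmoothed aggregate, and recovery assessed on the
binned aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .signal_model import (
    DeflectionRecord,
    NoiseModel,
    get_preset,
    simulate_deflection,
)
from .pipeline import (
    NormalizedTrace,
    aggregate_replicates,
    bin_post_stimulus,
    compute_variance_trace,
    normalize_to_baseline,
)
from .features import (
    ResponseProfile,
    assess_recovery,
    detect_minima,
    smooth_trace,
)

__all__ = ["ScenarioResult", "analyze_record", "profile_from_traces", "run_scenario"]


@dataclass(frozen=True)
class ScenarioResult:
    """Everything a scenario run produces."""

    profile: ResponseProfile
    aggregate: NormalizedTrace  # unbinned mean trace across replicates
    aggregate_binned: NormalizedTrace
    replicates: tuple[NormalizedTrace, ...]  # unbinned per-record traces


def analyze_record(
    record: DeflectionRecord,
    window_length: float = 30.0,
) -> NormalizedTrace:
    """Unbinned normalized variance trace of one record."""
    return normalize_to_baseline(compute_variance_trace(record, window_length))


def profile_from_traces(
    traces: list[NormalizedTrace],
    bin_width: float = 240.0,
    smooth_width: int = 5,
    min_depth: float = 0.1,
    min_separation: float = 240.0,
    recovery_tolerance: float = 0.1,
) -> ScenarioResult:
    """Aggregate unbinned replicate traces and extract the response profile."""
    aggregate = aggregate_replicates(traces)
    binned = bin_post_stimulus(aggregate, bin_width)
    smoothed = smooth_trace(aggregate, smooth_width)
    profile = detect_minima(
        smoothed,
        unsmoothed=aggregate,
        min_depth=min_depth,
        min_separation=min_separation,
    )
    profile = assess_recovery(binned, profile, tolerance=recovery_tolerance)
    return ScenarioResult(
        profile=profile,
        aggregate=aggregate,
        aggregate_binned=binned,
        replicates=tuple(traces),
    )


def run_scenario(
    preset_id: str,
    seeds: tuple[int, ...] = (1, 2, 3),
    noise: NoiseModel = NoiseModel(),
    baseline_duration: float = 1200.0,
    post_duration: float = 2700.0,
    sampling_rate: float = 2000.0,
    window_length: float = 30.0,
    bin_width: float = 240.0,
    smooth_width: int = 5,
    min_depth: float = 0.1,
    min_separation: float = 240.0,
    recovery_tolerance: float = 0.1,
) -> ScenarioResult:
    """Simulate `seeds` replicates of a preset and run the full analysis."""
    preset = get_preset(preset_id)
    traces = [
        analyze_record(
            simulate_deflection(
                preset,
                noise=noise,
                baseline_duration=baseline_duration,
                post_duration=post_duration,
                sampling_rate=sampling_rate,
                seed=int(seed),
            ),
            window_length=window_length,
        )
        for seed in seeds
    ]
    return profile_from_traces(
        traces,
        bin_width=bin_width,
        smooth_width=smooth_width,
        min_depth=min_depth,
        min_separation=min_separation,
        recovery_tolerance=recovery_tolerance,
    )
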