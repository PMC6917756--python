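"""Shared fixtures: a session-wide cache of simulated, analyzed records.

The Monte-Carlo checks (parameter recovery, minima counts, flat-control
behaviour) all consume the same full-length scenario simulations, so each
(preset, seed) record is simulated and pushed through the variance pipeline
exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanomotion import simulate_deflection, get_preset
from nanomotion.workflow import analyze_record

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Full study conditions: 20 min pre-stimulus baseline, 45 min post-stimulus,
# desk-scale 2 kHz sampling, default noise model.
FULL_RUN = dict(baseline_duration=1200.0, post_duration=2700.0, sampling_rate=2000.0)


@pytest.fixture(scope="session")
def trace_cache():
    """Callable (preset_id, seed) -> unbinned NormalizedTrace, memoized."""
    cache: dict[tuple[str, int], object] = {}

    def get(preset_id: str, seed: int):
        key = (preset_id, seed)
        if key not in cache:
            record = simulate_deflection(get_preset(preset_id), seed=seed, **FULL_RUN)
            cache[key] = analyze_record(record)
        return cache[key]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20191217)
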