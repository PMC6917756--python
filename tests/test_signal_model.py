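"""Generator correctness: envelope math, AR(1) statistics, preset catalogue."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from nanomotion import (
    EnvelopeDip,
    NoiseModel,
    ScenarioPreset,
    envelope_value,
    get_preset,
    list_presets,
    simulate_deflection,
)
from nanomotion.pipeline import compute_variance_trace

SINGLE_06 = ScenarioPreset(id="d06", dips=(EnvelopeDip(0.6, 300.0),))
SINGLE_05 = ScenarioPreset(
    id="d05", dips=(EnvelopeDip(0.5, 300.0, width_rise=60.0, width_decay=120.0),)
)


class TestEnvelope:
    @pytest.mark.parametrize(
        "preset,t,expected",
        [
            (SINGLE_06, -60.0, 1.0),  # pre-stimulus baseline
            (SINGLE_06, 0.0, 1.0),  # stimulus instant still baseline
            (SINGLE_06, 300.0, 0.4),  # 1 - depth at the dip centre
            (SINGLE_05, 420.0, 1.0 - 0.5 * np.exp(-0.5)),  # one decay-sigma out
        ],
    )
    def test_pointwise_values(self, preset, t, expected):
        assert envelope_value(preset, t) == pytest.approx(expected, abs=1e-12)

    def test_floor_prevents_zero_variance(self):
        deep = ScenarioPreset(id="deep", dips=(EnvelopeDip(0.995, 300.0),))
        assert envelope_value(deep, 300.0) == pytest.approx(0.01)

    def test_vectorized_matches_scalar(self):
        t = np.linspace(-100, 2000, 211)
        vec = envelope_value(SINGLE_05, t)
        assert vec.shape == t.shape
        for i in [0, 50, 120, 210]:
            assert vec[i] == pytest.approx(envelope_value(SINGLE_05, float(t[i])))

    def test_asymmetric_widths(self):
        # 60 s before the centre (one rise sigma) vs 120 s after (one decay sigma)
        before = envelope_value(SINGLE_05, 240.0)
        after = envelope_value(SINGLE_05, 420.0)
        assert before == pytest.approx(after, abs=1e-12)
        # but at equal absolute offsets the decay side is deeper
        assert envelope_value(SINGLE_05, 360.0) < envelope_value(SINGLE_05, 240.0)


class TestSimulation:
    def test_determinism_bit_for_bit(self):
        a = simulate_deflection(SINGLE_06, seed=7, baseline_duration=60, post_duration=60)
        b = simulate_deflection(SINGLE_06, seed=7, baseline_duration=60, post_duration=60)
        assert np.array_equal(a.samples, b.samples)
        c = simulate_deflection(SINGLE_06, seed=8, baseline_duration=60, post_duration=60)
        assert not np.array_equal(a.samples, c.samples)

    def test_stationary_marginal_variance(self):
        noise = NoiseModel(sigma0=1.5, sigma_meas=0.0, drift_slope=0.0)
        flat = get_preset("P0")
        rec = simulate_deflection(
            flat, noise=noise, baseline_duration=500, post_duration=500,
            sampling_rate=2000.0, seed=3,
        )
        assert rec.samples.size == 2_000_000
        assert np.var(rec.samples) == pytest.approx(1.5**2, rel=0.01)

    def test_rate_rescaling_preserves_variance(self):
        # phi is defined at 2 kHz; at 20 kHz the per-sample autocorrelation is
        # larger but the marginal variance must not change
        noise = NoiseModel(drift_slope=0.0)
        assert noise.phi_at(2000.0) == pytest.approx(0.95)
        assert noise.phi_at(20000.0) == pytest.approx(0.95**0.1)
        rec = simulate_deflection(
            get_preset("P0"), noise=noise, baseline_duration=50, post_duration=50,
            sampling_rate=20000.0, seed=11,
        )
        assert np.var(rec.samples) == pytest.approx(1.0, rel=0.05)

    def test_stationarity_no_trend_in_window_variances(self):
        # no dips + no drift: the variance trace should show no time trend
        noise = NoiseModel(drift_slope=0.0)
        flat = get_preset("P0")
        nonsig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rec = simulate_deflection(
                flat, noise=noise, baseline_duration=150, post_duration=150,
                sampling_rate=2000.0, seed=seed,
            )
            trace = compute_variance_trace(rec)
            t = np.array([w.t_center_rel for w in trace.windows])
            v = np.array([w.variance for w in trace.windows])
            if stats.linregress(t, v).pvalue >= 0.01:
                nonsig += 1
        assert nonsig >= 0.95 * n_seeds

    def test_window_variance_tracks_envelope(self):
        # expected window variance = sigma0^2 * mean(m) + sigma_meas^2
        noise = NoiseModel(sigma0=1.0, sigma_meas=0.5, drift_slope=0.0)
        preset = ScenarioPreset(
            id="mid", dips=(EnvelopeDip(0.5, 240.0, width_rise=60.0, width_decay=120.0),)
        )
        traces = []
        for seed in range(12):
            rec = simulate_deflection(
                preset, noise=noise, baseline_duration=120, post_duration=600,
                sampling_rate=2000.0, seed=100 + seed,
            )
            tr = compute_variance_trace(rec)
            traces.append([w.variance for w in tr.windows])
            t_rel = np.array([w.t_center_rel for w in tr.windows])
        mean_var = np.mean(traces, axis=0)
        fine = np.linspace(-15, 15, 301)
        expected = np.array(
            [np.mean(envelope_value(preset, tc + fine)) + 0.25 for tc in t_rel]
        )
        assert mean_var == pytest.approx(expected, rel=0.06)

    def test_normalized_trace_distribution_is_rate_invariant(self):
        # the AR(1) correlation time is fixed in seconds, so per-window
        # normalized variances at 2 kHz and 8 kHz share one distribution
        from nanomotion.pipeline import normalize_to_baseline

        preset = ScenarioPreset(id="rate", dips=(EnvelopeDip(0.5, 240.0),))
        pooled = {}
        for rate in (2000.0, 8000.0):
            values = []
            for seed in range(8):
                rec = simulate_deflection(
                    preset, baseline_duration=180, post_duration=720,
                    sampling_rate=rate, seed=300 + seed,
                )
                values.append(normalize_to_baseline(compute_variance_trace(rec)).values)
            pooled[rate] = np.concatenate(values)
        assert stats.ks_2samp(pooled[2000.0], pooled[8000.0]).pvalue > 0.01

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(baseline_duration=0),
            dict(post_duration=-5),
            dict(sampling_rate=0),
            dict(seed=None),
        ],
    )
    def test_rejects_invalid_arguments(self, kwargs):
        full = dict(baseline_duration=60, post_duration=60, sampling_rate=100, seed=1)
        full.update(kwargs)
        with pytest.raises(ValueError):
            simulate_deflection(SINGLE_06, **full)


class TestPresetCatalogue:
    def test_expected_conditions(self):
        presets = {p.id: p for p in list_presets()}
        assert set(presets) == {"P0", "P1", "P2", "P3", "P4", "P5"}
        expected = {
            "P0": [],
            "P1": [(0.4, 600.0)],
            "P2": [(0.6, 300.0), (0.35, 1620.0)],
            "P3": [(0.7, 180.0), (0.2, 840.0), (0.50, 2160.0)],
            "P4": [(0.3, 420.0), (0.25, 1800.0)],
            "P5": [(0.2, 480.0), (0.5, 2100.0)],
        }
        for pid, dips in expected.items():
            got = [(d.depth, d.center) for d in presets[pid].dips]
            assert got == dips, pid

    def test_dips_sorted_and_separable(self):
        for p in list_presets():
            centers = [d.center for d in p.dips]
            assert centers == sorted(centers)
            for i, a in enumerate(p.dips):
                for j, b in enumerate(p.dips):
                    if i != j:
                        assert float(a.value_at(np.array(b.center))) < 0.01

    def test_presets_immutable(self):
        p = get_preset("P2")
        with pytest.raises(dataclasses.FrozenInstanceError):
            p.id = "hacked"
        with pytest.raises(dataclasses.FrozenInstanceError):
            p.dips[0].depth = 0.9

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            get_preset("P99")

    def test_overlapping_dips_rejected(self):
        with pytest.raises(ValueError, match="too close"):
            ScenarioPreset(
                id="bad", dips=(EnvelopeDip(0.5, 300.0), EnvelopeDip(0.5, 360.0))
            )


class TestNoiseModelValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(sigma0=0.0), dict(sigma0=-1.0), dict(phi=1.0), dict(phi=-0.1),
         dict(sigma_meas=-0.5)],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            NoiseModel(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(depth=0.0), dict(depth=1.0), dict(center=-10.0), dict(width_rise=0.0)],
    )
    def test_invalid_dips(self, kwargs):
        full = dict(depth=0.5, center=300.0)
        full.update(kwargs)
        with pytest.raises(ValueError):
            EnvelopeDip(**full)
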