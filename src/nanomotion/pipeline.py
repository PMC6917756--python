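"""Windowed detrended-variance pipeline for deflection records.

The analysis splits the record into 30-second sets, removes a simple linear
fit from each set, computes the residual variance per set, normalizes every
window to the mean pre-stimulus variance (tagged 100%), and finally averages
the post-stimulus points into 3-5-minute bins.  Replicate traces on a common
grid are aggregated pointwise (mean, SD, n).

Conventions
-----------
* The window grid restarts at the stimulus so no window mixes pre- and
  post-stimulus signal; partial windows (trailing, or truncated at the
  stimulus) are discarded.
* Residual variance uses n - 2 degrees of freedom (two fitted parameters).
* Normalized values are percent of baseline; "units" of drop used in feature
  reporting equal (100 - value)/100.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_model import DeflectionRecord

__all__ = [
    "WindowStat",
    "VarianceTrace",
    "NormalizedTrace",
    "segment_windows",
    "detrend_linear",
    "residual_variance",
    "compute_variance_trace",
    "normalize_to_baseline",
    "bin_post_stimulus",
    "aggregate_replicates",
]

DEFAULT_WINDOW_LENGTH = 30.0  # s
DEFAULT_BIN_WIDTH = 240.0  # s; valid range 180-300 s
MIN_BIN_WIDTH = 180.0
MAX_BIN_WIDTH = 300.0
MIN_BASELINE_WINDOWS = 5


@dataclass(frozen=True)
class WindowStat:
    """Linear fit and residual variance of one analysis window."""

    t_start: float  # s from record start
    t_end: float
    t_center_rel: float  # window centre, s relative to stimulus
    fit_slope: float  # a.u./s
    fit_intercept: float  # a.u. at t = 0 (record start)
    variance: float  # residual variance, a.u.^2
    n_samples: int


@dataclass(frozen=True)
class VarianceTrace:
    """Per-window residual variances of one record."""

    windows: tuple[WindowStat, ...]
    sampling_rate: float
    stimulus_time: float | None
    condition: str = ""
    replicate_id: str = ""
    window_length: float = DEFAULT_WINDOW_LENGTH


@dataclass(frozen=True)
class NormalizedTrace:
    """Baseline-normalized variance series (percent of baseline).

    `times` are window or bin centres in seconds relative to the stimulus
    (relative to record start when the record has no stimulus).  `bin_width`
    is ``None`` for the unbinned one-point-per-window form.  After replicate
    aggregation `sd` and `n` are populated per point; `is_partial` flags
    bins that do not cover a full bin width.
    """

    times: np.ndarray
    values: np.ndarray
    baseline_mean: float  # a.u.^2
    baseline_n: int
    bin_width: float | None = None
    window_length: float = DEFAULT_WINDOW_LENGTH
    sd: np.ndarray | None = None
    n: np.ndarray | None = None
    is_partial: np.ndarray | None = None
    condition: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")

    def post_stimulus(self) -> "NormalizedTrace":
        """The t > 0 portion of the trace."""
        keep = self.times > 0
        return replace(
            self,
            times=self.times[keep],
            values=self.values[keep],
            sd=None if self.sd is None else self.sd[keep],
            n=None if self.n is None else self.n[keep],
            is_partial=None if self.is_partial is None else self.is_partial[keep],
        )


def segment_windows(
    record: DeflectionRecord, window_length: float = DEFAULT_WINDOW_LENGTH
) -> list[tuple[int, int]]:
    """Split a record into contiguous full windows of `window_length` seconds.

    Returns ``(start, stop)`` sample-index pairs.  Windows are laid out from
    t = 0; the grid restarts at the stimulus so no window straddles it, and
    any partial window (trailing, or truncated at the stimulus) is dropped.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    n_win = int(round(window_length * record.sampling_rate))
    n = record.samples.size
    if n < n_win:
        raise ValueError(
            f"record ({record.duration:.1f}s) shorter than one "
            f"{window_length:.0f}s window"
        )
    blocks: list[tuple[int, int]] = []
    if record.stimulus_time is None:
        boundaries = [(0, n)]
    else:
        i_stim = int(round(record.stimulus_time * record.sampling_rate))
        boundaries = [(0, i_stim), (i_stim, n)]
    for lo, hi in boundaries:
        start = lo
        while start + n_win <= hi:
            blocks.append((start, start + n_win))
            start += n_win
    return blocks


def detrend_linear(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Residuals of an ordinary least-squares line fitted to one window.

    Residuals sum to zero and are orthogonal to time (to float precision).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("window must have at least 3 samples")
    tc = times - times.mean()
    stt = float(tc @ tc)
    if stt == 0.0:
        raise ValueError("degenerate window: constant time axis")
    slope = float(tc @ (values - values.mean())) / stt
    return values - values.mean() - slope * tc


def residual_variance(residuals: np.ndarray, n_params: int = 2) -> float:
    """Sum of squared residuals over ``n - n_params`` degrees of freedom."""
    residuals = np.asarray(residuals, dtype=float)
    n = residuals.size
    if n <= n_params:
        raise ValueError(f"need more than {n_params} samples, got {n}")
    return float(residuals @ residuals) / (n - n_params)


def _window_stats_vectorized(
    record: DeflectionRecord, blocks: list[tuple[int, int]]
) -> list[WindowStat]:
    """OLS fit + residual variance per window, grouped by window size."""
    stats: dict[int, WindowStat] = {}
    fs = record.sampling_rate
    stim = record.stimulus_time
    sizes: dict[int, list[int]] = {}
    for k, (lo, hi) in enumerate(blocks):
        sizes.setdefault(hi - lo, []).append(k)
    for n_win, idxs in sizes.items():
        starts = np.array([blocks[k][0] for k in idxs])
        y = np.stack([record.samples[s : s + n_win] for s in starts])
        # identical within-window time axis: centred offsets in seconds
        tc = (np.arange(n_win) - (n_win - 1) / 2.0) / fs
        stt = float(tc @ tc)
        ybar = y.mean(axis=1)
        slope = (y @ tc) / stt
        resid = y - ybar[:, None] - slope[:, None] * tc[None, :]
        var = np.einsum("ij,ij->i", resid, resid) / (n_win - 2)
        t_mid = (starts + (n_win - 1) / 2.0) / fs
        for j, k in enumerate(idxs):
            lo, hi = blocks[k]
            t_start, t_end = lo / fs, hi / fs
            t_center = (t_start + t_end) / 2.0
            stats[k] = WindowStat(
                t_start=t_start,
                t_end=t_end,
                t_center_rel=t_center - stim if stim is not None else t_center,
                fit_slope=float(slope[j]),
                fit_intercept=float(ybar[j] - slope[j] * t_mid[j]),
                variance=float(var[j]),
                n_samples=n_win,
            )
    return [stats[k] for k in range(len(blocks))]


def compute_variance_trace(
    record: DeflectionRecord, window_length: float = DEFAULT_WINDOW_LENGTH
) -> VarianceTrace:
    """Window, detrend and compute residual variance for a whole record."""
    blocks = segment_windows(record, window_length)
    windows = _window_stats_vectorized(record, blocks)
    return VarianceTrace(
        windows=tuple(windows),
        sampling_rate=record.sampling_rate,
        stimulus_time=record.stimulus_time,
        condition=record.condition,
        replicate_id=record.replicate_id,
        window_length=window_length,
    )


def normalize_to_baseline(
    trace: VarianceTrace, min_baseline_windows: int = MIN_BASELINE_WINDOWS
) -> NormalizedTrace:
    """Normalize window variances to the mean pre-stimulus variance (=100%).

    For a record without a stimulus every window counts as baseline, so the
    trace fluctuates around 100 by construction.
    """
    variances = np.array([w.variance for w in trace.windows])
    t_rel = np.array([w.t_center_rel for w in trace.windows])
    if trace.stimulus_time is None:
        baseline = variances
    else:
        baseline = variances[t_rel < 0]
    if baseline.size < min_baseline_windows:
        raise ValueError(
            f"only {baseline.size} baseline windows; "
            f"need at least {min_baseline_windows}"
        )
    baseline_mean = float(baseline.mean())
    if baseline_mean <= 0:
        raise ValueError("baseline mean variance must be positive")
    return NormalizedTrace(
        times=t_rel,
        values=100.0 * variances / baseline_mean,
        baseline_mean=baseline_mean,
        baseline_n=int(baseline.size),
        bin_width=None,
        window_length=trace.window_length,
        condition=trace.condition,
        replicate_id=trace.replicate_id,
    )


def bin_post_stimulus(
    trace: NormalizedTrace, bin_width: float = DEFAULT_BIN_WIDTH
) -> NormalizedTrace:
    """Average the normalized points into consecutive bins aligned at t = 0.

    Post-stimulus bins cover [0, w), [w, 2w), ...; pre-stimulus points are
    averaged into same-width bins for plotting.  The bin time is the nominal
    bin centre.  A trailing bin with fewer points than a full bin holds is
    kept and flagged partial.
    """
    if trace.bin_width is not None:
        raise ValueError("trace is already binned")
    if not MIN_BIN_WIDTH <= bin_width <= MAX_BIN_WIDTH:
        raise ValueError(
            f"bin_width must be in [{MIN_BIN_WIDTH:.0f}, {MAX_BIN_WIDTH:.0f}] s"
        )
    if abs(bin_width / trace.window_length - round(bin_width / trace.window_length)) > 1e-9:
        raise ValueError("bin_width must be a multiple of the window length")
    per_bin = int(round(bin_width / trace.window_length))

    idx = np.floor_divide(trace.times, bin_width).astype(int)
    out_t, out_v, out_n, out_part = [], [], [], []
    for b in np.unique(idx):
        sel = idx == b
        out_t.append((b + 0.5) * bin_width)
        out_v.append(float(trace.values[sel].mean()))
        cnt = int(np.count_nonzero(sel))
        out_n.append(cnt)
        out_part.append(cnt < per_bin)
    return NormalizedTrace(
        times=np.array(out_t),
        values=np.array(out_v),
        baseline_mean=trace.baseline_mean,
        baseline_n=trace.baseline_n,
        bin_width=bin_width,
        window_length=trace.window_length,
        n=np.array(out_n),
        is_partial=np.array(out_part),
        condition=trace.condition,
        replicate_id=trace.replicate_id,
    )


def aggregate_replicates(traces: list[NormalizedTrace]) -> NormalizedTrace:
    """Pointwise mean, SD and n over replicate traces on a common grid."""
    if not traces:
        raise ValueError("need at least one trace")
    ref = traces[0]
    for t in traces[1:]:
        if t.times.shape != ref.times.shape or not np.allclose(
            t.times, ref.times, atol=1e-9
        ):
            raise ValueError("replicate traces are not on a common time grid")
        if (t.bin_width is None) != (ref.bin_width is None):
            raise ValueError("cannot mix binned and unbinned traces")
    stack = np.stack([t.values for t in traces])
    mean = stack.mean(axis=0)
    sd = (
        stack.std(axis=0, ddof=1)
        if len(traces) > 1
        else np.zeros_like(mean)
    )
    return NormalizedTrace(
        times=ref.times.copy(),
        values=mean,
        baseline_mean=float(np.mean([t.baseline_mean for t in traces])),
        baseline_n=int(sum(t.baseline_n for t in traces)),
        bin_width=ref.bin_width,
        window_length=ref.window_length,
        sd=sd,
        n=np.full(mean.shape, len(traces)),
        is_partial=None if ref.is_partial is None else ref.is_partial.copy(),
        condition=ref.condition,
        replicate_id=f"mean_of_{len(traces)}",
    )
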