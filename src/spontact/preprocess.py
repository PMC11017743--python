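"""Trace preprocessing: background subtraction, ΔF/F0, smoothing, resampling.

The normalization follows the standard ΔF/F0 = (Ft − F0)/F0 convention,
expressed in percent.  F0 is either the mean of a fixed initial window
(default: the first 2 s) or a whole-trace percentile for recordings that
begin mid-transient.  A clamp rule guards against aberrant amplification by
tiny baselines: when F0 < 1 the denominator — but not the numerator — is set
to 1.

Rate harmonization uses a centered moving average (shrinking at the edges,
so no invented samples) followed by plain linear interpolation onto the
target frame grid, with no anti-alias filter; when both smoothing and
resampling are requested the pipeline smooths first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trace import TraceMatrix

__all__ = [
    "BaselineSpec",
    "subtract_background",
    "delta_f_over_f0",
    "smooth",
    "resample_linear",
    "extract_segment",
]


@dataclass(frozen=True)
class BaselineSpec:
    """How to estimate the per-neuron baseline F0.

    method
        ``fixed_window`` — mean of the first ``window`` seconds;
        ``percentile`` — ``percentile``-th percentile of the whole trace.
    clamp_denominator_below_one
        When True (default), an F0 below 1 is replaced by 1 in the
        denominator only, preventing huge ΔF/F0 from dim neurons.
    """

    method: str = "fixed_window"
    window: float = 2.0        # s, for fixed_window
    percentile: float = 10.0   # for percentile
    clamp_denominator_below_one: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("fixed_window", "percentile"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.method == "fixed_window" and not self.window > 0:
            raise ValueError("window must be positive")
        if self.method == "percentile" and not (0 < self.percentile < 100):
            raise ValueError("percentile must lie in (0, 100)")


def subtract_background(traces: TraceMatrix,
                        background: np.ndarray) -> TraceMatrix:
    """Subtract a per-frame background signal from every neuron's trace.

    Values may go negative; the ΔF/F0 clamp downstream handles dim results.
    """
    background = np.asarray(background, dtype=float).ravel()
    if background.size != traces.n_frames:
        raise ValueError(
            f"background length {background.size} does not match "
            f"frame count {traces.n_frames}")
    return traces.evolve("subtract_background",
                         values=traces.values - background[None, :])


def delta_f_over_f0(traces: TraceMatrix,
                    baseline: BaselineSpec | None = None) -> TraceMatrix:
    """Normalize raw traces to ΔF/F0 percent.

    Per neuron: ``100 × (Ft − F0) / F0_denom``, where ``F0_denom`` is
    ``max(F0, 1)`` when clamping is enabled and ``F0`` otherwise; the
    numerator always uses the unclamped F0.
    """
    if traces.normalized:
        raise ValueError("input is already ΔF/F0-normalized")
    baseline = baseline or BaselineSpec()

    x = traces.values
    if baseline.method == "fixed_window":
        if baseline.window > traces.duration + 1.0 / traces.sampling_rate:
            raise ValueError("baseline window exceeds recording duration")
        w = max(int(round(baseline.window * traces.sampling_rate)), 1)
        f0 = x[:, :w].mean(axis=1)
    else:
        f0 = np.percentile(x, baseline.percentile, axis=1)

    if baseline.clamp_denominator_below_one:
        denom = np.maximum(f0, 1.0)
    else:
        zero = np.isclose(f0, 0.0)
        if np.any(zero):
            bad = [traces.neuron_ids[i] for i in np.flatnonzero(zero)]
            raise ValueError(
                "F0 is zero with clamping disabled for neurons: "
                + ", ".join(bad))
        denom = f0
    out = 100.0 * (x - f0[:, None]) / denom[:, None]
    return traces.evolve("delta_f_over_f0", values=out, normalized=True,
                         method=baseline.method,
                         clamp=baseline.clamp_denominator_below_one)


def smooth(traces: TraceMatrix, window: float = 1.0) -> TraceMatrix:
    """Centered moving average over ``round(window × rate)`` frames.

    The window shrinks at the boundaries (no padding), so edge frames are
    averages of the frames that actually exist.  Length is preserved.
    """
    if window < 1.0 / traces.sampling_rate:
        raise ValueError("window must cover at least one frame")
    if window > traces.duration + 1.0 / traces.sampling_rate:
        raise ValueError("smoothing window exceeds recording duration")
    w = max(int(round(window * traces.sampling_rate)), 1)
    if w == 1:
        return traces.evolve("smooth", values=traces.values.copy(),
                             window=window)

    x = traces.values
    n = x.shape[1]
    half_l = (w - 1) // 2
    half_r = w // 2
    # sliding window sums with per-position counts, via cumulative sums
    cs = np.cumsum(np.concatenate(
        [np.zeros((x.shape[0], 1)), x], axis=1), axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r, n - 1)
    sums = cs[:, hi + 1] - cs[:, lo]
    counts = (hi - lo + 1).astype(float)
    return traces.evolve("smooth", values=sums / counts, window=window)


def resample_linear(traces: TraceMatrix, target_rate: float) -> TraceMatrix:
    """Resample onto a grid at ``target_rate`` Hz by linear interpolation.

    The new grid spans the same interval [0, (n−1)/rate]; each new value is
    a linear interpolation between the bracketing source frames.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if traces.n_frames < 2:
        raise ValueError("need at least 2 frames to resample")
    if math.isclose(target_rate, traces.sampling_rate):
        return traces.evolve("resample_linear", values=traces.values.copy(),
                             target_rate=target_rate)

    span = traces.duration
    n_new = int(math.floor(span * target_rate)) + 1
    t_old = traces.times
    t_new = np.arange(n_new) / target_rate
    out = np.empty((traces.n_neurons, n_new))
    for i in range(traces.n_neurons):
        out[i] = np.interp(t_new, t_old, traces.values[i])
    return traces.evolve("resample_linear", values=out,
                         sampling_rate=target_rate, target_rate=target_rate)


def extract_segment(traces: TraceMatrix, which: str,
                    n_frames: int) -> TraceMatrix:
    """Contiguous head (``first``) or tail (``last``) segment of ``n_frames``.

    Frames are 0-based, segments half-open, so ``first 1100`` of a recording
    is frames [0, 1100).
    """
    if which not in ("first", "last"):
        raise ValueError("which must be 'first' or 'last'")
    if not (0 < n_frames <= traces.n_frames):
        raise ValueError(
            f"n_frames={n_frames} out of range for a "
            f"{traces.n_frames}-frame recording")
    if which == "first":
        sl = slice(0, n_frames)
    else:
        sl = slice(traces.n_frames - n_frames, traces.n_frames)
    return traces.evolve("extract_segment", values=traces.values[:, sl].copy(),
                         which=which, n_frames=n_frames,
                         start_frame=sl.start)
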