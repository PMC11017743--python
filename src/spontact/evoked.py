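"""Stimulus-evoked response detection with a baseline-referenced threshold.

For each neuron and stimulus epoch the smoothed ΔF/F0 trace is compared
against ``Fb + (Fb_max − Fb) × x``, where Fb and Fb_max are the mean and
maximum over a pre-stimulus baseline window and x (default 2.5, usually
chosen in [2, 3] depending on baseline stability).  A response is positive
when the in-epoch peak exceeds the threshold *and* the longest contiguous
suprathreshold run lasts at least ``min_duration`` (default 0.5 s — very
brief excursions are excluded because a slow indicator cannot produce them).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import smooth
from .trace import TraceMatrix

__all__ = ["StimulusProtocol", "EvokedRule", "detect_evoked",
           "summarize_evoked"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping stimulus epochs (onset, offset in seconds)."""

    epochs: tuple[tuple[float, float], ...]
    modality: str = "unspecified"

    def __post_init__(self) -> None:
        prev_off = -np.inf
        for onset, offset in self.epochs:
            if not offset > onset:
                raise ValueError(f"epoch ({onset}, {offset}) has no extent")
            if onset < prev_off:
                raise ValueError("epochs must be ordered and non-overlapping")
            prev_off = offset


@dataclass(frozen=True)
class EvokedRule:
    x: float = 2.5                   # threshold multiplier, usually in [2, 3]
    smoothing_window: float = 1.0    # s
    min_duration: float = 0.5        # s, contiguous time above threshold
    baseline_start_offset: float = 1.0  # s after recording (or prior epoch)
    baseline_end_offset: float = 1.0    # s before stimulus onset
    post_offset_grace: float = 1.0      # s after offset still searched (slow indicator lag)

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("x must be positive")
        if not (2.0 <= self.x <= 3.0):
            warnings.warn(
                f"x = {self.x} lies outside the usual [2, 3] range",
                RuntimeWarning, stacklevel=2)
        if self.min_duration < 0:
            raise ValueError("min_duration must be nonnegative")


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest True run."""
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def detect_evoked(traces: TraceMatrix, protocol: StimulusProtocol,
                  rule: EvokedRule | None = None) -> pd.DataFrame:
    """Score every neuron × epoch for a positive evoked response.

    The baseline window for an epoch runs from ``baseline_start_offset``
    after the later of (recording start, previous epoch offset + grace) to
    ``baseline_end_offset`` before the epoch onset, so earlier evoked
    transients do not contaminate Fb.  A flat baseline (Fb_max = Fb) makes
    the threshold Fb itself — any sufficiently long suprathreshold
    excursion then counts.
    """
    if not traces.normalized:
        raise ValueError("detect_evoked expects ΔF/F0-normalized traces")
    rule = rule or EvokedRule()
    sm = smooth(traces, rule.smoothing_window)
    fs = sm.sampling_rate
    t_end = sm.duration

    rows = []
    prev_offset = None
    for eidx, (onset, offset) in enumerate(protocol.epochs):
        if onset >= t_end:
            logger.warning("epoch %d (onset %.2f s) outside the %.2f-s "
                           "recording; skipped", eidx, onset, t_end)
            continue
        base_from = rule.baseline_start_offset
        if prev_offset is not None:
            base_from = max(base_from, prev_offset + rule.post_offset_grace
                            + rule.baseline_start_offset)
        base_to = onset - rule.baseline_end_offset
        prev_offset = offset
        if base_to <= base_from:
            logger.warning("epoch %d has no usable baseline window; skipped",
                           eidx)
            continue
        b0 = int(np.ceil(base_from * fs))
        b1 = int(np.floor(base_to * fs)) + 1
        e0 = int(np.ceil(onset * fs))
        e1 = min(int(np.floor((offset + rule.post_offset_grace) * fs)) + 1,
                 sm.n_frames)

        base = sm.values[:, b0:b1]
        win = sm.values[:, e0:e1]
        fb = base.mean(axis=1)
        fb_max = base.max(axis=1)
        threshold = fb + (fb_max - fb) * rule.x
        peak = win.max(axis=1)
        min_frames = max(int(np.ceil(rule.min_duration * fs)), 1)
        for i, nid in enumerate(sm.neuron_ids):
            above = win[i] > threshold[i]
            run = _longest_run(above)
            positive = bool(peak[i] > threshold[i] and run >= min_frames)
            rows.append({
                "neuron_id": nid, "epoch": eidx,
                "onset": onset, "offset": offset,
                "fb": fb[i], "fb_max": fb_max[i],
                "threshold": threshold[i], "peak": peak[i],
                "duration_above": run / fs, "positive": positive,
            })
    return pd.DataFrame(rows, columns=[
        "neuron_id", "epoch", "onset", "offset", "fb", "fb_max",
        "threshold", "peak", "duration_above", "positive"])


def summarize_evoked(table: pd.DataFrame, quorum: int = 1) -> pd.DataFrame:
    """Collapse the per-epoch table into per-neuron responder flags.

    A neuron is a responder when it is positive in at least ``quorum``
    epochs; the fraction of positive epochs is reported alongside.
    """
    if quorum < 1:
        raise ValueError("quorum must be ≥ 1")
    if table.empty:
        return pd.DataFrame(columns=["neuron_id", "n_epochs", "n_positive",
                                     "response_fraction", "responder"])
    grp = table.groupby("neuron_id", sort=False)
    out = grp["positive"].agg(n_epochs="count", n_positive="sum").reset_index()
    out["response_fraction"] = out["n_positive"] / out["n_epochs"]
    out["responder"] = out["n_positive"] >= quorum
    return out
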