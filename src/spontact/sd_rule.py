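"""Standard-deviation threshold rule for spontaneous-activity calls.

The historical comparator the interval forests are measured against: a
neuron is called spontaneously active when its ΔF/F0 trace exceeds
mean + k×SD on more than ``min_occasions`` occasions within a 5-minute
window (defaults k = 2.5, 30 occasions, 300 s).  An "occasion" defaults to
an upward crossing — a sample above threshold whose predecessor was at or
below — so a single long transient cannot count as hundreds of occasions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trace import ACTIVE, INACTIVE, LabelSet, TraceMatrix

__all__ = ["SdRule", "sd_classify", "sd_statistics"]


@dataclass(frozen=True)
class SdRule:
    k: float = 2.5
    min_occasions: int = 30
    window: float = 300.0  # s
    occasion_definition: str = "upward_crossing"  # or "sample_above"

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be positive")
        if self.min_occasions < 1:
            raise ValueError("min_occasions must be ≥ 1")
        if not self.window > 0:
            raise ValueError("window must be positive")
        if self.occasion_definition not in ("upward_crossing", "sample_above"):
            raise ValueError(
                f"unknown occasion definition {self.occasion_definition!r}")


def _count_occasions(x: np.ndarray, threshold: float, definition: str) -> int:
    above = x > threshold
    if definition == "sample_above":
        return int(above.sum())
    # upward crossing: above now, at-or-below at the previous frame
    return int(np.count_nonzero(above[1:] & ~above[:-1]))


def sd_classify(traces: TraceMatrix,
                rule: SdRule | None = None) -> tuple[LabelSet, pd.DataFrame]:
    """Apply the SD-threshold rule per neuron.

    Recordings longer than the window are evaluated on the first window only
    (matching the training-segment convention); shorter recordings scale the
    occasion requirement proportionally, rounded up.  Returns the label set
    and a per-neuron report (SD, threshold, occasion count, degenerate flag).
    """
    if not traces.normalized:
        raise ValueError("sd_classify expects ΔF/F0-normalized traces")
    rule = rule or SdRule()

    n_window = int(round(rule.window * traces.sampling_rate))
    n_eval = min(traces.n_frames, max(n_window, 2))
    if n_eval < n_window:
        span = n_eval / traces.sampling_rate
        min_occ = math.ceil(rule.min_occasions * span / rule.window)
    else:
        min_occ = rule.min_occasions

    seg = traces.values[:, :n_eval]
    rows = []
    labels: dict[str, str] = {}
    degenerate = []
    for i, nid in enumerate(traces.neuron_ids):
        x = seg[i]
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        if sd == 0.0:
            degenerate.append(nid)
            labels[nid] = INACTIVE
            rows.append((nid, sd, mean, mean, 0, True, INACTIVE))
            continue
        threshold = mean + rule.k * sd
        occ = _count_occasions(x, threshold, rule.occasion_definition)
        lab = ACTIVE if occ > min_occ else INACTIVE  # strict: "more than 30"
        labels[nid] = lab
        rows.append((nid, sd, mean, threshold, occ, False, lab))
    if degenerate:
        warnings.warn(
            f"zero-variance traces labeled inactive: {degenerate}",
            RuntimeWarning, stacklevel=2)

    report = pd.DataFrame(
        rows, columns=["neuron_id", "sd", "mean", "threshold",
                       "occasions", "degenerate", "label"])
    report.attrs["min_occasions_effective"] = min_occ
    report.attrs["n_frames_evaluated"] = n_eval
    return LabelSet(labels, source="predicted_sd"), report


def sd_statistics(traces: TraceMatrix,
                  labels: LabelSet | None = None,
                  sd_cutoff: float | None = None) -> pd.DataFrame:
    """Per-neuron SD table (ΔF/F0 percent), sample (n−1) convention.

    With ``labels`` and ``sd_cutoff`` given, the returned frame's ``attrs``
    carry the fraction of each label class with SD below the cutoff — the
    style of summary used to show that SD distributions of active and
    inactive neurons overlap.
    """
    if not traces.normalized:
        raise ValueError("sd_statistics expects ΔF/F0-normalized traces")
    sds = np.std(traces.values, axis=1, ddof=1)
    table = pd.DataFrame({"neuron_id": traces.neuron_ids, "sd": sds})
    if labels is not None:
        table["label"] = [labels[nid] for nid in traces.neuron_ids]
        if sd_cutoff is not None:
            frac = {}
            for lab, grp in table.groupby("label"):
                frac[lab] = float((grp["sd"] < sd_cutoff).mean())
            table.attrs["fraction_below_cutoff"] = frac
            table.attrs["sd_cutoff"] = sd_cutoff
    return table
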