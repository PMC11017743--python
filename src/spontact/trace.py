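"""Core in-memory containers: fluorescence trace matrices and label sets.

A :class:`TraceMatrix` holds a neurons-by-frames array of either raw
fluorescence (arbitrary units) or baseline-normalized ΔF/F0 (percent),
together with the sampling rate and stable neuron identifiers.  Every
operation in the pipeline consumes and returns these objects and appends a
record to the provenance log, so a processed matrix carries its own history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = ["TraceMatrix", "LabelSet", "ACTIVE", "INACTIVE", "AMBIGUOUS"]

ACTIVE = "active"
INACTIVE = "inactive"
AMBIGUOUS = "ambiguous"

_VALID_LABELS = frozenset({ACTIVE, INACTIVE, AMBIGUOUS})


@dataclass
class TraceMatrix:
    """Fluorescence traces for a recording, one row per neuron.

    Parameters
    ----------
    values : ndarray, shape (n_neurons, n_frames)
        Fluorescence values.  Raw (arbitrary units) unless ``normalized``
        is True, in which case they are ΔF/F0 in percent.
    sampling_rate : float
        Acquisition rate in Hz.
    neuron_ids : sequence of str, optional
        Stable identifiers, one per row.  Defaults to ``n0, n1, ...``.
    normalized : bool
        Whether ``values`` are ΔF/F0 percent.
    provenance : list of dict
        Append-only log of the operations applied so far.
    """

    values: np.ndarray
    sampling_rate: float
    neuron_ids: Sequence[str] | None = None
    normalized: bool = False
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D neurons × frames array")
        if self.values.shape[1] < 2:
            raise ValueError("a trace matrix needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must all be finite")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = [f"n{i}" for i in range(self.values.shape[0])]
        else:
            self.neuron_ids = [str(n) for n in self.neuron_ids]
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must match the number of rows")
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise ValueError("neuron_ids must be unique")

    # -- basic geometry -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Time spanned by the frame grid, (n_frames − 1) / rate, seconds."""
        return (self.n_frames - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.sampling_rate

    # -- derivation -----------------------------------------------------
    def evolve(self, step: str, /, values: np.ndarray | None = None,
               **changes) -> "TraceMatrix":
        """Return a copy with ``values``/metadata replaced and ``step``
        (plus its parameters) appended to the provenance log."""
        params = {k: v for k, v in changes.items()
                  if k not in ("sampling_rate", "normalized", "neuron_ids")}
        fields = {k: v for k, v in changes.items()
                  if k in ("sampling_rate", "normalized", "neuron_ids")}
        new = replace(
            self,
            values=self.values if values is None else values,
            provenance=[*self.provenance, {"step": step, **params}],
            **fields,
        )
        return new

    def copy(self) -> "TraceMatrix":
        return replace(self, values=self.values.copy(),
                       provenance=list(self.provenance))


@dataclass
class LabelSet:
    """Per-neuron activity labels with their provenance.

    ``labels`` maps neuron_id → one of ``active`` / ``inactive`` /
    ``ambiguous``; ``source`` records how the labels were produced
    (e.g. ``simulated_truth``, ``predicted_rise``, ``ground_truth_lidocaine``).
    """

    labels: Mapping[str, str]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.labels = dict(self.labels)
        bad = {v for v in self.labels.values()} - _VALID_LABELS
        if bad:
            raise ValueError(f"invalid labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, neuron_id: str) -> str:
        return self.labels[neuron_id]

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.labels)

    def unambiguous(self) -> dict[str, str]:
        return {k: v for k, v in self.labels.items() if v != AMBIGUOUS}

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)

    def to_array(self, neuron_ids: Sequence[str]) -> np.ndarray:
        """Binary vector (1 = active) over ``neuron_ids``; ambiguous raises."""
        out = np.empty(len(neuron_ids), dtype=int)
        for i, nid in enumerate(neuron_ids):
            lab = self.labels[nid]
            if lab == AMBIGUOUS:
                raise ValueError(f"neuron {nid} is ambiguous")
            out[i] = 1 if lab == ACTIVE else 0
        return out

    @classmethod
    def from_array(cls, neuron_ids: Sequence[str], flags: Sequence[int],
                   source: str = "unspecified") -> "LabelSet":
        return cls({str(n): (ACTIVE if f else INACTIVE)
                    for n, f in zip(neuron_ids, flags, strict=True)}, source)
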