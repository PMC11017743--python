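"""Readers and writers: trace matrices (CSV/HDF5 + JSON metadata), label
tables, stimulus tables and trained-model archives.

Conventions: trace files are oriented rows = neurons, columns = frames;
CSV uses comma separators, period decimals and a neuron_id index column.
A JSON sidecar (``<stem>.json``) carries sampling rate, normalization state
and the provenance log; HDF5 files carry the same as attributes.
Model archives are zip files holding ``metadata.json`` plus a joblib store
of the fitted forest; the format version is checked on load.
"""

from __future__ import annotations

import json
import logging
import zipfile
from pathlib import Path

import h5py
import joblib
import numpy as np
import pandas as pd

from .classify import ForestModel
from .evoked import StimulusProtocol
from .trace import LabelSet, TraceMatrix

__all__ = [
    "read_traces", "write_traces",
    "read_labels", "write_labels",
    "read_stimulus_table", "write_stimulus_table",
    "save_model", "load_model",
    "MODEL_FORMAT_VERSION",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


# ---------------------------------------------------------------------------
# trace matrices
# ---------------------------------------------------------------------------

def write_traces(traces: TraceMatrix, path: str | Path) -> Path:
    """Write a trace matrix to ``.csv`` or ``.h5``/``.hdf5`` (by extension),
    plus a JSON metadata sidecar for CSV."""
    path = Path(path)
    meta = {
        "sampling_rate": traces.sampling_rate,
        "normalized": traces.normalized,
        "n_neurons": traces.n_neurons,
        "n_frames": traces.n_frames,
        "provenance": traces.provenance,
    }
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("traces", data=traces.values)
            ds.attrs["sampling_rate"] = traces.sampling_rate
            ds.attrs["normalized"] = traces.normalized
            ds.attrs["neuron_ids"] = [str(n) for n in traces.neuron_ids]
            ds.attrs["provenance"] = json.dumps(traces.provenance)
    elif path.suffix.lower() == ".csv":
        df = pd.DataFrame(traces.values, index=traces.neuron_ids)
        df.index.name = "neuron_id"
        df.to_csv(path)
        _sidecar(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r}")
    return path


def read_traces(path: str | Path,
                sampling_rate: float | None = None) -> TraceMatrix:
    """Read a trace matrix written by :func:`write_traces` (or hand-made in
    the same layout).  ``sampling_rate`` overrides / substitutes for a
    missing sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["traces"]
            values = ds[...]
            rate = float(ds.attrs["sampling_rate"])
            normalized = bool(ds.attrs.get("normalized", False))
            ids = [str(n) for n in ds.attrs.get("neuron_ids", [])] or None
            prov = json.loads(str(ds.attrs.get("provenance", "[]")))
        return TraceMatrix(values, sampling_rate or rate, neuron_ids=ids,
                           normalized=normalized, provenance=prov)

    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    rate = sampling_rate or meta.get("sampling_rate")
    if rate is None:
        raise ValueError(
            f"no sampling rate: provide one or add a sidecar {_sidecar(path)}")
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric cell at row {i} (neuron "
                    f"{df.index[i]!r}), column {j} ({col!r}) of {path}")
        raise ValueError(f"non-numeric data in {path}")
    return TraceMatrix(values.astype(float), float(rate),
                       neuron_ids=[str(i) for i in df.index],
                       normalized=bool(meta.get("normalized", False)),
                       provenance=list(meta.get("provenance", [])))


# ---------------------------------------------------------------------------
# labels and stimulus tables
# ---------------------------------------------------------------------------

def write_labels(labels: LabelSet, path: str | Path,
                 votes: dict[str, float] | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({"neuron_id": list(labels.labels),
                       "label": list(labels.labels.values())})
    if votes is not None:
        df["vote_fraction"] = [votes.get(n, np.nan) for n in df["neuron_id"]]
    df.attrs["source"] = labels.source
    df.to_csv(path, index=False)
    return path


def read_labels(path: str | Path, source: str = "file") -> LabelSet:
    df = pd.read_csv(path)
    if not {"neuron_id", "label"} <= set(df.columns):
        raise ValueError(f"{path} must have neuron_id and label columns")
    return LabelSet(dict(zip(df["neuron_id"].astype(str), df["label"])),
                    source=source)


def write_stimulus_table(protocol: StimulusProtocol, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"onset": a, "offset": b, "modality": protocol.modality}
         for a, b in protocol.epochs]).to_csv(path, index=False)
    return path


def read_stimulus_table(path: str | Path) -> StimulusProtocol:
    df = pd.read_csv(path)
    if not {"onset", "offset"} <= set(df.columns):
        raise ValueError(f"{path} must have onset and offset columns")
    modality = (str(df["modality"].iloc[0])
                if "modality" in df.columns and len(df) else "unspecified")
    epochs = tuple((float(a), float(b))
                   for a, b in zip(df["onset"], df["offset"]))
    return StimulusProtocol(epochs=epochs, modality=modality)


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------

def save_model(model: ForestModel, path: str | Path) -> Path:
    """Serialize a trained forest to a zip archive (metadata + tree store)."""
    path = Path(path)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "algorithm": model.algorithm,
        "n_trees": model.n_trees,
        "training_length": model.training_length,
        "sampling_rate": model.sampling_rate,
        "seed": model.seed,
        "normalization_mode": model.normalization_mode,
        "class_labels": list(model.class_labels),
        "hyperparams": model.hyperparams,
        "training_metadata": model.training_metadata,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("metadata.json", json.dumps(meta, indent=1))
        import io as _io
        buf = _io.BytesIO()
        joblib.dump(model.forest, buf)
        zf.writestr("forest.joblib", buf.getvalue())
    return path


def load_model(path: str | Path) -> ForestModel:
    """Load a model archive; refuses unknown format versions."""
    path = Path(path)
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("metadata.json"))
        version = meta.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model archive {path} has format version {version!r}; "
                f"this build reads version {MODEL_FORMAT_VERSION}")
        import io as _io
        forest = joblib.load(_io.BytesIO(zf.read("forest.joblib")))
    return ForestModel(
        algorithm=meta["algorithm"], forest=forest,
        training_length=int(meta["training_length"]),
        sampling_rate=float(meta["sampling_rate"]),
        seed=int(meta["seed"]), n_trees=int(meta["n_trees"]),
        normalization_mode=meta.get("normalization_mode", "dff0"),
        class_labels=tuple(meta.get("class_labels", ("inactive", "active"))),
        hyperparams=meta.get("hyperparams", {}),
        training_metadata=meta.get("training_metadata", {}))
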