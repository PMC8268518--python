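"""Reading and writing of raw SMBJ current traces and dataset manifests.

A single-molecule break-junction (SMBJ) experiment produces one current
trace per junction pull.  Traces within a dataset share acquisition
metadata (bias voltage, sampling rate) but in general have unequal
lengths, so the canonical on-disk layout is a hierarchical (HDF5)
container with one group per dataset and one array per trace; delimited
text (one trace per column) is accepted as a secondary import dialect.

Currents are stored in amperes as floating point.  No unit autodetection
is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CurrentTrace",
    "DatasetManifest",
    "TraceIOError",
    "read_manifest",
    "write_manifest",
    "read_traces",
    "write_traces",
]


class TraceIOError(ValueError):
    """Raised for malformed trace files or manifest records."""


@dataclass(frozen=True)
class CurrentTrace:
    """One junction-pull current time series with acquisition metadata.

    Parameters
    ----------
    samples : array of float
        Preamplifier current readings in amperes, in acquisition order.
    sampling_rate : float
        Acquisition rate in Hz (must be positive).
    bias_voltage : float
        Applied bias in volts (must be positive).
    dataset_label : str
        Identifier of the dataset the trace belongs to (e.g. ``"S1"``).
    trace_id : str
        Stable identifier; ``<dataset_label>:<index>`` when auto-assigned.
    """

    samples: np.ndarray
    sampling_rate: float
    bias_voltage: float
    dataset_label: str = ""
    trace_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise TraceIOError(
                f"trace {self.trace_id!r}: samples must be a non-empty 1-D array"
            )
        object.__setattr__(self, "samples", samples)
        if not self.sampling_rate > 0:
            raise TraceIOError(f"trace {self.trace_id!r}: sampling_rate must be > 0")
        if not self.bias_voltage > 0:
            raise TraceIOError(f"trace {self.trace_id!r}: bias_voltage must be > 0")

    def __len__(self) -> int:
        return int(self.samples.size)

    def with_samples(self, samples: np.ndarray, **changes) -> "CurrentTrace":
        """Copy of this trace with new sample values (metadata preserved)."""
        return replace(self, samples=samples, **changes)


@dataclass(frozen=True)
class DatasetManifest:
    """Per-dataset acquisition record: one row of the study's design table.

    ``sequence_note`` and ``buffer_note`` are opaque free text carried
    along for provenance; they are never interpreted.
    """

    label: str
    bias_voltage: float
    sampling_rate: float
    sequence_note: str = ""
    buffer_note: str = ""

    def __post_init__(self) -> None:
        if not self.bias_voltage > 0:
            raise TraceIOError(f"manifest {self.label!r}: bias_voltage must be > 0")
        if not self.sampling_rate > 0:
            raise TraceIOError(f"manifest {self.label!r}: sampling_rate must be > 0")


_MANIFEST_COLUMNS = {
    "label": "label",
    "sequence_note": "sequence_note",
    "bias_voltage_V": "bias_voltage",
    "sampling_rate_Hz": "sampling_rate",
    "buffer_note": "buffer_note",
}


def read_manifest(path: str | Path) -> list[DatasetManifest]:
    """Read dataset manifests from CSV or JSON.

    CSV columns / JSON keys: ``label, sequence_note, bias_voltage_V,
    sampling_rate_Hz, buffer_note``.  Labels must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"manifest file not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    manifests = []
    for rec in records:
        kwargs = {}
        for col, attr in _MANIFEST_COLUMNS.items():
            if col in rec and not pd.isna(rec[col]):
                kwargs[attr] = rec[col]
        try:
            manifests.append(
                DatasetManifest(
                    label=str(kwargs["label"]),
                    bias_voltage=float(kwargs["bias_voltage"]),
                    sampling_rate=float(kwargs["sampling_rate"]),
                    sequence_note=str(kwargs.get("sequence_note", "")),
                    buffer_note=str(kwargs.get("buffer_note", "")),
                )
            )
        except KeyError as exc:
            raise TraceIOError(f"manifest record missing field {exc}: {rec}") from exc
    labels = [m.label for m in manifests]
    if len(set(labels)) != len(labels):
        raise TraceIOError(f"duplicate labels in manifest: {labels}")
    return manifests


def write_manifest(manifests: Sequence[DatasetManifest], path: str | Path) -> Path:
    """Write manifests as CSV (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    records = [
        {
            "label": m.label,
            "sequence_note": m.sequence_note,
            "bias_voltage_V": m.bias_voltage,
            "sampling_rate_Hz": m.sampling_rate,
            "buffer_note": m.buffer_note,
        }
        for m in manifests
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2))
    else:
        pd.DataFrame(records).to_csv(path, index=False)
    return path


def write_traces(traces: Sequence[CurrentTrace], path: str | Path) -> Path:
    """Write a single-dataset trace collection to an HDF5 container.

    Layout: one group named after the dataset label, one dataset per
    trace (``trace_000000`` ...), with manifest metadata as group
    attributes and the trace id as a per-array attribute.  Unequal trace
    lengths are preserved without padding.
    """
    traces = list(traces)
    if not traces:
        raise TraceIOError("cannot write an empty trace collection")
    labels = {t.dataset_label for t in traces}
    if len(labels) != 1:
        raise TraceIOError(f"all traces must share one dataset_label, got {sorted(labels)}")
    path = Path(path)
    with h5py.File(path, "a") as f:
        label = traces[0].dataset_label
        if label in f:
            del f[label]
        grp = f.create_group(label)
        grp.attrs["bias_voltage_V"] = traces[0].bias_voltage
        grp.attrs["sampling_rate_Hz"] = traces[0].sampling_rate
        for i, trace in enumerate(traces):
            ds = grp.create_dataset(f"trace_{i:06d}", data=trace.samples)
            ds.attrs["trace_id"] = trace.trace_id or f"{label}:{i}"
    return path


def read_traces(path: str | Path, manifest: DatasetManifest) -> list[CurrentTrace]:
    """Read the traces of one dataset, tagging them with manifest metadata.

    Supported dialects:

    * HDF5 container written by :func:`write_traces` (group named
      ``manifest.label``);
    * delimited text (CSV), one trace per column; trailing blank cells
      allow unequal lengths.

    Missing trace ids are assigned as ``<label>:<zero-based index>``.
    """
    path = Path(path)
    if not path.exists():
        raise TraceIOError(f"trace file not found: {path}")
    if path.suffix.lower() in {".h5", ".hdf5", ".hdf"}:
        return _read_hdf5(path, manifest)
    return _read_delimited(path, manifest)


def _read_hdf5(path: Path, manifest: DatasetManifest) -> list[CurrentTrace]:
    traces = []
    with h5py.File(path, "r") as f:
        if manifest.label not in f:
            raise TraceIOError(f"dataset {manifest.label!r} not present in {path}")
        grp = f[manifest.label]
        for i, name in enumerate(sorted(grp.keys())):
            samples = np.asarray(grp[name][()], dtype=np.float64)
            if samples.size == 0:
                raise TraceIOError(f"empty trace {name!r} in dataset {manifest.label!r}")
            trace_id = grp[name].attrs.get("trace_id", f"{manifest.label}:{i}")
            traces.append(
                CurrentTrace(
                    samples=samples,
                    sampling_rate=manifest.sampling_rate,
                    bias_voltage=manifest.bias_voltage,
                    dataset_label=manifest.label,
                    trace_id=str(trace_id),
                )
            )
    return traces


def _read_delimited(path: Path, manifest: DatasetManifest) -> list[CurrentTrace]:
    try:
        frame = pd.read_csv(path, header=None)
    except pd.errors.EmptyDataError as exc:
        raise TraceIOError(f"no trace records in {path}") from exc
    traces = []
    for j, col in enumerate(frame.columns):
        raw = frame[col]
        values = pd.to_numeric(raw, errors="coerce")
        bad = values.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TraceIOError(
                f"non-numeric sample at row {row}, column {j} of {path}: {raw.iloc[row]!r}"
            )
        samples = values.dropna().to_numpy(dtype=np.float64)
        if samples.size == 0:
            raise TraceIOError(f"empty trace in column {j} of {path}")
        traces.append(
            CurrentTrace(
                samples=samples,
                sampling_rate=manifest.sampling_rate,
                bias_voltage=manifest.bias_voltage,
                dataset_label=manifest.label,
                trace_id=f"{manifest.label}:{j}",
            )
        )
    return traces
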