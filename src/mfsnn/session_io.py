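"""HDF5 session/benchmark files and tabular result export.

Layout: one group per session (``/session_<k>/spikes`` int16 trials x
channels x bins, ``/session_<k>/labels`` int8) with provenance stored as
JSON text in group attributes and paradigm-level metadata in file
attributes.  Integer inputs of other widths are accepted and coerced to
the canonical dtypes when they fit.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .synth import SessionData

__all__ = [
    "save_session",
    "load_session",
    "save_benchmark",
    "load_benchmark",
    "export_results",
    "export_labels_csv",
]


def _coerce_int(arr: np.ndarray, dtype, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{name} must be an integer array, got dtype {arr.dtype}")
    info = np.iinfo(dtype)
    if arr.size and (arr.min() < info.min or arr.max() > info.max):
        raise ValueError(f"{name} values do not fit in {np.dtype(dtype).name}")
    return arr.astype(dtype)


def _write_session(group: h5py.Group, session: SessionData) -> None:
    group.create_dataset("spikes", data=_coerce_int(session.spikes, np.int16, "spikes"))
    group.create_dataset("labels", data=_coerce_int(session.labels, np.int8, "labels"))
    group.attrs["session_id"] = session.session_id
    group.attrs["provenance"] = json.dumps(session.provenance, sort_keys=True)


def _read_session(group: h5py.Group, key: str) -> SessionData:
    for name in ("spikes", "labels"):
        if name not in group:
            raise KeyError(f"session group '{key}' is missing dataset '{name}'")
    return SessionData(
        spikes=group["spikes"][...].astype(np.int16),
        labels=group["labels"][...].astype(np.int8),
        session_id=str(group.attrs.get("session_id", key)),
        provenance=json.loads(group.attrs.get("provenance", "{}")),
    )


def save_session(path, session: SessionData) -> None:
    """Write a single session as ``/session_0`` in a fresh HDF5 file."""
    save_benchmark(path, [session])


def load_session(path, index: int = 0) -> SessionData:
    return load_benchmark(path)[index]


def save_benchmark(path, sessions: list[SessionData], attrs: dict | None = None) -> None:
    """Write sessions as ``/session_<k>`` groups plus file-level metadata."""
    with h5py.File(path, "w") as fh:
        fh.attrs["n_sessions"] = len(sessions)
        prov = sessions[0].provenance if sessions else {}
        spec = prov.get("population_spec", {})
        fh.attrs["paradigm"] = spec.get("paradigm", "unknown")
        fh.attrs["bin_ms"] = float(spec.get("bin_ms", 0.0))
        fh.attrs["specs_json"] = json.dumps(spec, sort_keys=True)
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v
        for k, sess in enumerate(sessions):
            _write_session(fh.create_group(f"session_{k}"), sess)


def load_benchmark(path) -> list[SessionData]:
    with h5py.File(path, "r") as fh:
        keys = sorted(
            (k for k in fh if k.startswith("session_")),
            key=lambda s: int(s.split("_")[1]),
        )
        if not keys:
            raise KeyError(f"no session groups found in {path}")
        return [_read_session(fh[k], k) for k in keys]


def export_labels_csv(session: SessionData, path) -> None:
    pd.DataFrame(
        {"trial": np.arange(session.n_trials), "label": session.labels}
    ).to_csv(path, index=False)


def export_results(result, path) -> None:
    """CSV for tabular protocol results, JSON for energy reports."""
    from .energy import EnergyReport
    from .training import ProtocolResult

    if isinstance(result, ProtocolResult):
        result.to_csv(path)
    elif isinstance(result, EnergyReport):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(result.to_json())
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False, float_format="%.6f")
    else:
        raise TypeError(f"cannot export object of type {type(result).__name__}")
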