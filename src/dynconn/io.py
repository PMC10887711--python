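"""File formats at the pipeline boundary.

HDF5 is the canonical intermediate format (datasets ``/data`` (channels
x samples), ``/rate``, ``/labels``, optional ``/coords``); CSV (one
header row of labels, samples as rows) and EDF (read-only, via mne) are
supported at the boundary.  Ground-truth networks and connectivity
graphs serialize to JSON/TSV edge lists, behavior to TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import MultichannelSeries
from .synth import BehavioralSession, Edge, MVARSpec
from .tpdc import ConnectivityGraph

__all__ = [
    "read_recording",
    "write_recording",
    "write_edges_json",
    "read_edges_json",
    "write_graph",
    "write_behavior_tsv",
]


def write_recording(path: str | Path, series: MultichannelSeries) -> Path:
    """Write a series to HDF5 (.h5/.hdf5) or CSV (.csv, with .rate sidecar)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=series.data)
            f.create_dataset("rate", data=float(series.rate))
            f.create_dataset(
                "labels",
                data=np.array(series.labels, dtype=h5py.string_dtype()),
            )
            f.create_dataset("t0", data=float(series.t0))
    elif path.suffix == ".csv":
        pd.DataFrame(series.data.T, columns=series.labels).to_csv(
            path, index=False
        )
        path.with_suffix(".rate.json").write_text(
            json.dumps({"rate": series.rate, "t0": series.t0})
        )
    else:
        raise ValueError(f"unsupported output format {path.suffix!r}")
    return path


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    rate: float | None = None,
) -> MultichannelSeries:
    """Read a recording from HDF5, CSV, or EDF.

    For CSV the sampling rate comes from a ``<stem>.rate.json`` sidecar
    or the ``rate`` argument; EDF reading requires the optional mne
    dependency.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or {
        ".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv", ".edf": "edf"
    }.get(path.suffix.lower())
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            labels = [
                x.decode() if isinstance(x, bytes) else str(x)
                for x in f["labels"][()]
            ]
            return MultichannelSeries(
                f["data"][()], float(f["rate"][()]), labels,
                float(f["t0"][()]) if "t0" in f else 0.0,
            )
    if fmt == "csv":
        df = pd.read_csv(path)
        t0 = 0.0
        sidecar = path.with_suffix(".rate.json")
        if rate is None:
            if not sidecar.exists():
                raise ValueError(
                    f"sampling rate unknown for {path.name}: provide the "
                    "--rate flag or a .rate.json sidecar"
                )
            meta = json.loads(sidecar.read_text())
            rate = float(meta["rate"])
            t0 = float(meta.get("t0", 0.0))
        return MultichannelSeries(
            df.to_numpy(dtype=float).T, rate, list(df.columns), t0
        )
    if fmt == "edf":
        try:
            import mne
        except ImportError as err:  # pragma: no cover
            raise ImportError(
                "EDF reading requires mne (install the 'edf' extra)"
            ) from err
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return MultichannelSeries(
            raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)
        )
    raise ValueError(f"cannot infer format of {path}")


def write_edges_json(path: str | Path, spec: MVARSpec) -> Path:
    """Serialize a ground-truth edge list as JSON records."""
    path = Path(path)
    records = [
        {"src": e.src, "dst": e.dst, "coeff": e.coeff, "lag": e.lag}
        for e in (spec.edges or [])
    ]
    path.write_text(json.dumps({"edges": records, "labels": spec.labels}))
    return path


def read_edges_json(path: str | Path) -> list[Edge]:
    payload = json.loads(Path(path).read_text())
    return [Edge(**rec) for rec in payload["edges"]]


def write_graph(path: str | Path, graph: ConnectivityGraph) -> Path:
    """Write a connectivity graph as JSON (.json) or TSV edge list (.tsv)."""
    path = Path(path)
    df = graph.to_dataframe()
    if path.suffix == ".json":
        payload = {
            "band": graph.band.name,
            "nodes": graph.node_labels,
            "coords": None if graph.coords is None else graph.coords.tolist(),
            "edges": df.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    elif path.suffix == ".tsv":
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unsupported graph format {path.suffix!r}")
    return path


def write_behavior_tsv(path: str | Path, session: BehavioralSession) -> Path:
    """One row per condition: trial counts, hits, false alarms."""
    rows = [
        {
            "condition": cond,
            "n_signal_trials": c.n_signal_trials,
            "n_noise_trials": c.n_noise_trials,
            "hits": c.hits,
            "false_alarms": c.false_alarms,
        }
        for cond, c in session.conditions.items()
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
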