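"""HDF5 containers and flat-text exports for the pipeline's artefacts.

One container layout is shared by all RDM-like objects: ``labels`` (UTF-8),
``times`` (ms), a ``values`` stack, and a ``source`` attribute.  Loaders
also accept per-timepoint CSV matrices for externally supplied M/EEG or
fMRI RDMs.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .rdm import RDM, RDMSeries
from .similarity import TimeTimeMap
from .trajectories import MeanTrajectorySet

__all__ = [
    "save_rdm",
    "load_rdm",
    "save_rdm_series",
    "load_rdm_series",
    "save_means",
    "load_means",
    "save_timetime",
    "load_timetime",
    "rdm_series_to_csv",
    "rdm_from_csv_matrix",
    "write_json",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_labels(g, labels):
    g.create_dataset(
        "labels", data=np.array(labels, dtype=object), dtype=_STR, track_times=False
    )


def _read_labels(g):
    return [l.decode() if isinstance(l, bytes) else str(l) for l in g["labels"][()]]


def save_rdm(path, rdm: RDM) -> None:
    with h5py.File(path, "w") as f:
        _write_labels(f, rdm.labels)
        f.create_dataset("values", data=rdm.values, track_times=False)
        f.attrs["source"] = rdm.source
        f.attrs["kind"] = "rdm"


def load_rdm(path) -> RDM:
    with h5py.File(path, "r") as f:
        return RDM(_read_labels(f), f["values"][()], str(f.attrs.get("source", "")))


def save_rdm_series(path, series: RDMSeries) -> None:
    with h5py.File(path, "w") as f:
        _write_labels(f, series.labels)
        f.create_dataset("times", data=series.times, track_times=False)
        f.create_dataset("values", data=series.values, compression="gzip", track_times=False)
        f.attrs["source"] = series.source
        f.attrs["kind"] = "rdm_series"


def load_rdm_series(path) -> RDMSeries:
    with h5py.File(path, "r") as f:
        return RDMSeries(
            _read_labels(f),
            f["times"][()],
            f["values"][()],
            str(f.attrs.get("source", "")),
        )


def save_means(path, means: MeanTrajectorySet) -> None:
    with h5py.File(path, "w") as f:
        _write_labels(f, means.labels)
        f.create_dataset("times", data=means.time_grid, track_times=False)
        f.create_dataset("mean_x", data=means.mean_x, track_times=False)
        f.create_dataset("mean_y", data=means.mean_y, track_times=False)
        f.create_dataset("n_contributing", data=means.n_contributing, track_times=False)
        f.attrs["kind"] = "mean_trajectories"


def load_means(path) -> MeanTrajectorySet:
    with h5py.File(path, "r") as f:
        return MeanTrajectorySet(
            labels=_read_labels(f),
            time_grid=f["times"][()],
            mean_x=f["mean_x"][()],
            mean_y=f["mean_y"][()],
            n_contributing=f["n_contributing"][()],
        )


def save_timetime(path, tmap: TimeTimeMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("neural_times", data=tmap.neural_times, track_times=False)
        f.create_dataset("movement_times", data=tmap.movement_times, track_times=False)
        f.create_dataset("values", data=tmap.values, compression="gzip", track_times=False)
        f.attrs["covariates"] = json.dumps(tmap.covariates)
        f.attrs["region"] = tmap.region
        f.attrs["participants"] = json.dumps(tmap.participants)
        f.attrs["kind"] = "timetime_map"


def load_timetime(path) -> TimeTimeMap:
    with h5py.File(path, "r") as f:
        return TimeTimeMap(
            neural_times=f["neural_times"][()],
            movement_times=f["movement_times"][()],
            values=f["values"][()],
            covariates=json.loads(f.attrs.get("covariates", "[]")),
            region=str(f.attrs.get("region", "full")),
            participants=json.loads(f.attrs.get("participants", "[]")),
        )


def rdm_series_to_csv(path, series: RDMSeries) -> None:
    """Flat long-format export: time, label_i, label_j, value (upper
    triangle only)."""
    iu, ju = np.triu_indices(len(series.labels), k=1)
    rows = {
        "time_ms": np.repeat(series.times, iu.size),
        "label_i": np.tile(np.array(series.labels)[iu], series.times.size),
        "label_j": np.tile(np.array(series.labels)[ju], series.times.size),
        "value": series.values[:, iu, ju].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def rdm_from_csv_matrix(path, source: str = "") -> RDM:
    """Read a static RDM stored as a labelled square CSV matrix."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    return RDM(labels, df.to_numpy(dtype=float), source=source)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
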