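"""Result and projection-matrix I/O.

Monitor outputs are written either as HDF5 (one dataset per monitor, with
the sample period and labels as attributes) or as delimited text with the
4-D array flattened to ``time x (svar*space*modes)`` columns.  Projection
(lead-field) matrices are delimited text, sensors x sources, with an
optional ``#``-prefixed header line of sensor labels.
"""

from __future__ import annotations

import json

import numpy as np

from .monitors import ProjectionMatrix, TimeSeriesResult

__all__ = [
    "save_timeseries_h5",
    "load_timeseries_h5",
    "save_timeseries_txt",
    "load_projection_matrix",
    "save_projection_matrix",
]


def save_timeseries_h5(path, results: dict[str, TimeSeriesResult]) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        for name, ts in results.items():
            ds = fh.create_dataset(name, data=ts.data)
            ds.attrs["sample_period_ms"] = ts.sample_period
            ds.attrs["t0_ms"] = ts.t0
            ds.attrs["axes"] = "time,state_variables,space,modes"
            ds.attrs["labels"] = json.dumps(ts.labels, default=str)


def load_timeseries_h5(path) -> dict[str, TimeSeriesResult]:
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        for name, ds in fh.items():
            out[name] = TimeSeriesResult(
                data=ds[()],
                sample_period=float(ds.attrs["sample_period_ms"]),
                t0=float(ds.attrs.get("t0_ms", 0.0)),
                labels=json.loads(ds.attrs.get("labels", "{}")),
            )
    return out


def save_timeseries_txt(path, ts: TimeSeriesResult) -> None:
    t, s, n, m = ts.data.shape
    flat = ts.data.reshape(t, s * n * m)
    header = (
        f"sample_period_ms={ts.sample_period} t0_ms={ts.t0} "
        f"shape={t}x{s}x{n}x{m} axes=time,svar,space,modes"
    )
    np.savetxt(path, flat, header=header)


def save_projection_matrix(path, projection: ProjectionMatrix) -> None:
    header = " ".join(projection.sensor_labels)
    np.savetxt(path, projection.gain, header=header)


def load_projection_matrix(path) -> ProjectionMatrix:
    labels = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        labels = first[1:].split()
    gain = np.loadtxt(path, ndmin=2)
    if labels is not None and len(labels) != gain.shape[0]:
        labels = None  # header was not a label row for these sensors
    return ProjectionMatrix(gain=gain, sensor_labels=labels)
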