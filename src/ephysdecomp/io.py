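"""Trace and table I/O.

Sweep families are stored as HDF5 (one group per sweep with ``signal`` and
``command`` datasets and ``dt_ms``/``mode``/``units``/``group_label``
attributes, plus a JSON-serialized protocol at file level) or, as a plain
text fallback, as one two-column CSV per sweep next to a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .protocol import Epoch, Protocol, Trace

__all__ = [
    "save_traces_h5",
    "load_traces_h5",
    "save_traces_csv",
    "load_traces_csv",
    "write_table",
]


def _protocol_to_json(protocol: Protocol | None) -> str:
    if protocol is None:
        return ""
    d = {
        "mode": protocol.mode,
        "holding": protocol.holding,
        "duration_ms": protocol.duration_ms,
        "epochs": [asdict(e) for e in protocol.epochs],
        "sweep_levels": list(map(float, protocol.sweep_levels)),
        "sample_rate_hz": protocol.sample_rate_hz,
        "inter_sweep_interval_s": protocol.inter_sweep_interval_s,
    }
    return json.dumps(d)


def _protocol_from_json(s: str) -> Protocol | None:
    if not s:
        return None
    d = json.loads(s)
    return Protocol(
        mode=d["mode"],
        holding=d["holding"],
        duration_ms=d["duration_ms"],
        epochs=[Epoch(**e) for e in d["epochs"]],
        sweep_levels=d["sweep_levels"],
        sample_rate_hz=d["sample_rate_hz"],
        inter_sweep_interval_s=d.get("inter_sweep_interval_s", 5.0),
    )


def save_traces_h5(path, traces: list[Trace], group_label: str = "") -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        proto = traces[0].meta.get("protocol") if traces else None
        f.attrs["protocol_json"] = _protocol_to_json(proto)
        f.attrs["group_label"] = group_label
        for i, tr in enumerate(traces):
            g = f.create_group(f"sweep_{i:03d}")
            g.create_dataset("signal", data=tr.signal)
            g.create_dataset("command", data=tr.command)
            g.attrs["dt_ms"] = tr.dt_ms
            g.attrs["mode"] = tr.mode
            g.attrs["units"] = tr.units
            g.attrs["group_label"] = group_label
            if "level" in tr.meta:
                g.attrs["level"] = tr.meta["level"]


def load_traces_h5(path) -> list[Trace]:
    path = Path(path)
    traces: list[Trace] = []
    with h5py.File(path, "r") as f:
        proto = _protocol_from_json(f.attrs.get("protocol_json", ""))
        label = str(f.attrs.get("group_label", ""))
        for name in sorted(k for k in f.keys() if k.startswith("sweep_")):
            g = f[name]
            meta = {"protocol": proto, "group_label": label}
            if "level" in g.attrs:
                meta["level"] = float(g.attrs["level"])
            traces.append(
                Trace(
                    dt_ms=float(g.attrs["dt_ms"]),
                    signal=g["signal"][...],
                    command=g["command"][...],
                    mode=str(g.attrs["mode"]),
                    units=str(g.attrs["units"]),
                    meta=meta,
                )
            )
    return traces


def save_traces_csv(directory, traces: list[Trace], group_label: str = "") -> None:
    """Plain-text fallback: sweep_NNN.csv (signal, command columns) plus
    traces.json with sampling/protocol metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    proto = traces[0].meta.get("protocol") if traces else None
    sidecar = {
        "group_label": group_label,
        "protocol_json": _protocol_to_json(proto),
        "sweeps": [],
    }
    for i, tr in enumerate(traces):
        fname = f"sweep_{i:03d}.csv"
        pd.DataFrame({"signal": tr.signal, "command": tr.command}).to_csv(
            directory / fname, index=False
        )
        sidecar["sweeps"].append(
            {
                "file": fname,
                "dt_ms": tr.dt_ms,
                "mode": tr.mode,
                "units": tr.units,
                "level": tr.meta.get("level"),
            }
        )
    (directory / "traces.json").write_text(json.dumps(sidecar, indent=1))


def load_traces_csv(directory) -> list[Trace]:
    directory = Path(directory)
    sidecar = json.loads((directory / "traces.json").read_text())
    proto = _protocol_from_json(sidecar.get("protocol_json", ""))
    traces = []
    for sw in sidecar["sweeps"]:
        df = pd.read_csv(directory / sw["file"])
        meta = {"protocol": proto, "group_label": sidecar.get("group_label", "")}
        if sw.get("level") is not None:
            meta["level"] = float(sw["level"])
        traces.append(
            Trace(
                dt_ms=float(sw["dt_ms"]),
                signal=df["signal"].to_numpy(float),
                command=df["command"].to_numpy(float),
                mode=sw["mode"],
                units=sw["units"],
                meta=meta,
            )
        )
    return traces


def write_table(df: pd.DataFrame, path) -> None:
    """Write a feature/result table as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
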