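"""Trace containers on disk.

Trace sets go to one HDF5 file with a group per sweep
(``/<phenotype>/<condition>/<frequency>/train<k>``, datasets ``t`` and ``y``,
metadata as attributes) or to per-sweep two-column CSV files; a JSON manifest
records parameters, protocol and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .params import CellModelParams, StimulationProtocol, TraceRecording

__all__ = [
    "write_traces_h5",
    "read_traces_h5",
    "write_trace_csv",
    "read_trace_csv",
    "write_manifest",
]

_ATTRS = ("mode", "condition", "phenotype", "train_index", "cell_id")


def _group_name(tr: TraceRecording) -> str:
    freq = (
        1000.0 / np.diff(tr.stim_times).mean() if tr.stim_times.size > 1 else 0.0
    )
    return f"{tr.phenotype}/{tr.condition}/{freq:g}Hz/{tr.cell_id}/train{tr.train_index}"


def write_traces_h5(path: str | Path, traces: list[TraceRecording]) -> None:
    with h5py.File(path, "w") as f:
        for tr in traces:
            g = f.create_group(_group_name(tr))
            g.create_dataset("t", data=tr.t, compression="gzip")
            g.create_dataset("y", data=tr.y, compression="gzip")
            g.create_dataset("stim_times", data=tr.stim_times)
            for a in _ATTRS:
                g.attrs[a] = getattr(tr, a)
            if tr.holding_potential is not None:
                g.attrs["holding_potential"] = tr.holding_potential


def read_traces_h5(path: str | Path) -> list[TraceRecording]:
    out: list[TraceRecording] = []

    def visit(name, obj):
        if isinstance(obj, h5py.Group) and "t" in obj and "y" in obj:
            out.append(
                TraceRecording(
                    t=obj["t"][...],
                    y=obj["y"][...],
                    stim_times=obj["stim_times"][...] if "stim_times" in obj else np.empty(0),
                    mode=str(obj.attrs["mode"]),
                    condition=str(obj.attrs["condition"]),
                    phenotype=str(obj.attrs["phenotype"]),
                    train_index=int(obj.attrs["train_index"]),
                    holding_potential=(
                        float(obj.attrs["holding_potential"])
                        if "holding_potential" in obj.attrs
                        else None
                    ),
                    cell_id=str(obj.attrs["cell_id"]),
                )
            )

    with h5py.File(path, "r") as f:
        f.visititems(visit)
    return out


def write_trace_csv(path: str | Path, trace: TraceRecording) -> None:
    """Two-column (time_ms, value) CSV for one sweep."""
    pd.DataFrame({"time_ms": trace.t, "value": trace.y}).to_csv(path, index=False)


def read_trace_csv(
    path: str | Path,
    stim_times: np.ndarray,
    mode: str,
    **kwargs,
) -> TraceRecording:
    df = pd.read_csv(path)
    return TraceRecording(
        t=df["time_ms"].to_numpy(),
        y=df["value"].to_numpy(),
        stim_times=np.asarray(stim_times, float),
        mode=mode,
        **kwargs,
    )


def write_manifest(
    path: str | Path,
    params: CellModelParams | list[CellModelParams],
    protocols: StimulationProtocol | list[StimulationProtocol],
    seed: int,
    extra: dict | None = None,
) -> None:
    if isinstance(params, CellModelParams):
        params = [params]
    if isinstance(protocols, StimulationProtocol):
        protocols = [protocols]
    doc = {
        "seed": int(seed),
        "cells": [dataclasses.asdict(p) for p in params],
        "protocols": [dataclasses.asdict(p) for p in protocols],
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=float))
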