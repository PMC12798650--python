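"""Reading and writing: time-series text files, scenario configs, GC tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .neural_mass import Connection, Network, preset
from .preprocess import TimeSeriesSet

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "network_from_config",
    "load_scenario_config",
    "write_gc_matrix",
]


def write_timeseries(ts: TimeSeriesSet, path) -> None:
    """Write a delimited text file: header lines with fs/labels, one column per channel.

    Values are written with 17 significant digits so the round trip is
    lossless at double precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={ts.fs!r}\n")
        if "seed" in ts.meta:
            fh.write(f"# seed={ts.meta['seed']}\n")
        fh.write("\t".join(ts.labels) + "\n")
        np.savetxt(fh, ts.data, fmt="%.17g", delimiter="\t")


def read_timeseries(path) -> TimeSeriesSet:
    path = Path(path)
    fs = None
    meta = {}
    header_rows = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                header_rows += 1
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "fs":
                    fs = float(val)
                elif key.strip() == "seed":
                    meta["seed"] = int(val)
            else:
                labels = tuple(line.strip().split("\t"))
                header_rows += 1
                break
        else:
            raise ValueError(f"{path}: empty time-series file")
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header")
    data = np.loadtxt(path, skiprows=header_rows, delimiter="\t", ndmin=2)
    return TimeSeriesSet(data, fs=fs, labels=labels, meta=meta)


def network_from_config(cfg: dict) -> Network:
    """Build a Network from a parsed config mapping.

    Expected shape::

        rois:
          - rhythm: gamma            # preset name
            m_p: 400                 # optional ROIParams overrides
        connections:
          - {source: 0, target: 1, W: 40, kind: excitatory, delay: 0.010}
    """
    rois = []
    for entry in cfg["rois"]:
        if isinstance(entry, str):
            rois.append(preset(entry))
        else:
            entry = dict(entry)
            rhythm = entry.pop("rhythm")
            rois.append(preset(rhythm, **entry))
    conns = []
    for c in cfg.get("connections", []):
        conns.append(
            Connection(
                source=int(c["source"]), target=int(c["target"]), W=float(c["W"]),
                kind=c.get("kind", "excitatory"), D=float(c.get("delay", 0.010)),
            )
        )
    return Network(rois=tuple(rois), connections=tuple(conns))


def load_scenario_config(path) -> dict:
    """Load a YAML or JSON scenario definition."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def write_gc_matrix(path, matrix: np.ndarray, labels, what: str = "GC") -> None:
    """Labeled CSV of a directed matrix; rows are targets, columns are sources."""
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.index.name = f"{what} target \\ source"
    df.to_csv(path)
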