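"""Delimited-text I/O and run provenance.

Count series, filtered signals, events, directing processes and
waiting-time distributions are exchanged as TSV with a header line and
``#``-prefixed metadata comments.  Every command writes a JSON run
manifest listing inputs, outputs, seeds and the configuration hash, so a
run can be reproduced byte-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import StateTimeSeries
from .events import DirectingProcess
from .labels import StateLabel
from .wtd import ConfidenceBand, WTDResult


def write_series_tsv(series: StateTimeSeries, path: str | Path,
                     metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        if series.config_hash:
            fh.write(f"# config_hash: {series.config_hash}\n")
        fh.write("time_s\t" + "\t".join(series.tokens()) + "\n")
        for t, row in zip(series.times, series.counts):
            fh.write(f"{t:g}\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_series_tsv(path: str | Path) -> StateTimeSeries:
    path = Path(path)
    config_hash = ""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# config_hash:"):
                config_hash = line.split(":", 1)[1].strip()
    frame = pd.read_csv(path, sep="\t", comment="#")
    if "time_s" not in frame.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    labels = tuple(StateLabel.from_token(c) for c in frame.columns[1:])
    return StateTimeSeries(times=frame["time_s"].to_numpy(dtype=float),
                           counts=frame.iloc[:, 1:].to_numpy(),
                           labels=labels, config_hash=config_hash)


def write_events_tsv(dp: DirectingProcess, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("time_s\tamplitude\tkind\n")
        for t, a, k in zip(dp.physical_times, dp.amplitudes, dp.kinds):
            fh.write(f"{t:g}\t{a:g}\t{k}\n")


def write_directing_tsv(dp: DirectingProcess, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tt_phys_s\tsip_s\tamplitude\n")
        sips = np.concatenate([[np.nan], dp.sips])
        for i, (t, s, a) in enumerate(zip(dp.physical_times, sips,
                                          dp.amplitudes)):
            sip = "" if np.isnan(s) else f"{s:g}"
            fh.write(f"{i}\t{t:g}\t{sip}\t{a:g}\n")


def write_wtd_tsv(result: WTDResult, path: str | Path,
                  band: ConfidenceBand | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# epoch: [{result.epoch[0]:g}, {result.epoch[1]:g}]\n")
        fh.write(f"# n_events: {result.n_events}\n")
        cols = "tau_s\tintegral_dist\tpsi"
        if band is not None:
            cols += "\tci_lo\tci_hi"
        fh.write(cols + "\n")
        for k, tau in enumerate(result.tau_grid):
            row = f"{tau:g}\t{result.integral_dist[k]:g}\t{result.psi[k]:g}"
            if band is not None:
                row += f"\t{band.lo[k]:g}\t{band.hi[k]:g}"
            fh.write(row + "\n")


@dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    seeds: list[int]
    config_hash: str = ""
    parameters: dict = field(default_factory=dict)
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    status: str = "ok"
    wall_time_s: float = 0.0

    def write(self, path: str | Path) -> None:
        from . import __version__

        payload = {
            "command": self.command,
            "tool_version": __version__,
            "seeds": self.seeds,
            "config_hash": self.config_hash,
            "parameters": self.parameters,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "status": self.status,
            "wall_time_s": round(self.wall_time_s, 3),
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
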