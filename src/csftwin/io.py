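"""CSV time-series I/O and run manifests.

Waveform files are one cardiac cycle per file: two columns
``time_s,flow_ml_min`` with a mandatory header, comma separator, dot decimal.
The time grid must be uniform (tolerance 1e-6 s) and closed-open: the sample
at t = period is NOT included.  Values are written at ``repr`` precision so a
write/read round trip is bitwise lossless.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .errors import FormatError
from .network import SimulationResult
from .waveforms import SampledWaveform

WAVEFORM_COLUMNS = ["time_s", "flow_ml_min"]
RESULT_COLUMNS = [
    "time_s",
    "icp_mmHg",
    "p_cistern_mmHg",
    "p_cranial_chamber_mmHg",
    "q_spinal_ml_min",
]
_GRID_TOL_S = 1e-6


def read_waveform_csv(path: str | Path) -> SampledWaveform:
    """Read a one-cycle waveform; validates the header and grid uniformity."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != WAVEFORM_COLUMNS:
        raise FormatError(
            f"expected header {','.join(WAVEFORM_COLUMNS)!r}, got {','.join(map(str, df.columns))!r}"
        )
    if len(df) < 2:
        raise FormatError("waveform file needs at least two rows to establish the grid")
    t = df["time_s"].to_numpy(float)
    dt = t[1] - t[0]
    if dt <= 0:
        raise FormatError("time must be strictly increasing", row=1)
    gaps = np.abs(np.diff(t) - dt) > _GRID_TOL_S
    if gaps.any():
        row = int(np.argmax(gaps)) + 1
        raise FormatError(f"non-uniform time grid at row {row}", row=row)
    return SampledWaveform(period=dt * len(df), values=df["flow_ml_min"].to_numpy(float))


def write_waveform_csv(wf: SampledWaveform, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(WAVEFORM_COLUMNS)
        for t, v in zip(wf.times, wf.values):
            writer.writerow([repr(float(t)), repr(float(v))])


def write_result_csv(res: SimulationResult, path: str | Path) -> None:
    """Write a simulation's recorded series with the documented five columns."""
    df = pd.DataFrame(
        {
            "time_s": res.time,
            "icp_mmHg": res.icp,
            "p_cistern_mmHg": res.p_cistern,
            "p_cranial_chamber_mmHg": res.p_cranial_chamber,
            "q_spinal_ml_min": res.q_spinal,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_result_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"result file lacks columns: {', '.join(missing)}")
    return df


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config_snapshot: dict,
    seeds: dict[str, int] | None = None,
    inputs: Iterable[str | Path] = (),
    outputs: Iterable[str | Path] = (),
) -> None:
    """Record everything needed to reproduce a run: configuration, seeds,
    package version and digests of the input files."""
    manifest = {
        "command": command,
        "csftwin_version": __version__,
        "config": config_snapshot,
        "seeds": seeds or {},
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
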