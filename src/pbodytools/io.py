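"""Table and trajectory I/O shared by the CLI stages.

TSV with a header row is the universal table dialect.  Lattice trajectories
use an extended-XYZ text dialect: per frame, a bead count line, a comment
line carrying the step index and total energy, then one ``LABEL x y z`` line
per bead with integer (wrapped) lattice coordinates.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .lattice_mc import BeadType, FrameSummary, LatticeState

_BEAD_LABELS = {BeadType.IDR: "IDR", BeadType.OD: "OD", BeadType.RNA: "RNA"}


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV table, sniffing the delimiter from the extension."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_xyz_frame(fh: IO[str], state: LatticeState, step: int, energy: float) -> None:
    wrapped = state.wrapped_coords
    fh.write(f"{state.n_beads}\n")
    fh.write(f"step={step} energy_kT={energy:.6f} L={state.L}\n")
    for i in range(state.n_beads):
        label = _BEAD_LABELS[BeadType(int(state.btype[i]))]
        fh.write(f"{label} {wrapped[i, 0]} {wrapped[i, 1]} {wrapped[i, 2]}\n")


def read_xyz_frames(path: str | Path) -> list[dict]:
    """Parse an extended-XYZ trajectory back into per-frame dicts."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        meta = dict(kv.split("=") for kv in lines[i + 1].split())
        rows = [ln.split() for ln in lines[i + 2:i + 2 + n]]
        frames.append(
            {
                "step": int(meta["step"]),
                "energy_kT": float(meta["energy_kT"]),
                "L": int(meta["L"]),
                "labels": [r[0] for r in rows],
                "coords": np.array([[int(r[1]), int(r[2]), int(r[3])] for r in rows]),
            }
        )
        i += 2 + n
    return frames


def write_manifest(
    out_dir: str | Path,
    stage: str,
    params: dict,
    seed: int | None,
    inputs: Sequence[str] = (),
    wall_s: float | None = None,
) -> Path:
    """Log a reproducibility manifest beside a stage's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "parameters": params,
        "seed": seed,
        "inputs": list(inputs),
        "software_version": __version__,
        "wall_clock_s": wall_s,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
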