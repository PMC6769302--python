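"""Tabular and JSON output writers.

All floats are written with 12 significant digits so repeated runs of the
same configuration produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np

from .diagnostics import HeatmapGrid, WaveTrack
from .discrete_sim import SomiteRecord
from .profiles import PhaseProfile

__all__ = [
    "fmt",
    "write_profile_csv",
    "write_somites_csv",
    "write_heatmap_csv",
    "write_wave_csv",
    "write_table_csv",
    "write_summary_json",
]


def fmt(value) -> str:
    """Format a number with 12 significant digits (ints verbatim)."""
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if value is None:
        return ""
    return f"{float(value):.12g}"


def _write_rows(path: str | Path, header: list[str], rows: Iterable[Iterable]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(fmt(v) for v in row) + "\n")


def write_profile_csv(profile: PhaseProfile, path: str | Path) -> None:
    psi = profile.psi
    _write_rows(
        path,
        ["x", "phase_rad", "lag_rad"],
        zip(profile.x, profile.phi, psi),
    )


def write_somites_csv(records: Iterable[SomiteRecord], path: str | Path) -> None:
    _write_rows(
        path,
        ["n", "time_min", "cells_removed", "phase_span_rad", "beta", "len_before", "len_after"],
        (
            (r.index, r.time, r.cells_removed, r.phase_span, r.beta, r.len_before, r.len_after)
            for r in records
        ),
    )


def write_heatmap_csv(grid: HeatmapGrid, path: str | Path) -> None:
    frame = grid.to_frame()
    _write_rows(
        path,
        ["lambda", "beta", "phi_before_rad"],
        frame.itertuples(index=False),
    )


def write_wave_csv(track: WaveTrack, path: str | Path) -> None:
    # velocities live on interval midpoints; the last row has no velocity
    vels = list(track.velocities) + [None]
    _write_rows(
        path,
        ["time_min", "x", "velocity"],
        zip(track.times, track.positions, vels),
    )


def write_table_csv(frame, path: str | Path) -> None:
    """Write a pandas DataFrame with the package float convention."""
    _write_rows(path, list(frame.columns), frame.itertuples(index=False))


def write_summary_json(summary: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
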