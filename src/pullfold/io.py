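"""Delimited-text interchange for traces, rupture tables and results.

All tables are UTF-8 tab-separated text with a mandatory header row. A trace
file holds one sample per row (columns ``time_s``, ``lambda_nm``,
``force_pN`` plus metadata columns); long-format files carrying several
cycles are split on (molecule_id, cycle_id, direction). Each simulated trace
file has a ground-truth sidecar with the same stem and suffix ``.truth``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fdc import PullingTrace
from .simulate import FdcTruth

__all__ = [
    "TRACE_COLUMNS",
    "write_trace",
    "read_trace_table",
    "write_truth",
    "read_truth",
    "write_table",
    "write_json",
]

TRACE_COLUMNS = ("time_s", "lambda_nm", "force_pN")
_META_COLUMNS = ("molecule_id", "cycle_id", "direction", "loading_rate_pN_s", "sampling_rate_hz")


def trace_to_frame(trace: PullingTrace) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": trace.time,
            "lambda_nm": trace.lam,
            "force_pN": trace.force,
            "molecule_id": trace.molecule_id,
            "cycle_id": trace.cycle_id,
            "direction": trace.direction,
            "loading_rate_pN_s": trace.loading_rate,
            "sampling_rate_hz": trace.sampling_rate,
        }
    )


def write_trace(
    path: str | Path,
    traces: PullingTrace | list[PullingTrace],
    digest: str | None = None,
) -> Path:
    """Write one or more traces to a single long-format TSV file."""
    if isinstance(traces, PullingTrace):
        traces = [traces]
    frame = pd.concat([trace_to_frame(t) for t in traces], ignore_index=True)
    return write_table(path, frame, digest=digest)


def read_trace_table(path: str | Path) -> list[PullingTrace]:
    """Read a trace file, splitting long format into per-cycle traces.

    Raises a ValueError naming the file and the problem for a missing
    header column or a non-monotone time channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} in header")
    for col, default in (
        ("molecule_id", "mol0"),
        ("cycle_id", 0),
        ("direction", None),
        ("loading_rate_pN_s", np.nan),
        ("sampling_rate_hz", np.nan),
    ):
        if col not in frame.columns:
            frame[col] = default
    traces = []
    for (mol, cyc, direction), grp in frame.groupby(
        ["molecule_id", "cycle_id", "direction"], sort=True, dropna=False
    ):
        t = grp["time_s"].to_numpy(float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2  # +1 header, +1 next row
            raise ValueError(f"{path}: non-monotone time near data line {bad} (cycle {cyc})")
        direction = direction if isinstance(direction, str) else _infer_direction(grp)
        sr = grp["sampling_rate_hz"].iloc[0]
        if not np.isfinite(sr):
            sr = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 1.0
        lr = grp["loading_rate_pN_s"].iloc[0]
        traces.append(
            PullingTrace(
                time=t,
                lam=grp["lambda_nm"].to_numpy(float),
                force=grp["force_pN"].to_numpy(float),
                direction=direction,
                loading_rate=float(lr) if np.isfinite(lr) else _infer_rate(grp, t),
                sampling_rate=float(sr),
                molecule_id=str(mol),
                cycle_id=int(cyc),
            )
        )
    return traces


def _infer_direction(grp: pd.DataFrame) -> str:
    f = grp["force_pN"].to_numpy(float)
    return "unfold" if f[-1] >= f[0] else "fold"


def _infer_rate(grp: pd.DataFrame, t: np.ndarray) -> float:
    f = grp["force_pN"].to_numpy(float)
    span = t[-1] - t[0]
    return abs(f[-1] - f[0]) / span if span > 0 else 1.0


def write_truth(path: str | Path, truths: list[FdcTruth]) -> Path:
    frame = pd.DataFrame(
        {
            "molecule_id": [tr.molecule_id for tr in truths],
            "cycle_id": [tr.cycle_id for tr in truths],
            "direction": [tr.direction for tr in truths],
            "true_force_pN": [tr.true_force for tr in truths],
            "true_index": [tr.true_index for tr in truths],
        }
    )
    return write_table(path, frame)


def read_truth(path: str | Path) -> list[FdcTruth]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        FdcTruth(
            direction=row.direction,
            true_force=float(row.true_force_pN),
            true_index=int(row.true_index),
            cycle_id=int(row.cycle_id),
            molecule_id=str(row.molecule_id),
        )
        for row in frame.itertuples()
    ]


def write_table(path: str | Path, frame: pd.DataFrame, digest: str | None = None) -> Path:
    """Write a TSV table; a config digest, if given, goes in a leading
    comment line so every output is traceable to its configuration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if digest:
            fh.write(f"# config_digest={digest}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
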