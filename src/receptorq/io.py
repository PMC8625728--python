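"""CSV/JSON writers and readers.

All writers are atomic (write to a temporary file in the target directory,
then rename), so a failing command never leaves a partial output behind.
Floats survive a write/read round trip exactly: CSV uses repr-precision
formatting and JSON relies on Python's shortest-round-trip float encoding.
"""
from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .oracle import OracleResult
from .queuesim import QueueSimResult
from .saturation import RateSeries

__all__ = ["write_series", "read_series", "write_hitting_curve",
           "write_summary", "read_summary", "write_sim_result",
           "write_oracle_result", "write_dosing_solution"]

SERIES_COLUMNS = ["t_s", "lambda_o", "lambda_o_prime", "Ao", "Lambda_r",
                  "Lambda_a", "N_r", "N_a", "E_busy"]
HITTING_COLUMNS = ["t_s", "fhit", "rabsorb_per_s", "lambda_o_per_s"]


def _atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _frame_to_csv(frame: pd.DataFrame, path: str | Path) -> None:
    # repr emits the shortest decimal (<= 17 significant digits) that
    # round-trips to the exact same float
    _atomic_write_text(path, frame.to_csv(
        index=False, float_format=lambda x: repr(float(x))))


def write_series(series: RateSeries, path: str | Path) -> None:
    """Rate series as CSV with the fixed column order ``SERIES_COLUMNS``."""
    _frame_to_csv(series.to_frame()[SERIES_COLUMNS], path)


def read_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_hitting_curve(t, fhit, rabsorb, lambda_o, path: str | Path) -> None:
    """Hitting-fraction and absorption-rate curves as CSV."""
    frame = pd.DataFrame(dict(zip(HITTING_COLUMNS, [t, fhit, rabsorb, lambda_o])))
    _frame_to_csv(frame, path)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_summary(summary: Mapping[str, Any] | Any, path: str | Path) -> None:
    """JSON with stable (insertion) key order and lossless floats."""
    _atomic_write_text(path, json.dumps(_jsonable(summary), indent=2) + "\n")


def read_summary(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def write_sim_result(result: QueueSimResult, path: str | Path) -> None:
    """Long-format CSV of the queue-bank counts, one row per (replicate, bin)."""
    frames = []
    for r in range(result.replicates):
        frames.append(pd.DataFrame({
            "t_s": result.time_bins,
            "arrivals": result.arrivals[r],
            "absorptions": result.absorptions[r],
            "rejections": result.rejections[r],
            "n_busy": result.n_busy[r],
            "replicate": r,
        }))
    _frame_to_csv(pd.concat(frames, ignore_index=True), path)


def write_oracle_result(result: OracleResult, path: str | Path) -> None:
    """Empirical hitting-fraction curve with binomial standard errors."""
    frame = pd.DataFrame({"t_s": result.t_grid,
                          "empirical_fhit": result.empirical_fhit,
                          "stderr": result.stderr})
    _frame_to_csv(frame, path)


def write_dosing_solution(solution, path: str | Path) -> None:
    """Dosing solution as JSON mirroring the dataclass fields."""
    write_summary(solution, path)
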