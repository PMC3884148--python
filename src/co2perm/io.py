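"""CSV and YAML I/O.

Traces travel as two-column CSV (``time_s, c18o16o``) with a mandatory
header; metadata (equilibrium value, response time, cell-addition time)
rides in ``# key: value`` comment lines above the header so a trace
round-trips losslessly through a plain text file.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import ConfigError, ParseError
from .o18 import MassSpecTrace

__all__ = ["read_trace", "write_trace", "load_config"]

_META_KEYS = ("equilibrium_value", "response_time", "t_add")


def write_trace(trace: MassSpecTrace, path: str | Path) -> None:
    """Write a trace as CSV with metadata comment lines."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# equilibrium_value: {trace.equilibrium_value!r}\n")
        fh.write(f"# response_time: {trace.response_time!r}\n")
        fh.write(f"# t_add: {trace.t_add!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["time_s", "c18o16o"])
        for t, c in zip(trace.times, trace.c18o16o):
            writer.writerow([repr(float(t)), repr(float(c))])


def read_trace(path: str | Path) -> MassSpecTrace:
    """Read a trace CSV; malformed rows raise :class:`ParseError` with
    the offending line number; non-monotone time is rejected."""
    path = Path(path)
    meta: dict[str, Any] = {"equilibrium_value": 0.0, "response_time": 3.0, "t_add": None}
    times, values = [], []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    if key in _META_KEYS:
                        val = val.strip()
                        meta[key] = None if val in ("None", "") else float(val)
                continue
            cells = [c.strip() for c in line.split(",")]
            if not header_seen:
                if cells[:2] != ["time_s", "c18o16o"]:
                    raise ParseError(
                        f"line {lineno}: expected header 'time_s,c18o16o', got {line!r}",
                        line=lineno,
                    )
                header_seen = True
                continue
            if len(cells) != 2:
                raise ParseError(f"line {lineno}: expected 2 columns, got {len(cells)}",
                                 line=lineno)
            try:
                times.append(float(cells[0]))
                values.append(float(cells[1]))
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric value in {line!r}",
                                 line=lineno)
    if not header_seen:
        raise ParseError("missing header 'time_s,c18o16o'", line=1)
    times_arr = np.asarray(times)
    if len(times_arr) and np.any(np.diff(times_arr) <= 0):
        bad = int(np.nonzero(np.diff(times_arr) <= 0)[0][0])
        raise ParseError(f"time values not strictly increasing near row {bad + 2}")
    return MassSpecTrace(times_arr, np.asarray(values), **meta)


def load_config(path: str | Path, allowed_keys: set[str] | None = None) -> dict:
    """Load a YAML config; unknown top-level keys are rejected."""
    path = Path(path)
    try:
        with path.open() as fh:
            cfg = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}")
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - allowed_keys
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return cfg
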