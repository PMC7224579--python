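"""Delimited-text series I/O, structured-text documents, run manifests.

One strict dialect: comma-separated, '.' decimal, UTF-8, one header row,
a ``time`` column followed by one (1D) or two (2D) value columns on a
uniformly spaced, strictly increasing grid. All writes are atomic
(write-then-rename) so interrupted runs never leave truncated files.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from ._exceptions import ScalesymError

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_json",
    "read_json",
    "file_sha256",
    "RunManifest",
]

#: Maximum tolerated relative jitter of the sampling interval.
MAX_RELATIVE_JITTER = 1e-6


class TimeseriesFormatError(ScalesymError, ValueError):
    """Malformed series file; the message carries the offending line."""


def read_timeseries(path):
    """Read a (time, value[, value2]) series from delimited text.

    Returns ``(times, values)`` with ``values`` of shape (n,) for one value
    column or (n, 2) for two. Raises :class:`TimeseriesFormatError` naming
    the first malformed line, non-monotone times, or irregular spacing
    beyond 1e-6 relative jitter.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as err:
        raise TimeseriesFormatError(f"{path}: cannot parse as delimited text: {err}") from err
    if frame.shape[1] not in (2, 3):
        raise TimeseriesFormatError(
            f"{path}: expected 2 or 3 columns, found {frame.shape[1]}"
        )
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            nonnum = (bad | frame[col].isna()).to_numpy().nonzero()[0][0]
            # +2: one for the header row, one for 1-based line numbering
            raise TimeseriesFormatError(
                f"{path}: non-numeric or missing value in column {col!r} at line {nonnum + 2}"
            )
    data = frame.to_numpy(dtype=float)
    times = data[:, 0]
    if len(times) < 2:
        raise TimeseriesFormatError(f"{path}: need at least 2 samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        i = int(np.argmax(steps <= 0))
        raise TimeseriesFormatError(
            f"{path}: times not strictly increasing at line {i + 3}"
        )
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > MAX_RELATIVE_JITTER * dt:
        raise TimeseriesFormatError(
            f"{path}: irregular sampling (relative jitter exceeds {MAX_RELATIVE_JITTER})"
        )
    values = data[:, 1] if data.shape[1] == 2 else data[:, 1:3]
    return times, values


def _atomic_write_text(path, text: str) -> None:
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix="~")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_timeseries(path, times, values, value_names=("y",)) -> None:
    """Write a series in the package dialect (atomically, full precision)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    cols = {"time": times}
    if values.ndim == 1:
        cols[value_names[0]] = values
    else:
        names = value_names if len(value_names) == values.shape[1] else ("x", "y")
        for j, nm in enumerate(names):
            cols[nm] = values[:, j]
    frame = pd.DataFrame(cols)
    _atomic_write_text(path, frame.to_csv(index=False, float_format="%.17g"))


def write_json(path, obj) -> None:
    _atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per CLI run.

    Stores the command, the full configuration snapshot and seed(s), and
    content hashes of every input and output file, so a run can be
    reproduced bit-identically by re-invoking the command recorded here.
    """

    command: str
    config: dict
    seed: int | None = None
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""
    version: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.version:
            from . import __version__

            self.version = __version__

    def record_input(self, path) -> None:
        self.inputs[os.fspath(path)] = file_sha256(path)

    def record_output(self, path) -> None:
        self.outputs[os.fspath(path)] = file_sha256(path)

    def write(self, path) -> None:
        write_json(
            path,
            {
                "command": self.command,
                "config": self.config,
                "seed": self.seed,
                "inputs": self.inputs,
                "outputs": self.outputs,
                "timestamp": self.timestamp,
                "version": self.version,
            },
        )

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = read_json(path)
        return cls(
            command=d["command"],
            config=d["config"],
            seed=d.get("seed"),
            inputs=d.get("inputs", {}),
            outputs=d.get("outputs", {}),
            timestamp=d.get("timestamp", ""),
            version=d.get("version", ""),
        )
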