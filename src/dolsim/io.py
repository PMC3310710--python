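"""Delimited-text writers for run outputs.

Everything is tab-separated with a header row so any spreadsheet or
plotting tool can consume it.  A writer holds a lockfile next to its
output path for its whole lifetime; a second writer on the same path
fails loudly instead of silently interleaving rows.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

GENERATION_COLUMNS = ["generation", "colony", "A1", "A2", "p1", "D", "F", "F_rel"]


class LogLockedError(RuntimeError):
    """Another writer already owns this log file."""


class GenerationLogWriter:
    """Append-safe TSV writer with a stable column order.

    Usage::

        with GenerationLogWriter(path) as w:
            w.append(records)           # list of dicts or a DataFrame
    """

    def __init__(self, path, columns=None):
        self.path = Path(path)
        self.columns = list(columns) if columns is not None else None
        self._lock = self.path.with_suffix(self.path.suffix + ".lock")
        self._fd = None
        self._wrote_header = False

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        try:
            self._fd = os.open(self._lock, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
        except FileExistsError:
            raise LogLockedError(f"{self.path} is locked by another writer "
                                 f"({self._lock} exists)") from None
        self.path.write_text("")
        return self

    def append(self, records):
        frame = pd.DataFrame(records)
        if self.columns is None:
            self.columns = list(frame.columns)
        if frame.empty:
            frame = pd.DataFrame(columns=self.columns)
        else:
            missing = set(self.columns) - set(frame.columns)
            if missing:
                raise ValueError(f"records missing columns: {sorted(missing)}")
            frame = frame[self.columns]
        with open(self.path, "a") as fh:
            frame.to_csv(fh, sep="\t", index=False, header=not self._wrote_header)
        self._wrote_header = True

    def close(self):
        if self._fd is not None:
            os.close(self._fd)
            self._fd = None
            self._lock.unlink(missing_ok=True)
        if not self._wrote_header and self.columns is not None:
            # contract: an opened-and-closed writer leaves a header-only file
            self.path.write_text("\t".join(self.columns) + "\n")

    def __exit__(self, exc_type, exc, tb):
        self.close()


def write_generation_log(records, path, columns=None) -> Path:
    """One-shot write of per-generation colony records to a TSV file."""
    cols = columns if columns is not None else (
        GENERATION_COLUMNS if _has_generation_schema(records) else None)
    with GenerationLogWriter(path, columns=cols) as w:
        w.append(records)
    return Path(path)


def _has_generation_schema(records) -> bool:
    frame = pd.DataFrame(records)
    return frame.empty or set(GENERATION_COLUMNS).issubset(frame.columns)


def write_table(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_response_map(labels: np.ndarray, s1_grid, s2_grid, path) -> Path:
    """Response-map grid as long-form TSV (s1, s2, label)."""
    from .network import MAP_LABELS
    s1_grid = np.asarray(s1_grid)
    s2_grid = np.asarray(s2_grid)
    rows = [{"s1": s1_grid[i], "s2": s2_grid[j],
             "label": MAP_LABELS[int(labels[i, j])]}
            for i in range(s1_grid.size) for j in range(s2_grid.size)]
    return write_table(pd.DataFrame(rows), path)
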