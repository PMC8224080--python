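"""Multivariate time-series containers and lag embedding.

Every information measure handled by this package — conditional mutual
information (CMI), directed information rate (DIR), causally conditioned
DIR, and transfer entropy (TE) — reduces, for stationary Markov sources,
to a single CMI ``I(X; Y | Z)`` evaluated on lag-windowed blocks of the
raw processes.  This module holds the raw-data container
(:class:`TimeSeriesDataset`), the embedded triple container
(:class:`EmbeddedCMIDataset`) and the two embeddings that produce it.

Conventions
-----------
* Time index is 0-based internally; windows are inclusive ranges.
* Within a window, blocks are laid out time-major then dimension-major:
  the window ``(t, ..., t+l)`` of a ``d``-dimensional process flattens to
  ``(v_t[0..d-1], v_{t+1}[0..d-1], ..., v_{t+l}[0..d-1])``.
* In the conditioning block the target's own history comes first,
  followed by each extra conditioning process in declared order.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesDataset",
    "EmbeddedCMIDataset",
    "load_dataset",
    "save_dataset",
    "embed_for_cmi",
    "embed_for_te",
]

_HEADER_RE = re.compile(r"^(?P<name>.+)_(?P<dim>\d+)$")


@dataclass
class TimeSeriesDataset:
    """Named stationary processes sampled on a common time grid.

    Parameters
    ----------
    processes
        Ordered mapping from process name to a time-major real matrix of
        shape ``(n, d_proc)``.
    meta
        Free-form provenance (seed, generating model, burn-in, ...).
    """

    processes: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.processes:
            raise ValueError("dataset must contain at least one process")
        procs: dict[str, np.ndarray] = {}
        n = None
        for name, mat in self.processes.items():
            arr = np.asarray(mat, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.ndim != 2:
                raise ValueError(f"process {name!r} must be a 2-D time-major matrix")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError(
                    f"process {name!r} has {arr.shape[0]} rows, expected {n}"
                )
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr))[0]
                raise ValueError(
                    f"process {name!r} has a non-finite value at time step {bad[0]}"
                )
            procs[name] = arr
        if n is None or n < 2:
            raise ValueError("dataset needs at least 2 time steps")
        self.processes = procs

    @property
    def n(self) -> int:
        """Number of time steps."""
        return next(iter(self.processes.values())).shape[0]

    @property
    def names(self) -> list[str]:
        return list(self.processes)

    def dim(self, name: str) -> int:
        return self.processes[name].shape[1]

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.processes[name]
        except KeyError:
            raise KeyError(
                f"unknown process {name!r}; available: {self.names}"
            ) from None


@dataclass
class EmbeddedCMIDataset:
    """Lag-windowed (x, y, z) triples on which batching operates.

    ``x_block``, ``y_block`` and ``z_block`` are ``(n_e, D)`` matrices with
    a common row count; row ``r`` corresponds to raw time step
    ``base_index[r]`` (the earliest step the row uses).  ``order`` records
    the Markov order / memory length used to build the embedding.
    """

    x_block: np.ndarray
    y_block: np.ndarray
    z_block: np.ndarray
    base_index: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.x_block = np.atleast_2d(np.asarray(self.x_block, dtype=float))
        self.y_block = np.atleast_2d(np.asarray(self.y_block, dtype=float))
        self.z_block = np.asarray(self.z_block, dtype=float)
        if self.z_block.ndim == 1:
            self.z_block = self.z_block[:, None]
        self.base_index = np.asarray(self.base_index, dtype=np.int64)
        n_e = self.x_block.shape[0]
        if self.y_block.shape[0] != n_e or self.z_block.shape[0] != n_e:
            raise ValueError("x, y and z blocks must share a row count")
        if self.base_index.shape != (n_e,):
            raise ValueError("base_index length must equal the row count")
        if n_e > 1 and not np.all(np.diff(self.base_index) > 0):
            raise ValueError("base_index must be strictly increasing")

    @property
    def n_e(self) -> int:
        return self.x_block.shape[0]

    @property
    def dims(self) -> tuple[int, int, int]:
        """(D_x, D_y, D_z) block widths."""
        return (
            self.x_block.shape[1],
            self.y_block.shape[1],
            self.z_block.shape[1],
        )


def load_dataset(path_or_buffer, *, sep: str | None = None) -> TimeSeriesDataset:
    """Read a delimited numeric table into a :class:`TimeSeriesDataset`.

    The header row is mandatory; each column is named ``<Process>_<dim>``
    and columns are grouped by process, dimensions ordered by their index.
    Comma- and tab-delimited files (optionally gzip-compressed) are
    accepted; the delimiter is sniffed from the header when not given.
    """
    header_line = _peek_header(path_or_buffer)
    if sep is None:
        sep = "\t" if "\t" in header_line else ","
    raw_cells = [c.strip() for c in header_line.rstrip("\n").split(sep)]
    dupes = {c for c in raw_cells if raw_cells.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicate header cell(s): {sorted(dupes)}")
    try:
        frame = pd.read_csv(path_or_buffer, sep=sep)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed table: {exc}") from exc

    groups: dict[str, dict[int, np.ndarray]] = {}
    for col in frame.columns:
        m = _HEADER_RE.match(str(col).strip())
        if m is None:
            raise ValueError(
                f"header cell {col!r} does not follow the <Process>_<dim> pattern"
            )
        name, dim = m.group("name"), int(m.group("dim"))
        values = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            raise ValueError(
                f"non-numeric or non-finite value in column {col!r}, "
                f"data row {bad[0]}"
            )
        per = groups.setdefault(name, {})
        if dim in per:
            raise ValueError(f"duplicate header for process {name!r} dimension {dim}")
        per[dim] = values

    processes = {
        name: np.column_stack([dims[i] for i in sorted(dims)])
        for name, dims in groups.items()
    }
    return TimeSeriesDataset(processes)


def save_dataset(data: TimeSeriesDataset, path, *, sep: str = ",") -> None:
    """Write a dataset as a delimited table with ``<Process>_<dim>`` headers."""
    cols: dict[str, np.ndarray] = {}
    for name, mat in data.processes.items():
        for j in range(mat.shape[1]):
            cols[f"{name}_{j}"] = mat[:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def _peek_header(path_or_buffer) -> str:
    """First line of the table, without consuming a seekable buffer."""
    if isinstance(path_or_buffer, (str, os.PathLike)):
        import gzip

        opener = gzip.open if str(path_or_buffer).endswith(".gz") else open
        with opener(path_or_buffer, "rt") as fh:
            return fh.readline()
    if isinstance(path_or_buffer, io.TextIOBase):
        pos = path_or_buffer.tell()
        header = path_or_buffer.readline()
        path_or_buffer.seek(pos)
        return header
    return ""


def _window(mat: np.ndarray, start: int, stop: int, n_e: int) -> np.ndarray:
    """Stack mat[t+start : t+stop+1] for t = 0..n_e-1, time-major flattened."""
    if stop < start:
        return np.empty((n_e, 0))
    return np.hstack([mat[t0 : t0 + n_e] for t0 in range(start, stop + 1)])


def embed_for_cmi(
    data: TimeSeriesDataset,
    source: str,
    target: str,
    extra_condition: Sequence[str] = (),
    order: int = 1,
) -> EmbeddedCMIDataset:
    """Lag-embed processes into the CMI triple behind DIR estimation.

    For Markov order ``l``, row ``t`` (``t = 0 .. n-l-1``) holds

    * ``x`` = source window ``(t, ..., t+l)``,
    * ``y`` = target at ``t+l``,
    * ``z`` = target history ``(t, ..., t+l-1)`` followed by each extra
      conditioning process's window ``(t, ..., t+l)``.

    CMI on the result estimates the DIR ``I(source -> target)`` (pairwise
    when ``extra_condition`` is empty, causally conditioned otherwise)
    provided ``order`` is at least the maximum Markov order of the
    processes.  With ``order=0`` and one extra process the rows reduce to
    instantaneous triples ``(X_i, Y_i, Z_i)``.
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    if order >= data.n:
        raise ValueError(f"order {order} must be smaller than n = {data.n}")
    src, tgt = data[source], data[target]
    extras = [data[name] for name in extra_condition]
    n_e = data.n - order
    x = _window(src, 0, order, n_e)
    y = tgt[order : order + n_e]
    z_parts = [_window(tgt, 0, order - 1, n_e)]
    z_parts += [_window(e, 0, order, n_e) for e in extras]
    z = np.hstack(z_parts)
    return EmbeddedCMIDataset(x, y, z, np.arange(n_e), order)


def embed_for_te(
    data: TimeSeriesDataset,
    source: str,
    target: str,
    J: int,
    L: int,
) -> EmbeddedCMIDataset:
    """Lag-embed for transfer entropy ``T_{source -> target}``.

    Rows realize ``(X_{i-J}^{i-1}; Y_i; Y_{i-L}^{i-1})`` for all
    admissible ``i``: the source's previous ``J`` steps against the
    target's present, conditioned on the target's previous ``L`` steps.
    CMI on the result estimates the stationary transfer entropy.
    """
    if J < 1 or L < 1:
        raise ValueError("memory lengths J and L must be positive")
    m = max(J, L)
    if m >= data.n:
        raise ValueError(f"max(J, L) = {m} must be smaller than n = {data.n}")
    src, tgt = data[source], data[target]
    n_e = data.n - m
    # row r corresponds to present time i = m + r; earliest step used is r.
    x = _window(src, m - J, m - 1, n_e)
    y = tgt[m : m + n_e]
    z = _window(tgt, m - L, m - 1, n_e)
    return EmbeddedCMIDataset(x, y, z, np.arange(n_e), m)
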