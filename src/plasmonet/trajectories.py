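"""Per-cell state trajectories.

A trajectory is the ordered sequence of discretized gene-expression
states (cluster IDs) a single plasmodial cell passes through on a
uniform 1 h sampling grid.  Tables of trajectories are the interface
between the clustering stage and Petri-net construction, and are
serialized as plain TSV with one row per cell::

    experiment  condition  cell  t0  t1 ... tK

Lines starting with ``#`` are comments.  Time is implicit in column
order at fixed 1 h spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .errors import ArgumentError, DataError, ParseError

__all__ = [
    "TrajectoryRow",
    "TrajectoryTable",
    "assign_trajectories",
    "read_trajectory_table",
    "write_trajectory_table",
]

CONDITIONS = ("dark", "far_red")


@dataclass(frozen=True)
class TrajectoryRow:
    cell: str
    experiment: str
    condition: str
    states: tuple[int, ...]


@dataclass
class TrajectoryTable:
    """Ordered state sequences of a set of cells on a shared time grid."""

    rows: list[TrajectoryRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r.states) for r in self.rows}
        if len(lengths) > 1:
            raise DataError(f"ragged trajectory table: lengths {sorted(lengths)}")
        keys = [(r.experiment, r.cell) for r in self.rows]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise DataError(f"duplicate (experiment, cell) keys: {dup}")
        for r in self.rows:
            if any(s <= 0 for s in r.states):
                raise DataError(f"non-positive state in trajectory of {r.cell}")

    # -- basic views ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def n_timepoints(self) -> int:
        return len(self.rows[0].states) if self.rows else 0

    @property
    def cells(self) -> list[str]:
        return [r.cell for r in self.rows]

    def __iter__(self) -> Iterator[TrajectoryRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrajectoryTable):
            return NotImplemented
        return self.rows == other.rows

    def row(self, cell: str) -> TrajectoryRow:
        for r in self.rows:
            if r.cell == cell:
                return r
        raise KeyError(cell)

    def states(self) -> set[int]:
        out: set[int] = set()
        for r in self.rows:
            out.update(r.states)
        return out

    def subset(
        self,
        cells: Sequence[str] | None = None,
        condition: str | None = None,
        experiment: str | None = None,
    ) -> "TrajectoryTable":
        rows = self.rows
        if cells is not None:
            wanted = set(cells)
            rows = [r for r in rows if r.cell in wanted]
        if condition is not None:
            rows = [r for r in rows if r.condition == condition]
        if experiment is not None:
            rows = [r for r in rows if r.experiment == experiment]
        return TrajectoryTable(list(rows))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"t{i}" for i in range(self.n_timepoints)]
        data = [
            [r.experiment, r.condition, r.cell, *r.states] for r in self.rows
        ]
        return pd.DataFrame(data, columns=["experiment", "condition", "cell", *cols])


def assign_trajectories(
    labels: Mapping[tuple[str, int], int],
    metadata: Mapping[str, tuple[str, str]],
) -> TrajectoryTable:
    """Assemble per-cell state sequences from cluster labels.

    Parameters
    ----------
    labels
        Map ``(cell, time_h) -> cluster_id`` covering every cell and
        time point of the design.
    metadata
        Map ``cell -> (experiment, condition)``.

    The time grid is taken as the sorted set of hours present in
    ``labels``; every cell must be labelled at every hour.
    """
    cells = sorted({c for c, _ in labels}, key=_natural_cell_key)
    hours = sorted({t for _, t in labels})
    rows = []
    gaps = [
        (c, t) for c in cells for t in hours if (c, t) not in labels
    ]
    if gaps:
        raise DataError(f"missing cluster labels for cell-timepoints: {gaps[:10]}")
    for cell in cells:
        if cell not in metadata:
            raise DataError(f"no experiment/condition metadata for cell {cell!r}")
        experiment, condition = metadata[cell]
        states = tuple(int(labels[(cell, t)]) for t in hours)
        rows.append(TrajectoryRow(cell, str(experiment), condition, states))
    return TrajectoryTable(rows)


def _natural_cell_key(cell: str):
    # sorts P2 before P10
    head = cell.rstrip("0123456789")
    tail = cell[len(head):]
    return (head, int(tail) if tail else -1)


def write_trajectory_table(table: TrajectoryTable, path: str | Path) -> None:
    path = Path(path)
    cols = "\t".join(f"t{i}" for i in range(table.n_timepoints))
    lines = [f"experiment\tcondition\tcell\t{cols}"]
    for r in table.rows:
        states = "\t".join(str(s) for s in r.states)
        lines.append(f"{r.experiment}\t{r.condition}\t{r.cell}\t{states}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trajectory_table(path: str | Path) -> TrajectoryTable:
    path = Path(path)
    rows: list[TrajectoryRow] = []
    header: list[str] | None = None
    n_states: int | None = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header[:3] != ["experiment", "condition", "cell"]:
                raise ParseError(
                    "header must start with 'experiment\tcondition\tcell'", lineno
                )
            expected = [f"t{i}" for i in range(len(header) - 3)]
            if header[3:] != expected:
                raise ParseError(
                    f"time columns must be t0..t{len(header) - 4}, got {header[3:]}",
                    lineno,
                )
            n_states = len(header) - 3
            continue
        if len(fields) != 3 + (n_states or 0):
            raise ParseError(
                f"expected {3 + (n_states or 0)} fields, got {len(fields)}", lineno
            )
        experiment, condition, cell = fields[:3]
        if condition not in CONDITIONS:
            raise ParseError(f"unknown condition {condition!r}", lineno)
        try:
            states = tuple(int(s) for s in fields[3:])
        except ValueError as exc:
            raise ParseError(f"non-integer state: {exc}", lineno) from None
        rows.append(TrajectoryRow(cell, experiment, condition, states))
    if header is None:
        raise ParseError("empty trajectory file")
    return TrajectoryTable(rows)


def validate_against_design(table: TrajectoryTable, n_timepoints: int) -> None:
    """Raise if the table does not match the expected time-grid length."""
    if n_timepoints < 1:
        raise ArgumentError("n_timepoints must be >= 1")
    if table.n_timepoints != n_timepoints:
        raise ParseError(
            f"table has {table.n_timepoints} time columns, design requires "
            f"{n_timepoints}"
        )
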