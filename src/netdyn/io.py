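"""Network and data file parsing with automatic format detection.

Supported dialects
------------------
* two-column edge list ("A interacts-with B", one pair per row)
* square 0/1 adjacency matrix with row and column labels
* Cytoscape SIF: three whitespace/tab-separated tokens (source relation target)
* dynamic edge list: long format with a frame-label column (source, target, frame)
* expression table: first column node id, remaining columns ordered frames

All text I/O is UTF-8 with Unix newlines.  The delimiter is sniffed by
trying tab, comma, semicolon, then any whitespace; the first candidate
yielding consistent multi-token column counts wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import DEFAULT_FRAME, TemporalNetwork, ExpressionSeries

__all__ = [
    "ParseError",
    "UnsupportedFormatError",
    "RawTable",
    "NetworkFormat",
    "EdgeRecord",
    "load_raw",
    "detect_format",
    "read_network",
    "read_expression",
    "read_dynamic_edges",
    "write_network",
    "write_expression",
]

logger = logging.getLogger(__name__)

#: default relation token written to SIF files when none was recorded
DEFAULT_RELATION = "interacts"

#: header tokens that mark the third column of a table as a frame label
FRAME_HEADER_HINTS = {"frame", "time", "timepoint", "dose", "day", "condition"}


class ParseError(ValueError):
    """A file could not be tokenized into a consistent table."""


class UnsupportedFormatError(ValueError):
    """A file's format is unknown or unsupported for the requested operation."""


class NetworkFormat(Enum):
    EDGE_LIST = "edge_list"
    ADJACENCY_MATRIX = "adjacency_matrix"
    SIF = "sif"
    DYNAMIC_EDGE_LIST = "dynamic_edge_list"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class EdgeRecord:
    """One parsed interaction row."""

    source: str
    target: str
    relation: str | None = None
    frame: str | None = None

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("edge endpoints must be non-empty")


@dataclass
class RawTable:
    """Tokenized file contents prior to format interpretation."""

    rows: list[list[str]]
    delimiter: str  # "\t", ",", ";" or "" for any-whitespace
    has_header: bool = False

    @property
    def body(self) -> list[list[str]]:
        return self.rows[1:] if self.has_header else self.rows


def _split(line: str, delimiter: str) -> list[str]:
    if delimiter == "":
        return line.split()
    return [token.strip() for token in line.split(delimiter)]


def load_raw(path: str | Path, *, has_header: bool = False) -> RawTable:
    """Read and tokenize a delimited text file.

    Raises
    ------
    ParseError
        If the file is empty, no delimiter yields multi-column rows, or the
        rows are ragged (inconsistent column counts).  The adjacency-matrix
        corner convention — a header row one token shorter than the body —
        is tolerated.
    """
    path = Path(path)
    lines = [
        line for line in path.read_text(encoding="utf-8").splitlines() if line.strip()
    ]
    if not lines:
        raise ParseError(f"{path}: file is empty")

    for delimiter in ("\t", ",", ";", ""):
        rows = [_split(line, delimiter) for line in lines]
        counts = [len(row) for row in rows]
        if max(counts) < 2:
            continue
        body_counts = counts[1:] if len(counts) > 1 else counts
        uniform = len(set(counts)) == 1
        corner = (
            len(counts) > 1
            and len(set(body_counts)) == 1
            and counts[0] == body_counts[0] - 1
        )
        if uniform or corner:
            if corner:
                rows[0].insert(0, "")
            rows = [[token.strip() for token in row] for row in rows]
            return RawTable(rows=rows, delimiter=delimiter, has_header=has_header)

    # no candidate was consistent: report the first ragged line for the
    # best candidate (the one splitting into the most columns)
    best = max(("\t", ",", ";", ""), key=lambda d: max(len(_split(l, d)) for l in lines))
    rows = [_split(line, best) for line in lines]
    expected = len(rows[0])
    for lineno, row in enumerate(rows, start=1):
        if len(row) != expected:
            raise ParseError(
                f"{path}: inconsistent column count at line {lineno} "
                f"(expected {expected}, found {len(row)})"
            )
    raise ParseError(f"{path}: could not determine a delimiter")


def _is_adjacency(raw: RawTable) -> bool:
    """Square grid whose body cells are all 0/1, with row+column labels."""
    if len(raw.rows) < 2:
        return False
    header, body = raw.rows[0], raw.rows[1:]
    width = len(body[0])
    if any(len(row) != width for row in body) or width < 2:
        return False
    if len(header) != width:
        return False
    if len(body) != width - 1:  # square: n row labels x n column labels
        return False
    return all(cell in ("0", "1") for row in body for cell in row[1:])


def detect_format(
    raw: RawTable,
    *,
    extension: str | None = None,
    frame_labels: Sequence[str] | None = None,
) -> NetworkFormat:
    """Classify a tokenized file into one of the supported network dialects.

    The decision is deterministic and total: every input maps to exactly
    one format, with :attr:`NetworkFormat.UNKNOWN` for anything ambiguous
    (never a silent guess).  Optional hints sharpen the three-column case,
    which is ambiguous between SIF (middle column = relation vocabulary)
    and a dynamic edge list (third column = frame label): a ``.sif``
    extension, a configured frame-label set, or a header naming the third
    column (frame/time/dose/...) decide it; otherwise the column with the
    small repeating vocabulary does.
    """
    if not raw.rows:
        raise ParseError("empty table")

    if _is_adjacency(raw):
        return NetworkFormat.ADJACENCY_MATRIX

    body = raw.body
    if not body:
        return NetworkFormat.UNKNOWN
    widths = {len(row) for row in body}
    if widths == {2}:
        return NetworkFormat.EDGE_LIST
    if len(widths) != 1:
        return NetworkFormat.UNKNOWN
    width = widths.pop()
    if width < 3:
        return NetworkFormat.UNKNOWN

    third = [row[2] for row in body]
    if extension and extension.lower().lstrip(".") == "sif" and width == 3:
        return NetworkFormat.SIF
    if frame_labels is not None and set(third) <= set(frame_labels):
        return NetworkFormat.DYNAMIC_EDGE_LIST
    if raw.has_header and raw.rows[0][2].lower() in FRAME_HEADER_HINTS:
        return NetworkFormat.DYNAMIC_EDGE_LIST

    small = max(1, math.ceil(len(body) / 2))
    n_third = len(set(third))
    if width > 3:
        return (
            NetworkFormat.DYNAMIC_EDGE_LIST
            if n_third <= small
            else NetworkFormat.UNKNOWN
        )
    n_middle = len({row[1] for row in body})
    if n_third < n_middle and n_third <= small:
        return NetworkFormat.DYNAMIC_EDGE_LIST
    if n_middle < n_third and n_middle <= small:
        return NetworkFormat.SIF
    return NetworkFormat.UNKNOWN


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------
def read_network(
    path: str | Path,
    format: NetworkFormat | str = "auto",
    *,
    directed: bool = True,
    has_header: bool = False,
    frame: str = DEFAULT_FRAME,
) -> TemporalNetwork:
    """Parse a static network file into a single-frame temporal network.

    Node set is the union of edge endpoints (for an adjacency matrix, the
    row/column labels); duplicate edges collapse; self-loops are kept.
    """
    path = Path(path)
    raw = load_raw(path, has_header=has_header)
    if format == "auto" or format is None:
        format = detect_format(raw, extension=path.suffix)
    elif isinstance(format, str):
        format = NetworkFormat(format)

    if format is NetworkFormat.EDGE_LIST:
        records = [EdgeRecord(row[0], row[1]) for row in raw.body]
        net = TemporalNetwork.from_edges(
            [(r.source, r.target) for r in records], directed=directed, frame=frame
        )
    elif format is NetworkFormat.SIF:
        records = [EdgeRecord(row[0], row[2], relation=row[1]) for row in raw.body]
        net = TemporalNetwork.from_edges(
            [(r.source, r.target, r.relation) for r in records],
            directed=directed,
            frame=frame,
        )
    elif format is NetworkFormat.ADJACENCY_MATRIX:
        header, body = raw.rows[0], raw.rows[1:]
        col_labels = header[1:]
        edges: list[tuple[str, str]] = []
        nodes: dict[str, None] = {}
        for row in body:
            nodes.setdefault(row[0])
        for label in col_labels:
            nodes.setdefault(label)
        for row in body:
            row_label = row[0]
            for col_label, cell in zip(col_labels, row[1:]):
                if cell not in ("0", "1"):
                    raise ValueError(
                        f"{path}: adjacency cell for ({row_label}, {col_label}) "
                        f"is {cell!r}, expected 0 or 1"
                    )
                if cell == "1":
                    edges.append((row_label, col_label))
        net = TemporalNetwork.from_edges(
            edges, directed=directed, frame=frame, nodes=list(nodes)
        )
    elif format is NetworkFormat.DYNAMIC_EDGE_LIST:
        raise UnsupportedFormatError(
            f"{path}: dynamic edge list detected; use read_dynamic_edges()"
        )
    else:
        raise UnsupportedFormatError(f"{path}: unrecognized network format")

    logger.info(
        "read %s: %d nodes, %d edges (%s)",
        path.name,
        len(net.nodes),
        net.n_edges(frame),
        format.value,
    )
    return net


def read_dynamic_edges(
    path: str | Path,
    *,
    directed: bool = True,
    has_header: bool = False,
    frame_order: list[str] | None = None,
) -> TemporalNetwork:
    """Parse a long-format dynamic edge file (source, target, frame label).

    Frame order is first-appearance order unless ``frame_order`` overrides
    it; the override must cover every label present in the file.
    """
    path = Path(path)
    raw = load_raw(path, has_header=has_header)
    body = raw.body
    if any(len(row) < 3 for row in body):
        raise UnsupportedFormatError(
            f"{path}: dynamic edge files need >= 3 columns (source, target, frame)"
        )
    frame_edges: dict[str, list[tuple[str, str]]] = {}
    for row in body:
        frame_edges.setdefault(row[2], []).append((row[0], row[1]))
    if frame_order is not None:
        missing = set(frame_edges) - set(frame_order)
        if missing:
            raise ValueError(
                f"{path}: frame order omits labels found in file: {sorted(missing)}"
            )
        frames = list(frame_order)
    else:
        frames = list(frame_edges)
    net = TemporalNetwork.from_frame_edges(
        frame_edges, directed=directed, frame_order=frames
    )
    logger.info(
        "read %s: %d nodes over %d frames", path.name, len(net.nodes), len(frames)
    )
    return net


def read_expression(path: str | Path) -> ExpressionSeries:
    """Parse an expression table: first column node ids, header row gives
    the ordered frame labels.  Empty cells are recorded as missing."""
    path = Path(path)
    raw = load_raw(path, has_header=True)
    header, body = raw.rows[0], raw.rows[1:]
    if not body:
        raise ParseError(f"{path}: expression table has no data rows")
    frames = header[1:]
    ids = [row[0] for row in body]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"{path}: duplicated node id(s): {sorted(dup)}")
    data: dict[str, list[float]] = {}
    for row_number, row in enumerate(body, start=2):
        values: list[float] = []
        for frame, cell in zip(frames, row[1:]):
            if cell == "" or cell.upper() in ("NA", "NAN"):
                values.append(float("nan"))
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {row_number}, "
                    f"column {frame!r}"
                ) from None
        data[row[0]] = values
    table = pd.DataFrame.from_dict(data, orient="index", columns=frames)
    return ExpressionSeries(table)


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------
def _frame_for_static_write(
    net: TemporalNetwork, frame: str | None, format: NetworkFormat
) -> str:
    if frame is not None:
        if frame not in net.frames:
            raise KeyError(f"unknown frame {frame!r}")
        return frame
    if net.is_static:
        return net.frames[0]
    raise ValueError(
        f"network has {len(net.frames)} frames; select one to write as "
        f"{format.value} or use DYNAMIC_EDGE_LIST"
    )


def write_network(
    net: TemporalNetwork,
    path: str | Path,
    format: NetworkFormat | str,
    *,
    frame: str | None = None,
) -> Path:
    """Write a network as edge-list TSV, SIF, or dynamic edge TSV.

    Round-trip guarantee: reading the written file back reproduces the node
    set (modulo isolated nodes, which text edge formats cannot carry) and
    the per-frame edge sets exactly.
    """
    path = Path(path)
    if isinstance(format, str):
        format = NetworkFormat(format)
    lines: list[str] = []
    if format is NetworkFormat.EDGE_LIST:
        selected = _frame_for_static_write(net, frame, format)
        for source, target, _ in sorted(net.edge_records(selected)):
            lines.append(f"{source}\t{target}")
    elif format is NetworkFormat.SIF:
        selected = _frame_for_static_write(net, frame, format)
        for source, target, relation in sorted(
            net.edge_records(selected), key=lambda r: (r[0], r[1])
        ):
            lines.append(f"{source}\t{relation or DEFAULT_RELATION}\t{target}")
    elif format is NetworkFormat.DYNAMIC_EDGE_LIST:
        for frame_label in net.frames:
            for source, target, _ in sorted(net.edge_records(frame_label)):
                lines.append(f"{source}\t{target}\t{frame_label}")
    else:
        raise UnsupportedFormatError(f"cannot write format {format.value}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_expression(expr: ExpressionSeries, path: str | Path) -> Path:
    """Write an expression series as TSV (node id column + frame columns)."""
    path = Path(path)
    table = expr.table.rename_axis("node")
    table.to_csv(path, sep="\t", na_rep="", lineterminator="\n")
    return path


def write_edge_records(records: Iterable[EdgeRecord], path: str | Path) -> Path:
    """Write edge records (with optional frame labels) as TSV."""
    path = Path(path)
    lines = []
    for record in records:
        fields = [record.source, record.target]
        if record.frame is not None:
            fields.append(record.frame)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
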