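"""Named-column time-series containers and gait-lab file formats.

The three containers here are the in-memory form of the standard motion-lab
files: ``TimeSeriesTable`` for MOT/STO tables (kinematics, generalized loads,
EMG envelopes, ground reactions), ``MarkerData`` for TRC marker trajectories,
and ``GroundReactionData`` for per-foot force/moment/expression-point triples.

All quantities are stored in SI units (metres, seconds, newtons); TRC files in
millimetres are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesTable",
    "MarkerData",
    "GroundReactionData",
    "FormatError",
    "DataError",
    "read_time_series",
    "write_time_series",
    "read_marker_file",
    "write_marker_file",
]


class FormatError(ValueError):
    """A file did not conform to its expected dialect."""


class DataError(ValueError):
    """A file parsed but its contents violate a data invariant."""


@dataclass
class TimeSeriesTable:
    """Uniform abstraction over MOT/STO tables: a strictly increasing time
    vector plus named columns of equal length."""

    time: np.ndarray
    columns: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1:
            raise DataError("time must be a 1-D vector")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise DataError("time column must be strictly increasing")
        cols = {}
        for name, vals in self.columns.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape != self.time.shape:
                raise DataError(
                    f"column {name!r} has length {arr.shape}, "
                    f"time has {self.time.shape}"
                )
            cols[name] = arr
        self.columns = cols

    @property
    def names(self) -> list[str]:
        return list(self.columns)

    def __len__(self) -> int:
        return len(self.time)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    def as_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = self.names if names is None else names
        return np.column_stack([self.columns[n] for n in names])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, **self.columns})

    @classmethod
    def from_matrix(cls, time, matrix, names, metadata=None) -> "TimeSeriesTable":
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        return cls(
            np.asarray(time, dtype=float),
            {n: matrix[:, j] for j, n in enumerate(names)},
            metadata or {},
        )


@dataclass
class MarkerData:
    """TRC marker trajectories in metres, one (n_frames, 3) array per marker."""

    time: np.ndarray
    markers: dict[str, np.ndarray]
    units: str = "m"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        mk = {}
        for name, pos in self.markers.items():
            arr = np.asarray(pos, dtype=float)
            if arr.shape != (len(self.time), 3):
                raise DataError(f"marker {name!r}: expected shape "
                                f"({len(self.time)}, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"marker {name!r} has non-finite positions")
            mk[name] = arr
        self.markers = mk

    @property
    def names(self) -> list[str]:
        return list(self.markers)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class GroundReactionData:
    """Per-foot ground reactions: 3-component force, moment, and the point
    the moment is expressed about, per frame."""

    time: np.ndarray
    feet: dict[str, dict[str, np.ndarray]]  # foot -> {force, moment, point}

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = len(self.time)
        for foot, d in self.feet.items():
            for key in ("force", "moment", "point"):
                arr = np.asarray(d[key], dtype=float)
                if arr.shape != (n, 3):
                    raise DataError(
                        f"{foot}/{key}: expected ({n}, 3), got {arr.shape}")
                d[key] = arr
            if not np.all(np.isfinite(d["point"])):
                raise DataError(f"{foot}: non-finite expression point")

    def to_table(self) -> TimeSeriesTable:
        cols: dict[str, np.ndarray] = {}
        for foot, d in self.feet.items():
            for key, tag in (("force", "force"), ("point", "point"),
                             ("moment", "moment")):
                for j, ax in enumerate("xyz"):
                    cols[f"{foot}_{tag}_{ax}"] = d[key][:, j]
        return TimeSeriesTable(self.time, cols)

    @classmethod
    def from_table(cls, table: TimeSeriesTable, feet: list[str]
                   ) -> "GroundReactionData":
        data = {}
        for foot in feet:
            data[foot] = {
                key: np.column_stack(
                    [table[f"{foot}_{key}_{ax}"] for ax in "xyz"])
                for key in ("force", "moment", "point")
            }
        return cls(table.time, data)


# ---------------------------------------------------------------------------
# MOT/STO dialect: tab-delimited, header terminated by "endheader", time first.
# ---------------------------------------------------------------------------

def write_time_series(table: TimeSeriesTable, path) -> None:
    if not table.columns:
        raise FormatError("cannot write a table with no data columns")
    names = table.names
    with open(path, "w") as fh:
        fh.write(f"{getattr(path, 'name', path)}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(table)}\n")
        fh.write(f"nColumns={len(names) + 1}\n")
        fh.write("inDegrees=no\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(names) + "\n")
        mat = table.as_matrix()
        for i in range(len(table)):
            row = [f"{table.time[i]:.15g}"] + [f"{v:.15g}" for v in mat[i]]
            fh.write("\t".join(row) + "\n")


def read_time_series(path) -> TimeSeriesTable:
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = {"provenance": str(path)}
    i = 0
    header_seen = False
    for i, line in enumerate(lines):
        if line.strip().lower() == "endheader":
            header_seen = True
            break
        if "=" in line:
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
    if not header_seen:
        # MOT dialect without endheader: first non-empty line is columns
        i = -1
    names_line = None
    for j in range(i + 1, len(lines)):
        if lines[j].strip():
            names_line = j
            break
    if names_line is None:
        raise FormatError(f"{path}: no column header line found")
    names = lines[names_line].split()
    if not names or names[0].lower() != "time":
        raise FormatError(
            f"{path}: line {names_line + 1}: first column must be 'time'")
    if len(set(names)) != len(names):
        raise FormatError(f"{path}: duplicate column names")
    rows = []
    for j in range(names_line + 1, len(lines)):
        if not lines[j].strip():
            continue
        vals = lines[j].split()
        if len(vals) != len(names):
            raise FormatError(
                f"{path}: line {j + 1}: expected {len(names)} values, "
                f"got {len(vals)}")
        rows.append([float(v) for v in vals])
    data = np.asarray(rows, dtype=float)
    if data.size == 0:
        raise FormatError(f"{path}: no data rows")
    time = data[:, 0]
    if len(time) > 1 and not np.all(np.diff(time) > 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    return TimeSeriesTable(
        time, {n: data[:, k + 1] for k, n in enumerate(names[1:])}, meta)


# ---------------------------------------------------------------------------
# TRC dialect: two-row header with camera-rate fields, Units from the header,
# per-marker X/Y/Z triples.
# ---------------------------------------------------------------------------

def write_marker_file(data: MarkerData, path, units: str = "m") -> None:
    scale = 1000.0 if units == "mm" else 1.0
    names = data.names
    n = len(data)
    rate = 1.0 / np.mean(np.diff(data.time)) if n > 1 else 100.0
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:.6g}\t{rate:.6g}\t{n}\t{len(names)}\t{units}\t"
                 f"{rate:.6g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        fh.write("\t\t" + "\t".join(
            f"X{j+1}\tY{j+1}\tZ{j+1}" for j in range(len(names))) + "\n")
        for i in range(n):
            vals = []
            for nm in names:
                vals.extend(f"{v * scale:.15g}" for v in data.markers[nm][i])
            fh.write(f"{i+1}\t{data.time[i]:.15g}\t" + "\t".join(vals) + "\n")


def read_marker_file(path) -> MarkerData:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise FormatError(f"{path}: truncated TRC header")
    fields = lines[1].split("\t")
    values = lines[2].split("\t")
    header = dict(zip(fields, values))
    try:
        n_markers = int(header["NumMarkers"])
        n_frames = int(header["NumFrames"])
        units = header["Units"].strip()
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: line 3: malformed TRC header "
                          f"({exc})") from exc
    if units not in ("mm", "m"):
        raise FormatError(f"{path}: unsupported Units tag {units!r} "
                          "(expected 'mm' or 'm')")
    scale = 1e-3 if units == "mm" else 1.0
    names = [t for t in lines[3].split("\t")[2:] if t.strip()]
    if len(names) != n_markers:
        raise FormatError(
            f"{path}: line 4: header claims {n_markers} markers, "
            f"name row lists {len(names)}")
    times = []
    tracks: list[list[list[float]]] = [[] for _ in range(n_markers)]
    for j, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        vals = line.split("\t")
        if len(vals) < 2 + 3 * n_markers:
            raise FormatError(
                f"{path}: line {j}: expected {2 + 3 * n_markers} fields "
                f"for {n_markers} markers, got {len(vals)}")
        times.append(float(vals[1]))
        for m in range(n_markers):
            xyz = vals[2 + 3 * m: 5 + 3 * m]
            tracks[m].append([float(v) * scale for v in xyz])
    if len(times) != n_frames:
        raise FormatError(
            f"{path}: header claims {n_frames} frames, found {len(times)}")
    markers = {nm: np.asarray(tracks[m]) for m, nm in enumerate(names)}
    return MarkerData(np.asarray(times), markers, units="m")
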