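"""Readers and writers for Hi-C matrices, TAD interval sets and signal tracks.

Contact matrices are accepted as dense whitespace-delimited grids or as
3-column COO text (``i  j  count``) with either bin or bp coordinates.
TAD sets use BED3 (0-based, half-open); signal tracks use bedGraph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "TadInterval",
    "TadSet",
    "SignalTrack",
    "read_dense_matrix",
    "read_coo_matrix",
    "read_tads_bed",
    "write_tads_bed",
    "read_bedgraph",
]


class FormatError(ValueError):
    """Malformed input file (shape, column count, coordinate grid)."""


@dataclass
class ContactMatrix:
    """Symmetric non-negative single-chromosome interaction matrix.

    Bin ``i`` covers the bp interval ``[i*resolution, (i+1)*resolution)``.
    """

    chrom: str
    resolution: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"values must be square, got shape {v.shape}")
        if v.shape[0] < 1:
            raise ValueError("matrix must have at least one bin")
        if not np.isfinite(v).all():
            raise ValueError("matrix contains NaN/Inf after load")
        if (v < 0).any():
            raise ValueError("matrix contains negative entries")
        if not np.array_equal(v, v.T):
            raise ValueError("matrix is not symmetric; symmetrize on read")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def row_sum(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def slice(self, rows: slice, cols: slice) -> np.ndarray:
        return self.values[rows, cols]


@dataclass(frozen=True)
class TadInterval:
    """One TAD as a half-open genomic interval, bin-aligned to a resolution."""

    chrom: str
    start_bin: int
    end_bin: int
    resolution: int
    source_window: int | None = None
    cluster_label: int | None = None

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError(
                f"empty interval: bins [{self.start_bin}, {self.end_bin})"
            )
        if self.start_bin < 0:
            raise ValueError("negative start bin")

    @property
    def start_bp(self) -> int:
        return self.start_bin * self.resolution

    @property
    def end_bp(self) -> int:
        return self.end_bin * self.resolution

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class TadSet:
    """Ordered, non-overlapping TAD intervals on one chromosome."""

    chrom: str
    resolution: int
    intervals: list[TadInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda t: t.start_bin)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_bin < a.end_bin:
                raise ValueError(
                    f"overlapping TADs: [{a.start_bin},{a.end_bin}) and "
                    f"[{b.start_bin},{b.end_bin})"
                )
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i: int) -> TadInterval:
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, TadSet):
            return NotImplemented
        mine = [(t.chrom, t.start_bp, t.end_bp) for t in self]
        theirs = [(t.chrom, t.start_bp, t.end_bp) for t in other]
        return mine == theirs

    @property
    def boundaries_bp(self) -> list[int]:
        """All distinct interval edges, in bp."""
        out: list[int] = []
        for t in self.intervals:
            out.extend((t.start_bp, t.end_bp))
        return sorted(set(out))


@dataclass
class SignalTrack:
    """Piecewise-constant genomic signal (bedGraph semantics) on one chrom."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.starts, dtype=np.int64)
        e = np.asarray(self.ends, dtype=np.int64)
        v = np.asarray(self.values, dtype=float)
        if not (len(s) == len(e) == len(v)):
            raise ValueError("starts/ends/values length mismatch")
        if (e <= s).any():
            raise ValueError("empty or inverted signal interval")
        if not np.isfinite(v).all():
            raise ValueError("non-finite signal value")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if (s[1:] < e[:-1]).any():
            raise ValueError("overlapping signal intervals")
        self.starts, self.ends, self.values = s, e, v


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


def read_dense_matrix(path, chrom: str, resolution: int) -> ContactMatrix:
    """Read an n x n whitespace/TSV numeric grid.

    NaN entries become 0; asymmetric input is symmetrized as (M + M.T)/2;
    negative entries are rejected.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rows.append(line.split())
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: ragged rows, not a rectangular grid")
    if len(rows) != width:
        raise FormatError(
            f"{path}: grid is {len(rows)}x{width}, expected a square matrix"
        )
    m = np.array(rows, dtype=float)
    m = np.nan_to_num(m, nan=0.0, posinf=np.nan, neginf=np.nan)
    if not np.isfinite(m).all():
        raise ValueError(f"{path}: infinite entries in matrix")
    if (m < 0).any():
        raise ValueError(f"{path}: negative contact counts")
    return ContactMatrix(chrom=chrom, resolution=resolution, values=_symmetrize(m))


def read_coo_matrix(
    path,
    chrom: str,
    resolution: int,
    coords: str = "bin",
    n_bins: int | None = None,
) -> ContactMatrix:
    """Read 3-column COO text ``(i, j, count)``.

    ``coords="bp"`` interprets i/j as bp starts (must be multiples of the
    resolution). Unlisted pairs are 0; duplicates are summed; both (i,j)
    and (j,i) are filled.
    """
    if coords not in ("bin", "bp"):
        raise ValueError(f"coords must be 'bin' or 'bp', got {coords!r}")
    tbl = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["i", "j", "count"], dtype=float,
    )
    if tbl.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns")
    if tbl.empty:
        if n_bins is None:
            raise FormatError(f"{path}: empty COO file and n_bins not given")
        return ContactMatrix(chrom, resolution, np.zeros((n_bins, n_bins)))
    ii = tbl["i"].to_numpy()
    jj = tbl["j"].to_numpy()
    cc = np.nan_to_num(tbl["count"].to_numpy(), nan=0.0)
    if coords == "bp":
        if ((ii % resolution) != 0).any() or ((jj % resolution) != 0).any():
            raise FormatError(
                f"{path}: bp coordinate not a multiple of resolution {resolution}"
            )
        ii = ii / resolution
        jj = jj / resolution
    i = ii.astype(np.int64)
    j = jj.astype(np.int64)
    if (i < 0).any() or (j < 0).any():
        raise FormatError(f"{path}: negative bin index")
    if (cc < 0).any():
        raise ValueError(f"{path}: negative contact counts")
    inferred = int(max(i.max(), j.max())) + 1
    n = inferred if n_bins is None else int(n_bins)
    if inferred > n:
        raise FormatError(f"{path}: bin index {inferred - 1} exceeds n_bins={n}")
    m = np.zeros((n, n))
    # duplicates (incl. asymmetric ones) accumulate, then mirror via symmetrization
    np.add.at(m, (i, j), cc)
    upper = np.triu(m) + np.tril(m, -1).T
    m = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom=chrom, resolution=resolution, values=m)


def write_tads_bed(tads: TadSet, path) -> None:
    """Write a TadSet as sorted BED3 (0-based half-open bp coordinates)."""
    with open(path, "w") as fh:
        for t in tads:
            fh.write(f"{t.chrom}\t{t.start_bp}\t{t.end_bp}\n")


def read_tads_bed(path, resolution: int) -> TadSet:
    """Read a BED3+ file into a TadSet at the given resolution.

    Off-grid coordinates are snapped outward (floor start, ceil end) with a
    warning.
    """
    chroms: list[str] = []
    intervals: list[TadInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise ValueError(f"{path}:{ln}: start {s} >= end {e}")
            if s % resolution or e % resolution:
                warnings.warn(
                    f"{path}:{ln}: interval [{s},{e}) not aligned to "
                    f"{resolution} bp bins; snapping outward",
                    stacklevel=2,
                )
            chroms.append(chrom)
            intervals.append(
                TadInterval(
                    chrom=chrom,
                    start_bin=s // resolution,
                    end_bin=-(-e // resolution),
                    resolution=resolution,
                )
            )
    chrom = chroms[0] if chroms else "."
    return TadSet(chrom=chrom, resolution=resolution, intervals=intervals)


def read_bedgraph(path, chrom: str | None = None) -> SignalTrack:
    """Read a bedGraph file; optionally restrict to one chromosome."""
    tbl = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    if chrom is not None:
        tbl = tbl[tbl["chrom"] == chrom]
    if tbl.empty:
        raise FormatError(f"{path}: no bedGraph records" +
                          (f" for {chrom}" if chrom else ""))
    name = chrom if chrom is not None else str(tbl["chrom"].iloc[0])
    return SignalTrack(
        chrom=name,
        starts=tbl["start"].to_numpy(np.int64),
        ends=tbl["end"].to_numpy(np.int64),
        values=tbl["value"].to_numpy(float),
    )


def shift_tads(tads: TadSet, offset_bins: int) -> TadSet:
    """Return a copy of ``tads`` with every interval shifted by whole bins."""
    return TadSet(
        chrom=tads.chrom,
        resolution=tads.resolution,
        intervals=[
            replace(t, start_bin=t.start_bin + offset_bins,
                    end_bin=t.end_bin + offset_bins)
            for t in tads
        ],
    )
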