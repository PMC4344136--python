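"""Census tables: the common currency of simulator output and observed data.

A census is a fully mapped snapshot of a forest plot: one row per living tree
with coordinates in metres from the plot corner, a species code, a stem
diameter (dbh, stored in millimetres to avoid unit ambiguity) and a status.
Files use a minimal ForestGEO-like tab-separated dialect with the plot
dimensions in ``#``-prefixed header lines::

    # width_m: 1000.0
    # height_m: 500.0
    tag	sp	gx	gy	dbh	status
    t000001	sp0012	12.34	56.78	231.0	alive

Reading applies the adult-tree filter used throughout the analysis: only
living stems with dbh >= 100 mm are retained.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Census", "read_census", "write_census", "MIN_DBH_MM"]

#: adult-tree threshold: stems with dbh >= 10 cm
MIN_DBH_MM = 100.0

_COLUMNS = ("tag", "sp", "gx", "gy", "dbh", "status")


@dataclass
class Census:
    """In-memory census: parallel arrays over trees plus plot dimensions."""

    x: np.ndarray
    y: np.ndarray
    species: np.ndarray
    width: float
    height: float
    ids: np.ndarray | None = None
    dbh: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.species = np.asarray(self.species)
        if not (len(self.x) == len(self.y) == len(self.species)):
            raise ValueError("x, y and species must have equal length")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != len(self.x):
                raise ValueError("ids length mismatch")
        if self.dbh is not None:
            self.dbh = np.asarray(self.dbh, dtype=np.float64)

    @property
    def n(self) -> int:
        return int(len(self.x))

    @property
    def area(self) -> float:
        return float(self.width * self.height)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n
        ids = self.ids if self.ids is not None else np.array([f"t{i:06d}" for i in range(n)])
        dbh = self.dbh if self.dbh is not None else np.full(n, MIN_DBH_MM)
        return pd.DataFrame(
            {
                "tag": np.asarray(ids).astype(str),
                "sp": self.species.astype(str),
                "gx": self.x,
                "gy": self.y,
                "dbh": dbh,
                "status": "alive",
            }
        )


def write_census(census: Census, path) -> None:
    """Write a census as TSV with plot dimensions in header comment lines.

    Coordinates are written at fixed 0.01 m precision, so a census whose
    coordinates are already multiples of 0.01 round-trips exactly.
    """
    df = census.to_dataframe()
    buf = io.StringIO()
    buf.write(f"# width_m: {census.width}\n# height_m: {census.height}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.2f")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_census(path, min_dbh_mm: float = MIN_DBH_MM) -> Census:
    """Read a census TSV, keeping living adult trees (dbh >= ``min_dbh_mm``).

    Raises
    ------
    ValueError
        On a missing mandatory column, duplicated tree tag, or a coordinate
        outside the plot bounds (the offending row is named).
    """
    width = height = None
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].partition(":")
            key = key.strip()
            if key == "width_m":
                width = float(value)
            elif key == "height_m":
                height = float(value)
    if width is None or height is None:
        raise ValueError(f"{path}: missing '# width_m:' / '# height_m:' header lines")

    df = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype={"tag": str, "sp": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    dup = df["tag"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{path}: duplicated tree tag {df['tag'].iloc[row]!r} at row {row}")

    gx = df["gx"].to_numpy(dtype=np.float64)
    gy = df["gy"].to_numpy(dtype=np.float64)
    bad = (gx < 0) | (gx > width) | (gy < 0) | (gy > height) | ~np.isfinite(gx) | ~np.isfinite(gy)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: coordinates ({gx[row]}, {gy[row]}) outside plot bounds at row {row}"
        )

    keep = (df["status"].astype(str).str.strip() == "alive") & (
        df["dbh"].to_numpy(dtype=np.float64) >= min_dbh_mm
    )
    df = df.loc[keep.to_numpy()]
    return Census(
        x=df["gx"].to_numpy(dtype=np.float64),
        y=df["gy"].to_numpy(dtype=np.float64),
        species=df["sp"].to_numpy(),
        width=width,
        height=height,
        ids=df["tag"].to_numpy(),
        dbh=df["dbh"].to_numpy(dtype=np.float64),
    )
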