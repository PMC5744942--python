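"""Tabular input/output: relocation tables and habitat quadrat tables.

CSV dialect is fixed: comma-separated, header row required, UTF-8, '.'
decimal. Floats are written with 12 significant digits so that a
write-then-read round trip is the identity at that precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"

#: accepted spellings for the individual-ID column, first match wins
_ID_COLUMNS = ("id", "individual", "individual_id", "bird", "bird_id")


@dataclass
class RelocationSet:
    """Relocation (sighting) points grouped by individual.

    Backed by a DataFrame with columns ``id``, ``x``, ``y`` preserving input
    row order; ``sex`` is carried through when present.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"id", "x", "y"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"RelocationSet requires columns {sorted(required)}")
        if not np.all(np.isfinite(self.df[["x", "y"]].to_numpy(float))):
            raise FormatError("relocation coordinates must be finite")

    @property
    def individuals(self) -> list:
        """IDs in order of first appearance."""
        return list(dict.fromkeys(self.df["id"]))

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def counts(self) -> dict:
        return {i: int((self.df["id"] == i).sum()) for i in self.individuals}

    def points(self, individual) -> np.ndarray:
        """(n, 2) coordinates for one individual, in input order."""
        sub = self.df[self.df["id"] == individual]
        if sub.empty:
            raise KeyError(f"unknown individual {individual!r}")
        return sub[["x", "y"]].to_numpy(float)

    def all_points(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(float)

    def subset(self, individuals) -> "RelocationSet":
        keep = self.df["id"].isin(list(individuals))
        return RelocationSet(self.df[keep].reset_index(drop=True))

    def equals(self, other: "RelocationSet") -> bool:
        a = self.df[["id", "x", "y"]].reset_index(drop=True)
        b = other.df[["id", "x", "y"]].reset_index(drop=True)
        return a.equals(b)


@dataclass
class QuadratTable:
    """One record per 1 m2 habitat quadrat: x, y plus named variables.

    Variable names are preserved verbatim; missing values stay as NaN and
    are counted in :attr:`n_missing`, never silently dropped.
    """

    df: pd.DataFrame
    variables: list = field(default_factory=list)

    def __post_init__(self):
        if not {"x", "y"}.issubset(self.df.columns):
            raise FormatError("QuadratTable requires 'x' and 'y' columns")
        if not self.variables:
            self.variables = [c for c in self.df.columns if c not in ("x", "y")]
        if not self.variables:
            raise FormatError("QuadratTable requires at least one variable column")
        xy = self.df[["x", "y"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise FormatError("quadrat coordinates must be finite")
        if self.df.duplicated(subset=["x", "y"]).any():
            dup = self.df[self.df.duplicated(subset=["x", "y"], keep=False)]
            raise FormatError(
                "duplicate quadrat coordinates (kriging system would be "
                f"singular): {dup[['x', 'y']].drop_duplicates().to_numpy().tolist()}"
            )

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_missing(self) -> dict:
        return {v: int(self.df[v].isna().sum()) for v in self.variables}

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(float)

    def values(self, variable: str) -> np.ndarray:
        if variable not in self.variables:
            raise KeyError(f"unknown variable {variable!r}")
        return self.df[variable].to_numpy(float)

    def equals(self, other: "QuadratTable") -> bool:
        cols = ["x", "y"] + self.variables
        if self.variables != other.variables:
            return False
        return self.df[cols].reset_index(drop=True).equals(
            other.df[cols].reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        # +2: one for the header line, one for 0-based indexing
        line = int(bad.idxmax()) + 2
        raise FormatError(
            f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
            f"{col!r} at line {line}"
        )
    return out.to_numpy(float)


def read_relocations(path) -> RelocationSet:
    """Read a relocation CSV (individual ID, x, y) into a RelocationSet."""
    df = _read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    id_col = next((lower[c] for c in _ID_COLUMNS if c in lower), None)
    if id_col is None:
        raise FormatError(
            f"{path}: missing individual-ID column (one of {_ID_COLUMNS})"
        )
    for c in ("x", "y"):
        if c not in lower:
            raise FormatError(f"{path}: missing column {c!r}")
    out = pd.DataFrame({
        "id": df[id_col].astype(str),
        "x": _numeric_column(df, lower["x"], path),
        "y": _numeric_column(df, lower["y"], path),
    })
    if "sex" in lower:
        out["sex"] = df[lower["sex"]].astype(str)
    rs = RelocationSet(out)
    for ind, n in rs.counts().items():
        log.info("read_relocations: individual %s has %d locations", ind, n)
    return rs


def write_relocations(rs: RelocationSet, path) -> None:
    cols = ["id", "x", "y"] + (["sex"] if "sex" in rs.df.columns else [])
    rs.df[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_quadrats(path) -> QuadratTable:
    """Read a quadrat CSV (x, y, one column per habitat variable)."""
    df = _read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    for c in ("x", "y"):
        if c not in lower:
            raise FormatError(f"{path}: missing column {c!r}")
    variables = [c for c in df.columns if c.lower() not in ("x", "y")]
    if not variables:
        raise FormatError(f"{path}: no habitat variable columns")
    out = pd.DataFrame({
        "x": _numeric_column(df, lower["x"], path),
        "y": _numeric_column(df, lower["y"], path),
    })
    for v in variables:
        out[v] = pd.to_numeric(df[v], errors="coerce").to_numpy(float)
    qt = QuadratTable(out, variables=variables)
    missing = {k: v for k, v in qt.n_missing.items() if v}
    if missing:
        log.warning("read_quadrats: missing values per variable: %s", missing)
    return qt


def write_quadrats(qt: QuadratTable, path) -> None:
    qt.df[["x", "y"] + qt.variables].to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )
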