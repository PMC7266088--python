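"""Readers and writers for the canonical cell, tree-metadata and trait tables.

All tables are plain RFC-4180 CSV with a dot decimal separator, fixed units
(micrometres for cell geometry, square micrometres for areas, metres for tree
height, years for age, centimetres for DBH) and a documented column schema.
Floating-point values are written with 12 significant digits, which makes
writes deterministic and read/write round trips numerically stable.

The cell-table schema is our own canonical dialect.  Raw exports from cell
image-analysis software (e.g. ROXAS) use different column headers; a
best-effort alias map is provided so such exports can be ingested after
renaming, but the alias spellings are unverified against any particular
software version.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping
import warnings

import pandas as pd
import yaml

from .errors import CompletenessError, FormatError, ValidationError

FLOAT_FORMAT = "%.12g"

#: Tolerance admitted on the elliptical lumen-area bound LA <= (pi/4)*Drad*Dtan.
ELLIPSE_EPS = 1e-6

# ---------------------------------------------------------------------------
# Schemas
# ---------------------------------------------------------------------------

#: Canonical cell-table columns, one row per tracheid.
CELL_COLUMNS = [
    "tree_id",      # tree identifier (string)
    "year",         # calendar year of the ring
    "file_index",   # tangential file ordinal within the 1-mm strip (1-based)
    "cell_index",   # radial ordinal within the file, 1 = pith side
    "rel_pos",      # relative radial position of the cell centre in [0, 1]
    "drad_lumen",   # radial lumen diameter, um
    "dtan_lumen",   # tangential lumen diameter, um
    "lumen_area",   # lumen area, um^2
    "cwt_pi",       # single tangential wall thickness, pith side, um
    "cwt_ba",       # single tangential wall thickness, bark side, um
    "cwt_le",       # single radial wall thickness, left, um
    "cwt_ri",       # single radial wall thickness, right, um
    "cwa",          # cell wall area, um^2
]

_CELL_GEOMETRY = ["drad_lumen", "dtan_lumen", "lumen_area",
                  "cwt_pi", "cwt_ba", "cwt_le", "cwt_ri", "cwa"]

#: Tree metadata columns.
META_COLUMNS = [
    "tree_id", "plot", "latitude", "longitude",
    "elevation", "height", "age", "dbh",
]

#: Percentile suffixes used throughout the trait catalogue (two digits).
PERCENTILE_SUFFIXES = ["01", "25", "50", "75", "99"]


def _with_variants(base: str) -> list[str]:
    return ([base, f"{base}_EW", f"{base}_LW"]
            + [f"{base}_{s}" for s in PERCENTILE_SUFFIXES])


#: The full ring-trait catalogue, grouped by function (ring growth, cell
#: growth, mechanical support, hydraulics).  Percentile rows of the catalogue
#: expand to one column per percentile.
TRAIT_COLUMNS = (
    # ring growth
    ["TRW", "BAI", "EW%", "LW%", "LW%/EW%"]
    # cell growth
    + ["NoCells_tang", "NoCells_rad", "EW_Nocells", "LW_Nocells",
       "EWW", "LWW", "Drad", "Dtan", "Drad_EW", "Dtan_LW",
       "CWA", "CWA_EW", "CWA_LW",
       "LA"] + [f"LA_{s}" for s in PERCENTILE_SUFFIXES]
    + ["CD", "CNO", "CNO_EW", "CNO_LW"]
    # mechanical support
    + _with_variants("CWTall")
    + _with_variants("CWTtan")
    + _with_variants("CWTrad")
    + _with_variants("rTSR")
    + _with_variants("RWD")
    # hydraulic efficiency and safety
    + ["Dh", "Ks", "Kh", "tb2", "tb2_05", "HCUE"]
)

TRAIT_TABLE_COLUMNS = ["tree_id", "year"] + TRAIT_COLUMNS

#: Functional grouping of the catalogue (used by the pipeline summary).
TRAIT_GROUPS: dict[str, list[str]] = {
    "ring growth": TRAIT_COLUMNS[:5],
    "cell growth": TRAIT_COLUMNS[5:28],
    "mechanical support": TRAIT_COLUMNS[28:68],
    "hydraulics": TRAIT_COLUMNS[68:],
}

#: Best-effort header aliases for raw image-analysis exports.  UNVERIFIED:
#: the exact export layout is not published; rename-and-check before trusting.
ROXAS_ALIASES: Mapping[str, str] = {
    "YEAR": "year",
    "ID": "tree_id",
    "RADNO": "cell_index",
    "TANNO": "file_index",
    "RRADDISTR": "rel_pos",
    "DRAD": "drad_lumen",
    "DTAN": "dtan_lumen",
    "LA": "lumen_area",
    "CWTPI": "cwt_pi",
    "CWTBA": "cwt_ba",
    "CWTLE": "cwt_le",
    "CWTRI": "cwt_ri",
    "CWA": "cwa",
}


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CellRecord:
    """Geometry of a single tracheid within its ring."""

    tree_id: str
    year: int
    file_index: int
    cell_index: int
    rel_pos: float
    drad_lumen: float
    dtan_lumen: float
    lumen_area: float
    cwt_pi: float
    cwt_ba: float
    cwt_le: float
    cwt_ri: float
    cwa: float


@dataclasses.dataclass(frozen=True)
class TreeMeta:
    """Location and biometry of one sampled tree."""

    tree_id: str
    plot: str
    latitude: float
    longitude: float
    elevation: float
    height: float
    age: float
    dbh: float

    def __post_init__(self) -> None:
        if not self.plot:
            raise ValidationError("plot code must be non-empty")
        if self.height <= 0:
            raise ValidationError(f"height must be > 0, got {self.height}")
        if self.age < 1:
            raise ValidationError(f"age must be >= 1, got {self.age}")


def cells_to_frame(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Convert CellRecord objects to the canonical cell DataFrame."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records],
                        columns=CELL_COLUMNS)


def frame_to_cells(frame: pd.DataFrame) -> list[CellRecord]:
    """Convert a canonical cell DataFrame to CellRecord objects."""
    return [CellRecord(**row) for row in frame[CELL_COLUMNS].to_dict("records")]


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

def validate_cell_frame(frame: pd.DataFrame, *, source: str = "<frame>") -> None:
    """Check value-level invariants of a cell table.

    Raises :class:`ValidationError` citing the 1-based data row of the first
    offending record.
    """
    for col in _CELL_GEOMETRY:
        bad = frame.index[frame[col] <= 0]
        if len(bad):
            row = int(bad[0]) + 1
            raise ValidationError(
                f"{source}: non-positive {col} on row {row}")
    bad = frame.index[(frame["rel_pos"] < 0) | (frame["rel_pos"] > 1)]
    if len(bad):
        raise ValidationError(
            f"{source}: rel_pos outside [0, 1] on row {int(bad[0]) + 1}")
    bound = (math.pi / 4) * frame["drad_lumen"] * frame["dtan_lumen"]
    bad = frame.index[frame["lumen_area"] > bound * (1 + ELLIPSE_EPS)]
    if len(bad):
        raise ValidationError(
            f"{source}: lumen_area exceeds elliptical bound on row "
            f"{int(bad[0]) + 1}")
    key = ["tree_id", "year", "file_index", "cell_index"]
    if frame.duplicated(subset=key).any():
        row = int(frame.index[frame.duplicated(subset=key)][0]) + 1
        raise ValidationError(
            f"{source}: duplicate (tree_id, year, file_index, cell_index) "
            f"key on row {row}")


def read_cell_table(path: str | Path, *,
                    aliases: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a cell table.

    Parameters
    ----------
    path:
        CSV file with the canonical header (see :data:`CELL_COLUMNS`).
    aliases:
        Optional header rename map applied before validation, e.g.
        :data:`ROXAS_ALIASES` for raw image-analysis exports.

    Unknown extra columns are ignored with a warning.  Row order is preserved.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if aliases:
        frame = frame.rename(columns=dict(aliases))
    missing = [c for c in CELL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in CELL_COLUMNS]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown column(s): "
                      f"{', '.join(extra)}", stacklevel=2)
    frame = frame[CELL_COLUMNS].reset_index(drop=True)
    frame["tree_id"] = frame["tree_id"].astype(str)
    for col in ("year", "file_index", "cell_index"):
        frame[col] = frame[col].astype(int)
    for col in ["rel_pos"] + _CELL_GEOMETRY:
        frame[col] = frame[col].astype(float)
    validate_cell_frame(frame, source=path.name)
    return frame


def write_cell_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table in the canonical column order."""
    missing = [c for c in CELL_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"cannot write cell table, missing column(s): "
                          f"{', '.join(missing)}")
    frame[CELL_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Tree metadata
# ---------------------------------------------------------------------------

def read_tree_meta(path: str | Path) -> pd.DataFrame:
    """Read the tree metadata table (one row per tree)."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}")
    frame = frame[META_COLUMNS].reset_index(drop=True)
    frame["tree_id"] = frame["tree_id"].astype(str)
    frame["plot"] = frame["plot"].astype(str)
    for col in META_COLUMNS[2:]:
        frame[col] = frame[col].astype(float)
    if (frame["height"] <= 0).any():
        row = int(frame.index[frame["height"] <= 0][0]) + 1
        raise ValidationError(f"{path.name}: non-positive height on row {row}")
    if (frame["age"] < 1).any():
        row = int(frame.index[frame["age"] < 1][0]) + 1
        raise ValidationError(f"{path.name}: age < 1 on row {row}")
    return frame


def write_tree_meta(frame: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"cannot write metadata, missing column(s): "
                          f"{', '.join(missing)}")
    frame[META_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def meta_frame(trees: Iterable[TreeMeta]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in trees],
                        columns=META_COLUMNS)


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

def write_trait_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the wide ring-trait table (one row per tree x year).

    The output carries the two key columns followed by the full trait
    catalogue in canonical order.  A missing catalogue column raises
    :class:`CompletenessError` naming the trait.
    """
    for col in ("tree_id", "year"):
        if col not in frame.columns:
            raise CompletenessError(f"trait table missing key column {col!r}")
    missing = [c for c in TRAIT_COLUMNS if c not in frame.columns]
    if missing:
        raise CompletenessError(
            f"trait table missing trait(s): {', '.join(missing)}")
    frame[TRAIT_TABLE_COLUMNS].to_csv(path, index=False,
                                      float_format=FLOAT_FORMAT)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a ring-trait table written by :func:`write_trait_table`."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in TRAIT_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing column(s): {', '.join(missing)}")
    frame["tree_id"] = frame["tree_id"].astype(str)
    return frame[TRAIT_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML configuration file into a plain mapping."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{Path(path).name}: top level must be a mapping")
    return data


def dump_yaml_config(data: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=True)
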