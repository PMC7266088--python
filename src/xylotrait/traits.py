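"""Derivation of ring-level anatomical traits from per-cell measurements.

The analysis unit is one tree ring observed on a tangential strip of fixed
width (1 mm by default).  Cells are organised in radial files; each file is a
tracheidogram running from the pith side (``cell_index`` 1) to the bark side.
From the per-cell geometry the module derives the full trait catalogue
(:data:`xylotrait.io_formats.TRAIT_COLUMNS`): ring and earlywood/latewood
widths, cell counts and density, lumen and wall summaries with percentiles,
the Mork index (rTSR), relative wood density (RWD), the cell-wall
reinforcement index (t/b)^2, and the hydraulic quantities Dh, Kh, Ks and
HCUE.

Earlywood/latewood discrimination follows the Mork criterion: a cell is
latewood when four times its single radial wall thickness reaches its radial
lumen diameter (index >= 1).  An alternative shape criterion (latewood when
the lumen is tangentially elongated, Drad/Dtan < 1) is available.

Conventions, fixed and documented because the trait values depend on them:

* single-wall thicknesses are averaged per axis before use; the "double
  wall" t of (t/b)^2 is twice the averaged single wall;
* percentiles use linear interpolation between order statistics;
* ring means over cells are unweighted;
* traits over an empty earlywood or latewood subset are missing (NaN),
  never zero, while the corresponding counts and widths are genuinely zero;
* the xylem area used for cell density and Ks is TRW x strip width.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ValidationError
from .io_formats import TRAIT_COLUMNS, PERCENTILE_SUFFIXES

#: Percentile levels of the trait catalogue.
PERCENTILES = (1, 25, 50, 75, 99)

EW, LW = "EW", "LW"


@dataclasses.dataclass(frozen=True)
class HydraulicConstants:
    """Physical constants for the conductivity traits.

    eta is the dynamic viscosity of water in MPa s (1.002e-9 at 20 degC),
    density in kg m^-3, and conductivities are expressed per 1 m tube length.
    """

    eta: float = 1.002e-9
    water_density: float = 998.2
    tube_length: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.water_density <= 0 or self.tube_length <= 0:
            raise ValidationError("hydraulic constants must be positive")


DEFAULT_CONSTANTS = HydraulicConstants()


@dataclasses.dataclass
class ClassificationResult:
    """Per-cell earlywood/latewood labels and the ring-level boundary."""

    labels: pd.Series          # "EW"/"LW" per cell, aligned with the input
    boundary: float            # mean relative position of the EW->LW switch
    degenerate: bool           # True when the ring lacks EW or LW cells


# ---------------------------------------------------------------------------
# Per-cell quantities
# ---------------------------------------------------------------------------

def mork_index(cells: pd.DataFrame) -> pd.Series:
    """Mork index per cell: 4 x single radial wall / radial lumen diameter.

    The single radial wall thickness is the mean of the left and right walls.
    """
    drad = cells["drad_lumen"]
    if (drad <= 0).any():
        raise ComputationError("Mork index undefined for non-positive "
                               "radial lumen diameter")
    cwt_rad = (cells["cwt_le"] + cells["cwt_ri"]) / 2.0
    return 4.0 * cwt_rad / drad


def classify_ew_lw(cells: pd.DataFrame, method: str = "mork") -> ClassificationResult:
    """Label each cell earlywood or latewood and locate the ring boundary.

    method="mork": latewood iff Mork index >= 1.
    method="shape": latewood iff drad_lumen / dtan_lumen < 1.

    The ring boundary is, per radial file, the relative position of the first
    cell (from the pith side) whose label and all successors' labels are
    latewood, averaged over files.  A file without such a terminal latewood
    run contributes 1.0.  Rings entirely earlywood (or latewood) yield a
    boundary of 1.0 (0.0) and are flagged degenerate.
    """
    if cells.empty:
        raise ComputationError("cannot classify an empty ring")
    if method == "mork":
        is_lw = mork_index(cells) >= 1.0
    elif method == "shape":
        is_lw = cells["drad_lumen"] / cells["dtan_lumen"] < 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    labels = pd.Series(np.where(is_lw, LW, EW), index=cells.index, name="label")

    boundaries = []
    for _, file_cells in cells.assign(_lw=is_lw).groupby("file_index", sort=True):
        ordered = file_cells.sort_values("cell_index")
        lw = ordered["_lw"].to_numpy()
        # first index i with lw[i:] all True
        not_lw = np.flatnonzero(~lw)
        start = not_lw[-1] + 1 if len(not_lw) else 0
        if start >= len(lw):          # no terminal latewood run
            boundaries.append(1.0)
        else:
            boundaries.append(float(ordered["rel_pos"].iloc[start]))
    degenerate = bool(is_lw.all() or (~is_lw).all())
    return ClassificationResult(labels=labels,
                                boundary=float(np.mean(boundaries)),
                                degenerate=degenerate)


# ---------------------------------------------------------------------------
# Ring geometry and counts
# ---------------------------------------------------------------------------

def _radial_extent(cells: pd.DataFrame) -> pd.Series:
    """Radial footprint of each cell: lumen plus both radial walls, um."""
    return cells["drad_lumen"] + cells["cwt_le"] + cells["cwt_ri"]


def ring_geometry(cells: pd.DataFrame, labels: pd.Series) -> dict[str, float]:
    """Ring, earlywood and latewood widths plus their percentages.

    Widths are means over radial files of the summed radial cell extents;
    EWW + LWW = TRW holds exactly because the labels partition each file.
    """
    if cells.empty:
        raise ComputationError("empty ring")
    extent = _radial_extent(cells)
    by_file = extent.groupby(cells["file_index"])
    trw = float(by_file.sum().mean())
    n_files = by_file.ngroups
    eww = float(extent[labels == EW].groupby(cells["file_index"]).sum()
                .reindex(by_file.sum().index, fill_value=0.0).mean()) \
        if (labels == EW).any() else 0.0
    lww = trw - eww
    ew_pct = 100.0 * eww / trw
    lw_pct = 100.0 * lww / trw
    ratio = lw_pct / ew_pct if ew_pct > 0 else math.nan
    return {"TRW": trw, "EWW": eww, "LWW": lww,
            "EW%": ew_pct, "LW%": lw_pct, "LW%/EW%": ratio,
            "_n_files": n_files}


def cell_counts(cells: pd.DataFrame, labels: pd.Series, trw: float,
                strip_mm: float = 1.0) -> dict[str, float]:
    """Cell counts, radial/tangential file statistics and cell density.

    NoCells_tang counts the radial files that contain latewood cells,
    per millimetre of strip; NoCells_rad is the total count divided by it.
    EW_Nocells / LW_Nocells are the corresponding per-file radial counts of
    each ring portion, so EW_Nocells + LW_Nocells = NoCells_rad.
    CD is cells per square millimetre of the analysed strip (TRW x width).
    """
    cno = int(len(cells))
    cno_ew = int((labels == EW).sum())
    cno_lw = cno - cno_ew
    lw_files = cells.loc[labels == LW, "file_index"].nunique()
    n_tang = lw_files / strip_mm
    if n_tang == 0:
        raise ComputationError("no latewood-bearing files: tangential cell "
                               "count is zero")
    n_rad = cno / n_tang
    cd = cno / ((trw / 1000.0) * strip_mm)
    return {"CNO": float(cno), "CNO_EW": float(cno_ew), "CNO_LW": float(cno_lw),
            "NoCells_tang": float(n_tang), "NoCells_rad": float(n_rad),
            "EW_Nocells": float(cno_ew / n_tang),
            "LW_Nocells": float(cno_lw / n_tang),
            "CD": float(cd)}


def bai_series(ring_widths_um: Sequence[float],
               inner_radius_um: float) -> np.ndarray:
    """Basal area increment per ring, in mm^2 per year.

    With cumulative radius ``r_i = inner_radius + sum_{j<=i} a_j`` the
    increment of ring i is ``pi * (r_i^2 - r_{i-1}^2)``.
    """
    widths = np.asarray(ring_widths_um, dtype=float)
    if (widths < 0).any():
        raise ValidationError("ring widths must be non-negative")
    if inner_radius_um < 0:
        raise ValidationError("inner radius must be non-negative")
    radii = inner_radius_um + np.concatenate([[0.0], np.cumsum(widths)])
    return (math.pi * (radii[1:] ** 2 - radii[:-1] ** 2)) / 1e6  # um^2 -> mm^2


# ---------------------------------------------------------------------------
# Wall, lumen and density metrics
# ---------------------------------------------------------------------------

def _percentiles(values: np.ndarray) -> list[float]:
    if len(values) == 0:
        return [math.nan] * len(PERCENTILES)
    return list(np.percentile(values, PERCENTILES))


def _subset_stats(name: str, values: np.ndarray,
                  ew_mask: np.ndarray) -> dict[str, float]:
    """Ring mean, EW/LW means and percentiles for one per-cell quantity."""
    out = {name: float(values.mean())}
    ew_vals, lw_vals = values[ew_mask], values[~ew_mask]
    out[f"{name}_EW"] = float(ew_vals.mean()) if len(ew_vals) else math.nan
    out[f"{name}_LW"] = float(lw_vals.mean()) if len(lw_vals) else math.nan
    for suffix, value in zip(PERCENTILE_SUFFIXES, _percentiles(values)):
        out[f"{name}_{suffix}"] = float(value)
    return out


def wall_metrics(cells: pd.DataFrame, labels: pd.Series) -> dict[str, float]:
    """Wall-thickness, wall-area, density and reinforcement traits.

    Per cell: CWTtan = (cwt_pi + cwt_ba)/2, CWTrad = (cwt_le + cwt_ri)/2,
    CWTall = (CWTtan + CWTrad)/2; rTSR (Mork index) = 4 CWTrad / Drad;
    RWD = CWA / (CWA + LA); (t/b)^2 takes t = 2 x single wall and b = the
    lumen span on the same axis, using whichever axis gives the smaller t/b
    before squaring.  Ring values are unweighted means; percentile columns
    are the 1/25/50/75/99th percentiles of the per-cell values, and tb2_05
    is the 5th percentile of per-cell (t/b)^2 (an earlywood-weighted safety
    summary).
    """
    if cells.empty:
        raise ComputationError("empty ring")
    ew_mask = (labels == EW).to_numpy()
    cwt_tan = ((cells["cwt_pi"] + cells["cwt_ba"]) / 2.0).to_numpy()
    cwt_rad = ((cells["cwt_le"] + cells["cwt_ri"]) / 2.0).to_numpy()
    cwt_all = (cwt_tan + cwt_rad) / 2.0
    drad = cells["drad_lumen"].to_numpy()
    dtan = cells["dtan_lumen"].to_numpy()
    cwa = cells["cwa"].to_numpy()
    la = cells["lumen_area"].to_numpy()

    rtsr = 4.0 * cwt_rad / drad
    rwd = cwa / (cwa + la)
    tb = np.minimum(2.0 * cwt_rad / drad, 2.0 * cwt_tan / dtan)
    tb2 = tb ** 2

    out: dict[str, float] = {}
    out.update(_subset_stats("CWTall", cwt_all, ew_mask))
    out.update(_subset_stats("CWTtan", cwt_tan, ew_mask))
    out.update(_subset_stats("CWTrad", cwt_rad, ew_mask))
    out.update(_subset_stats("rTSR", rtsr, ew_mask))
    out.update(_subset_stats("RWD", rwd, ew_mask))
    out["CWA"] = float(cwa.mean())
    out["CWA_EW"] = float(cwa[ew_mask].mean()) if ew_mask.any() else math.nan
    out["CWA_LW"] = float(cwa[~ew_mask].mean()) if (~ew_mask).any() else math.nan
    out["tb2"] = float(tb2.mean())
    out["tb2_05"] = float(np.percentile(tb2, 5))
    return out


def lumen_metrics(cells: pd.DataFrame, labels: pd.Series) -> dict[str, float]:
    """Lumen diameter and area summaries (ring, EW/LW subsets, percentiles)."""
    ew_mask = (labels == EW).to_numpy()
    drad = cells["drad_lumen"].to_numpy()
    dtan = cells["dtan_lumen"].to_numpy()
    la = cells["lumen_area"].to_numpy()
    out = {
        "Drad": float(drad.mean()),
        "Dtan": float(dtan.mean()),
        "Drad_EW": float(drad[ew_mask].mean()) if ew_mask.any() else math.nan,
        "Dtan_LW": float(dtan[~ew_mask].mean()) if (~ew_mask).any() else math.nan,
        "LA": float(la.mean()),
    }
    for suffix, value in zip(PERCENTILE_SUFFIXES, _percentiles(la)):
        out[f"LA_{suffix}"] = float(value)
    return out


# ---------------------------------------------------------------------------
# Hydraulics
# ---------------------------------------------------------------------------

def hydraulic_traits(cells: pd.DataFrame, trw_um: float,
                     strip_mm: float = 1.0,
                     constants: HydraulicConstants = DEFAULT_CONSTANTS,
                     conduit_shape: str = "ellipse") -> dict[str, float]:
    """Hydraulic diameter, theoretical conductivities and carbon efficiency.

    Dh is the moment-ratio mean sum(d^5)/sum(d^4) of the lumen-area
    equivalent circle diameters d = 2 sqrt(LA/pi).

    Kh sums the laminar (Poiseuille) conductivity of every conduit over a
    1 m tube.  With ``conduit_shape="ellipse"`` each conduit is an elliptical
    tube of semi-axes a = Drad/2, b = Dtan/2:

        k = pi a^3 b^3 / (4 eta (a^2 + b^2) L),

    which reduces to pi r^4 / (8 eta L) for circles; with
    ``conduit_shape="circle"`` the lumen-area equivalent radius is used in
    the circular formula.  Ks normalises Kh by the analysed xylem area
    (TRW x strip width, in m^2); HCUE is the mass-flow conductivity
    (Kh x water density) per unit of wall-area investment (sum of CWA, um^2).
    """
    if cells.empty:
        raise ComputationError("empty ring")
    la = cells["lumen_area"].to_numpy()
    if (la <= 0).any():
        raise ComputationError("hydraulic traits undefined for zero lumen")
    d_um = 2.0 * np.sqrt(la / math.pi)
    dh = float((d_um ** 5).sum() / (d_um ** 4).sum())

    eta, length = constants.eta, constants.tube_length
    if conduit_shape == "ellipse":
        a = cells["drad_lumen"].to_numpy() / 2.0 * 1e-6   # m
        b = cells["dtan_lumen"].to_numpy() / 2.0 * 1e-6
        k = math.pi * a ** 3 * b ** 3 / (4.0 * eta * (a ** 2 + b ** 2) * length)
    elif conduit_shape == "circle":
        r = d_um / 2.0 * 1e-6
        k = math.pi * r ** 4 / (8.0 * eta * length)
    else:
        raise ValueError(f"unknown conduit_shape {conduit_shape!r}")
    kh = float(k.sum())                                   # m^3 MPa^-1 s^-1
    xylem_area_m2 = (trw_um * 1e-6) * (strip_mm * 1e-3)
    ks = kh / xylem_area_m2
    hcue = kh * constants.water_density / float(cells["cwa"].sum())
    return {"Dh": dh, "Kh": kh, "Ks": ks, "HCUE": hcue}


# ---------------------------------------------------------------------------
# Ring aggregation
# ---------------------------------------------------------------------------

def aggregate_ring(cells: pd.DataFrame, *,
                   method: str = "mork",
                   strip_mm: float = 1.0,
                   inner_radius_um: float | None = None,
                   constants: HydraulicConstants = DEFAULT_CONSTANTS,
                   conduit_shape: str = "ellipse") -> dict[str, float]:
    """Compute the full trait catalogue for one ring.

    ``inner_radius_um`` is the stem radius at the ring's pith-side edge; when
    omitted, BAI is reported missing (it needs the radial position of the
    ring within the stem, which a lone cell table does not carry).
    Returns a mapping with exactly the catalogue keys (plus the EW/LW
    boundary under ``"_boundary"`` for diagnostics).
    """
    if cells.empty:
        raise ComputationError("empty ring")
    classification = classify_ew_lw(cells, method=method)
    labels = classification.labels
    geom = ring_geometry(cells, labels)
    trw = geom["TRW"]
    traits: dict[str, float] = {k: v for k, v in geom.items()
                                if not k.startswith("_")}
    traits.update(cell_counts(cells, labels, trw, strip_mm=strip_mm))
    traits.update(wall_metrics(cells, labels))
    traits.update(lumen_metrics(cells, labels))
    traits.update(hydraulic_traits(cells, trw, strip_mm=strip_mm,
                                   constants=constants,
                                   conduit_shape=conduit_shape))
    if inner_radius_um is None:
        traits["BAI"] = math.nan
    else:
        traits["BAI"] = float(bai_series([trw], inner_radius_um)[0])
    traits["_boundary"] = classification.boundary
    missing = [c for c in TRAIT_COLUMNS if c not in traits]
    if missing:  # pragma: no cover - guards catalogue drift
        raise ComputationError(f"catalogue incomplete: {missing}")
    return traits


def derive_trait_table(cells: pd.DataFrame, meta: pd.DataFrame, *,
                       method: str = "mork",
                       strip_mm: float = 1.0,
                       constants: HydraulicConstants = DEFAULT_CONSTANTS,
                       conduit_shape: str = "ellipse") -> pd.DataFrame:
    """Derive the ring-trait table for a whole stand.

    ``cells`` holds all rings of all trees (canonical cell table); ``meta``
    supplies per-tree DBH used to anchor the basal-area increment: the stem
    radius at the bark of the last measured ring is DBH/2, so the pith-side
    radius of the oldest measured ring is DBH/2 minus the summed widths of
    the measured rings (bark thickness ignored).
    """
    dbh_um = {str(t): d * 1e4 / 2.0    # cm diameter -> um radius
              for t, d in zip(meta["tree_id"].astype(str), meta["dbh"])}
    rows = []
    for tree_id, tree_cells in cells.groupby("tree_id", sort=True):
        years = sorted(tree_cells["year"].unique())
        ring_traits = {}
        for year in years:
            ring = tree_cells[tree_cells["year"] == year]
            ring_traits[year] = aggregate_ring(
                ring, method=method, strip_mm=strip_mm,
                constants=constants, conduit_shape=conduit_shape)
        widths = [ring_traits[y]["TRW"] for y in years]
        inner = dbh_um.get(str(tree_id))
        if inner is not None:
            inner_start = max(inner - sum(widths), 0.0)
            bai = bai_series(widths, inner_start)
        else:
            bai = [math.nan] * len(widths)
        for year, bai_i in zip(years, bai):
            row = {"tree_id": str(tree_id), "year": int(year)}
            traits = dict(ring_traits[year])
            traits.pop("_boundary", None)
            traits["BAI"] = float(bai_i)
            row.update(traits)
            rows.append(row)
    return pd.DataFrame(rows, columns=["tree_id", "year"] + TRAIT_COLUMNS)
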