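"""Synthetic stands of conifer trees with per-cell ring anatomy.

The generator emulates the structure of a three-plot altitudinal transect:
each plot contributes a fixed number of trees whose height, age and DBH are
drawn within plot-specific ranges (defaults follow the high / intermediate /
low plot demographics of the emulated stand), with height and age positively
but not collinearly correlated.  For every tree and calendar year a 1-mm
tangential strip of one ring is synthesised as a set of radial files
(tracheidograms): a wide-lumen, thin-walled earlywood plateau followed by a
logistic decline to narrow, thick-walled latewood, shaped so that the Mork
index crosses 1 at the start of the latewood block.

Biological structure encoded by the defaults:

* taller trees have larger tangential and (less strongly) radial earlywood
  lumen diameters, hence fewer tangential files per millimetre;
* older trees have thicker walls and a slightly higher latewood share;
* the latewood cell count per file is roughly constant, so ring width is
  driven by the earlywood cell count (which varies widely between trees);
* random variation decomposes into individual, year and cell components,
  with individual effects dominating year effects (at least 2x by default);
* individual effects can be spatially autocorrelated within a plot
  (Gaussian-kernel covariance on tree positions); by default only the
  dense high-elevation plot enables this.

Random effects are Gaussian on the log scale for strictly positive
quantities.  All randomness derives from a single master seed; every ring
uses a dedicated substream keyed by (tree index, year), so any ring is
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError, GenerationError
from .io_formats import CELL_COLUMNS, TreeMeta, meta_frame

#: Parameters that carry individual / year / cell variance components.
EFFECT_PARAMS = ("dtan", "drad", "cwt", "ew_count")

#: Metres per degree of latitude (for converting local metres to degrees).
_M_PER_DEG_LAT = 111_320.0


@dataclasses.dataclass(frozen=True)
class PlotSpec:
    """Demographics and location of one plot (defaults mirror a real
    three-plot spruce transect: dense young high plot, mixed mature
    intermediate and low plots)."""

    code: str
    latitude: float
    longitude: float
    elevation: float          # m a.s.l.
    area_ha: float
    height_range: tuple[float, float]   # m
    age_range: tuple[float, float]      # years
    dbh_range: tuple[float, float]      # cm
    spatial_autocorr: bool = False


DEFAULT_PLOTS = (
    PlotSpec("CAM-H", 44.1100, 10.6622, 1730.0, 0.25,
             (10.5, 18.0), (34.0, 71.0), (22.0, 56.0),
             spatial_autocorr=True),
    PlotSpec("CAM-E", 44.1131, 10.6631, 1615.0, 0.83,
             (11.0, 27.0), (35.0, 151.0), (20.0, 67.0)),
    PlotSpec("CAM-L", 44.1186, 10.6717, 1475.0, 1.95,
             (13.0, 33.0), (39.0, 155.0), (28.0, 122.0)),
)


def _default_sd_individual() -> dict[str, float]:
    return {"dtan": 0.06, "drad": 0.06, "cwt": 0.10, "ew_count": 0.55}


def _default_sd_year() -> dict[str, float]:
    return {"dtan": 0.02, "drad": 0.03, "cwt": 0.03, "ew_count": 0.12}


def _default_sd_cell() -> dict[str, float]:
    # per-cell log-scale noise; "drad" defaults to ew_drad_ring_cv
    return {"dtan": 0.03, "cwt": 0.06, "ew_count": 0.05}


@dataclasses.dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic stand generator.

    Effect sizes are linear on the natural scale (um per metre of height,
    um per year of age, percent latewood per year of age); variance
    components are log-scale standard deviations per affected parameter.
    """

    n_plots: int = 3
    trees_per_plot: int = 10
    years: tuple[int, ...] = (2008, 2009, 2010, 2011, 2012)
    plots: tuple[PlotSpec, ...] = DEFAULT_PLOTS

    # fixed effects
    dtan_per_height: float = 0.5      # um per m of tree height
    drad_per_height: float = 0.3      # um per m, smaller than the Dtan effect
    cwt_per_age: float = 0.008        # um per year of tree age
    lwpct_per_age: float = 0.03       # percent latewood per year of age

    # baseline anatomy (at reference height / age)
    dtan_mean: float = 28.0           # um, tangential lumen diameter
    ew_drad_mean: float = 32.0        # um, earlywood radial lumen diameter
    lw_drad_mean: float = 8.0         # um, latewood radial lumen diameter
    cwt_ew_mean: float = 2.0          # um, earlywood single wall
    cwt_lw_mean: float = 4.5          # um, latewood single wall
    ref_height: float = 19.0          # m
    ref_age: float = 80.0             # years

    # ring-width driver and latewood block
    ew_cell_count_median: float = 55.0
    lw_cell_count_mean: float = 6.0
    lw_cell_count_sd: float = 1.5
    lw_pct_ref: float = 10.0          # baseline LW%, anchors lwpct_per_age
    transition_width: float = 0.03    # logistic width, fraction of profile

    # variance components (log-scale SDs keyed by EFFECT_PARAMS)
    sd_individual: dict[str, float] = dataclasses.field(
        default_factory=_default_sd_individual)
    sd_year: dict[str, float] = dataclasses.field(
        default_factory=_default_sd_year)
    sd_cell: dict[str, float] = dataclasses.field(
        default_factory=_default_sd_cell)
    sd_plot: float = 0.0              # optional plot-level intercept SD
    ew_drad_ring_cv: float = 0.04     # within-ring CV of EW radial diameter

    # tree sampling
    height_age_copula_rho: float = 0.55   # latent correlation, height vs age
    spatial_autocorr_range: float = 15.0  # m; applied where plot enables it

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_plots < 1 or self.n_plots > len(self.plots):
            raise ConfigError(
                f"n_plots must be in [1, {len(self.plots)}], got {self.n_plots}")
        if self.trees_per_plot < 2:
            raise ConfigError(
                f"trees_per_plot must be >= 2, got {self.trees_per_plot}")
        if not self.years:
            raise ConfigError("years must be non-empty")
        for plot in self.plots[: self.n_plots]:
            for field in ("height_range", "age_range", "dbh_range"):
                lo, hi = getattr(plot, field)
                if not lo < hi:
                    raise ConfigError(
                        f"plot {plot.code}: {field} must satisfy min < max")
        for name in ("dtan_per_height", "drad_per_height",
                     "cwt_per_age", "lwpct_per_age"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.drad_per_height > self.dtan_per_height:
            raise ConfigError(
                "drad_per_height must not exceed dtan_per_height")
        for name in ("sd_individual", "sd_year", "sd_cell"):
            table = getattr(self, name)
            if any(v < 0 for v in table.values()):
                raise ConfigError(f"{name} entries must be >= 0")
        if self.lw_cell_count_sd < 0 or self.sd_plot < 0:
            raise ConfigError("lw_cell_count_sd and sd_plot must be >= 0")
        if self.ew_drad_ring_cv < 0:
            raise ConfigError("ew_drad_ring_cv must be >= 0")
        if self.spatial_autocorr_range < 0:
            raise ConfigError("spatial_autocorr_range must be >= 0")
        if not 0 <= self.height_age_copula_rho < 1:
            raise ConfigError("height_age_copula_rho must be in [0, 1)")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["years"] = list(self.years)
        data["plots"] = [dataclasses.asdict(p) for p in self.plots]
        for p in data["plots"]:
            for field in ("height_range", "age_range", "dbh_range"):
                p[field] = list(p[field])
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        data = dict(data)
        if "plots" in data:
            plots = []
            for p in data["plots"]:
                p = dict(p)
                for field in ("height_range", "age_range", "dbh_range"):
                    p[field] = tuple(p[field])
                plots.append(PlotSpec(**p))
            data["plots"] = tuple(plots)
        if "years" in data:
            data["years"] = tuple(data["years"])
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def _cell_sd(self, param: str) -> float:
        if param == "drad":
            return self.ew_drad_ring_cv
        return self.sd_cell.get(param, 0.0)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth ledger of one simulated stand.

    Stores everything needed to reconstruct the exact parameters of any
    ring: realized tree biometry and in-plot positions (metres), the
    individual, year and plot random effects per parameter, and the config.
    """

    config: GeneratorConfig
    trees: list[TreeMeta]
    positions: pd.DataFrame       # index tree_id; columns plot, x, y (m)
    ind_effects: pd.DataFrame     # index tree_id; columns EFFECT_PARAMS
    year_effects: pd.DataFrame    # index year; columns EFFECT_PARAMS
    plot_effects: pd.Series       # index plot code

    def tree_index(self, tree_id: str) -> int:
        return list(self.positions.index).index(tree_id)

    def tree(self, tree_id: str) -> TreeMeta:
        for t in self.trees:
            if t.tree_id == tree_id:
                return t
        raise KeyError(tree_id)

    def ring_params(self, tree_id: str, year: int) -> dict[str, float]:
        """Exact deterministic (pre cell-noise) parameters of one ring."""
        return _ring_params(self.tree(tree_id), int(year), self, self.config)


# ---------------------------------------------------------------------------
# Stand sampling
# ---------------------------------------------------------------------------

def sample_stand(config: GeneratorConfig) -> tuple[list[TreeMeta], SyntheticTruth]:
    """Draw tree biometry, positions and random effects for one stand.

    Heights, ages and DBH have uniform marginals over the plot ranges
    (maximizing spread) coupled through a Gaussian copula so that height and
    age correlate positively (target Pearson r of roughly 0.4-0.7) without
    being collinear.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(
        config.rng_seed, spawn_key=(0,)))
    rho = config.height_age_copula_rho
    corr = np.array([[1.0, rho, 0.70],
                     [rho, 1.0, 0.40],
                     [0.70, 0.40, 1.0]])
    chol = np.linalg.cholesky(corr)

    trees: list[TreeMeta] = []
    pos_rows = []
    ind_rows = []
    plot_effects = {}
    for p, plot in enumerate(config.plots[: config.n_plots]):
        code_letter = plot.code.split("-")[-1] if "-" in plot.code else plot.code
        side = math.sqrt(plot.area_ha * 10_000.0)
        xy = rng.uniform(0.0, side, size=(config.trees_per_plot, 2))
        z = rng.standard_normal((config.trees_per_plot, 3)) @ chol.T
        u = norm.cdf(z)
        heights = plot.height_range[0] + u[:, 0] * np.diff(plot.height_range)[0]
        ages = plot.age_range[0] + u[:, 1] * np.diff(plot.age_range)[0]
        dbhs = plot.dbh_range[0] + u[:, 2] * np.diff(plot.dbh_range)[0]
        plot_effects[plot.code] = (rng.normal(0.0, config.sd_plot)
                                   if config.sd_plot > 0 else 0.0)

        # individual random effects, optionally spatially autocorrelated
        eff = {}
        L = config.spatial_autocorr_range if plot.spatial_autocorr else 0.0
        for param in EFFECT_PARAMS:
            sd = config.sd_individual.get(param, 0.0)
            draws = rng.standard_normal(config.trees_per_plot)
            if L > 0 and sd > 0:
                d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
                K = np.exp(-d2 / (2.0 * L * L))
                K += 1e-9 * np.eye(len(K))
                draws = np.linalg.cholesky(K) @ draws
            eff[param] = sd * draws

        for i in range(config.trees_per_plot):
            tree_id = f"{code_letter}{i + 1:02d}"
            lat = plot.latitude + xy[i, 1] / _M_PER_DEG_LAT
            lon = plot.longitude + xy[i, 0] / (
                _M_PER_DEG_LAT * math.cos(math.radians(plot.latitude)))
            trees.append(TreeMeta(
                tree_id=tree_id, plot=plot.code,
                latitude=lat, longitude=lon, elevation=plot.elevation,
                height=float(heights[i]), age=float(round(ages[i])),
                dbh=float(dbhs[i])))
            pos_rows.append({"tree_id": tree_id, "plot": plot.code,
                             "x": xy[i, 0], "y": xy[i, 1]})
            ind_rows.append({"tree_id": tree_id,
                             **{param: eff[param][i]
                                for param in EFFECT_PARAMS}})

    year_effects = pd.DataFrame(
        {param: rng.normal(0.0, config.sd_year.get(param, 0.0),
                           size=len(config.years))
         for param in EFFECT_PARAMS},
        index=pd.Index(config.years, name="year"))

    truth = SyntheticTruth(
        config=config,
        trees=trees,
        positions=pd.DataFrame(pos_rows).set_index("tree_id"),
        ind_effects=pd.DataFrame(ind_rows).set_index("tree_id"),
        year_effects=year_effects,
        plot_effects=pd.Series(plot_effects, name="plot_effect"),
    )
    return trees, truth


# ---------------------------------------------------------------------------
# Ring simulation
# ---------------------------------------------------------------------------

def _ring_params(tree: TreeMeta, year: int, truth: SyntheticTruth,
                 config: GeneratorConfig) -> dict[str, float]:
    """Deterministic ring-level parameters for (tree, year)."""
    if tree.tree_id not in truth.ind_effects.index:
        raise GenerationError(f"tree {tree.tree_id!r} not present in truth")
    if year not in truth.year_effects.index:
        raise GenerationError(f"year {year} not simulated in this stand")
    ind = truth.ind_effects.loc[tree.tree_id]
    yr = truth.year_effects.loc[year]
    plot_eff = float(truth.plot_effects.get(tree.plot, 0.0))
    dh = tree.height - config.ref_height
    da = tree.age - config.ref_age

    params = {
        "dtan": (config.dtan_mean + config.dtan_per_height * dh)
        * math.exp(ind["dtan"] + yr["dtan"] + plot_eff),
        "ew_drad": (config.ew_drad_mean + config.drad_per_height * dh)
        * math.exp(ind["drad"] + yr["drad"] + plot_eff),
        "lw_drad": config.lw_drad_mean
        * math.exp(ind["drad"] + yr["drad"] + plot_eff),
        "cwt_ew": (config.cwt_ew_mean + config.cwt_per_age * da)
        * math.exp(ind["cwt"] + yr["cwt"]),
        "cwt_lw": (config.cwt_lw_mean + config.cwt_per_age * da)
        * math.exp(ind["cwt"] + yr["cwt"]),
        "n_ew_mean": config.ew_cell_count_median
        * math.exp(ind["ew_count"] + yr["ew_count"]),
        "n_lw_mean": config.lw_cell_count_mean
        * (1.0 + config.lwpct_per_age * da / config.lw_pct_ref),
    }
    for name, value in params.items():
        if value <= 0:
            raise GenerationError(
                f"infeasible parameter combination: {name} = {value:.3g} "
                f"for tree {tree.tree_id}, year {year}")
    return params


def simulate_ring(tree: TreeMeta, year: int, truth: SyntheticTruth,
                  config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the 1-mm strip of one tree ring as a canonical cell table.

    Each radial file holds an earlywood plateau followed by a logistic
    decline (radial lumen shrinking, walls thickening) placed so that the
    deterministic Mork index crosses 1 exactly at the start of the file's
    latewood block; the latewood cell count per file is drawn from a
    truncated normal (>= 3 cells).
    """
    params = _ring_params(tree, int(year), truth, config)
    rng = np.random.default_rng(np.random.SeedSequence(
        config.rng_seed,
        spawn_key=(1, truth.tree_index(tree.tree_id), int(year))))

    dtan, ew_drad = params["dtan"], params["ew_drad"]
    lw_drad = params["lw_drad"]
    cwt_ew, cwt_lw = params["cwt_ew"], params["cwt_lw"]

    # logistic level at which the Mork index equals 1
    denom = 4.0 * (cwt_lw - cwt_ew) + (ew_drad - lw_drad)
    s_star = (ew_drad - 4.0 * cwt_ew) / denom if denom != 0 else math.nan
    if not 0.0 < s_star < 1.0 or not math.isfinite(s_star):
        raise GenerationError(
            f"infeasible parameter combination: Mork index does not cross 1 "
            f"within the profile (tree {tree.tree_id}, year {year})")

    n_files = int(1000.0 // (dtan + 2.0 * cwt_ew))
    if n_files < 1:
        raise GenerationError(
            f"infeasible parameter combination: tangential cell pitch "
            f"exceeds the 1-mm strip (tree {tree.tree_id}, year {year})")

    sd_dtan = config._cell_sd("dtan")
    sd_drad = config._cell_sd("drad")
    sd_cwt = config._cell_sd("cwt")
    sd_count = config._cell_sd("ew_count")
    w = config.transition_width
    logit_s = math.log(s_star / (1.0 - s_star))

    frames = []
    truth_n_lw: dict[int, int] = {}
    for f in range(1, n_files + 1):
        n_ew = max(1, round(params["n_ew_mean"]
                            * math.exp(rng.normal(0.0, sd_count))))
        n_lw = max(3, round(rng.normal(params["n_lw_mean"],
                                       config.lw_cell_count_sd)))
        truth_n_lw[f] = n_lw
        n = n_ew + n_lw
        r = (np.arange(1, n + 1) - 0.5) / n
        c = n_ew / n - w * logit_s           # boundary between EW and LW runs
        s = 1.0 / (1.0 + np.exp(-(r - c) / w))

        drad = (ew_drad - (ew_drad - lw_drad) * s) \
            * np.exp(rng.normal(0.0, sd_drad, n))
        dt = dtan * np.exp(rng.normal(0.0, sd_dtan, n))
        cwt_base = cwt_ew + (cwt_lw - cwt_ew) * s
        walls = cwt_base[:, None] * np.exp(rng.normal(0.0, sd_cwt, (n, 4)))
        cwt_pi, cwt_ba, cwt_le, cwt_ri = walls.T

        la = math.pi / 4.0 * drad * dt
        extent_rad = drad + cwt_le + cwt_ri
        extent_tan = dt + cwt_pi + cwt_ba
        cwa = extent_rad * extent_tan - la
        if (cwa <= 0).any() or (drad <= 0).any() or (dt <= 0).any():
            raise GenerationError(
                f"infeasible parameter combination: non-positive geometry "
                f"(tree {tree.tree_id}, year {year}, file {f})")
        cum = np.cumsum(extent_rad)
        rel_pos = (cum - extent_rad / 2.0) / cum[-1]

        frames.append(pd.DataFrame({
            "tree_id": tree.tree_id, "year": int(year),
            "file_index": f, "cell_index": np.arange(1, n + 1),
            "rel_pos": rel_pos, "drad_lumen": drad, "dtan_lumen": dt,
            "lumen_area": la, "cwt_pi": cwt_pi, "cwt_ba": cwt_ba,
            "cwt_le": cwt_le, "cwt_ri": cwt_ri, "cwa": cwa,
        }))
    ring = pd.concat(frames, ignore_index=True)[CELL_COLUMNS]
    # ground-truth latewood cell count per file, for recovery checks
    ring.attrs["truth_n_lw"] = truth_n_lw
    return ring


def simulate_dataset(config: GeneratorConfig) -> tuple[
        dict[tuple[str, int], pd.DataFrame], pd.DataFrame, SyntheticTruth]:
    """Simulate a whole stand: one cell table per (tree, year) ring.

    Returns the per-ring cell tables, the tree metadata table and the
    ground-truth ledger.  Total rings = trees x years.
    """
    trees, truth = sample_stand(config)
    rings: dict[tuple[str, int], pd.DataFrame] = {}
    for tree in trees:
        for year in config.years:
            rings[(tree.tree_id, year)] = simulate_ring(
                tree, year, truth, config)
    return rings, meta_frame(trees), truth


def concat_rings(rings: Mapping[tuple[str, int], pd.DataFrame]) -> pd.DataFrame:
    """Stack per-ring cell tables into one canonical cell table."""
    return pd.concat(list(rings.values()), ignore_index=True)
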