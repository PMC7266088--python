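"""Statistical chain for ring-trait tables.

Covers, in the order an analysis runs: best-of-three curve fitting
(linear / exponential / logarithmic, compared by R-squared each in its own
fitted space), year-wise PCA on standardized traits, backward-selected
multiple regression of PC scores on tree height, age and plot (nested
likelihood-ratio tests), Mantel tests of geographic vs trait-space
distances, Procrustes (protest-style) tests of inter-annual ordination
stability, and a coefficient-of-variation ranking of trait stability.

The permutation machinery (Mantel and Procrustes nulls) is implemented from
first principles: one-tailed tests with the +1 convention
``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)``, so p is never 0.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from scipy.stats import chi2

from .errors import (CollinearityError, ComputationError,
                     InsufficientDataError)

# ---------------------------------------------------------------------------
# Best-of-three curve fits
# ---------------------------------------------------------------------------

CURVE_FAMILIES = ("linear", "exponential", "logarithmic")


@dataclasses.dataclass(frozen=True)
class CurveFit:
    """One bivariate fit; slope/intercept live in the fitted space
    (ln y for exponential, ln x for logarithmic)."""

    family: str
    intercept: float
    slope: float
    r_squared: float
    p_value: float
    n: int


def fit_best_curve(x: Sequence[float], y: Sequence[float]) -> CurveFit:
    """Fit linear, exponential and logarithmic models; keep the highest R^2.

    The exponential model regresses ln(y) on x (needs y > 0), the
    logarithmic regresses y on ln(x) (needs x > 0); ineligible families are
    skipped.  R^2 is computed in each family's own fitted space, which is a
    goodness-of-fit comparison, not a likelihood comparison.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(x) < 3:
        raise InsufficientDataError(
            f"need at least 3 observations, got {len(x)}")
    candidates: list[CurveFit] = []
    transforms = {
        "linear": (x, y),
        "exponential": (x, np.log(y, where=y > 0,
                                  out=np.full_like(y, np.nan))),
        "logarithmic": (np.log(x, where=x > 0,
                               out=np.full_like(x, np.nan)), y),
    }
    for family in CURVE_FAMILIES:
        if family == "exponential" and (y <= 0).any():
            continue
        if family == "logarithmic" and (x <= 0).any():
            continue
        fx, fy = transforms[family]
        res = scipy.stats.linregress(fx, fy)
        candidates.append(CurveFit(
            family=family, intercept=float(res.intercept),
            slope=float(res.slope), r_squared=float(res.rvalue ** 2),
            p_value=float(res.pvalue), n=len(x)))
    if not candidates:
        raise ComputationError("no eligible curve family for these data")
    return max(candidates, key=lambda fit: fit.r_squared)


def pairwise_trait_scan(table: pd.DataFrame,
                        pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Best-of-three fits for selected trait pairs.

    No multiple-testing correction is applied to the selection itself; a
    Benjamini-Hochberg adjusted column ``p_bh`` is emitted alongside for the
    reader.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for x_name, y_name in pairs:
        sub = pd.DataFrame({"x": table[x_name],
                            "y": table[y_name]}).dropna()
        fit = fit_best_curve(sub["x"], sub["y"])
        rows.append({"x": x_name, "y": y_name, "family": fit.family,
                     "intercept": fit.intercept, "slope": fit.slope,
                     "r_squared": fit.r_squared, "p_value": fit.p_value,
                     "n": fit.n})
    result = pd.DataFrame(rows)
    if len(result):
        result["p_bh"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result


# ---------------------------------------------------------------------------
# Year-wise PCA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PCAModel:
    """PCA of one year's standardized trait matrix."""

    year: int
    trait_names: list[str]
    means: np.ndarray
    sds: np.ndarray               # n-1 denominator
    loadings: np.ndarray          # traits x components, orthonormal columns
    scores: pd.DataFrame          # individuals x components
    variance_share: np.ndarray    # percent, sums to 100

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_year(traits: pd.DataFrame, year: int, *,
             on_constant: str = "drop") -> PCAModel:
    """PCA of a (individuals x traits) matrix after column standardization.

    Traits with missing values are removed (trait-completeness filtering);
    constant traits (zero SD) are dropped with a warning by default, or
    raise when ``on_constant="raise"``.  Components carry a deterministic
    sign: the loading of largest magnitude on each component is positive.
    """
    if len(traits) < 3:
        raise InsufficientDataError(
            f"PCA needs >= 3 individuals, got {len(traits)}")
    numeric = traits.select_dtypes("number")
    complete = numeric.dropna(axis=1)
    dropped_na = sorted(set(numeric.columns) - set(complete.columns))
    if dropped_na:
        warnings.warn(f"PCA {year}: dropping incomplete trait(s): "
                      f"{', '.join(dropped_na)}", stacklevel=2)
    sds = complete.std(ddof=1)
    constant = sorted(sds.index[sds == 0.0])
    if constant:
        if on_constant == "raise":
            raise ComputationError(
                f"constant trait(s) with zero SD: {', '.join(constant)}")
        warnings.warn(f"PCA {year}: dropping constant trait(s): "
                      f"{', '.join(constant)}", stacklevel=2)
        complete = complete.drop(columns=constant)
        sds = sds.drop(index=constant)
    if complete.shape[1] == 0:
        raise ComputationError("no usable traits for PCA")

    means = complete.mean()
    z = (complete - means) / sds
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    keep = s > s[0] * 1e-12 if s[0] > 0 else slice(0, 0)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    share = 100.0 * s ** 2 / (s ** 2).sum()
    return PCAModel(
        year=int(year),
        trait_names=list(complete.columns),
        means=means.to_numpy(),
        sds=sds.to_numpy(),
        loadings=vt.T,
        scores=pd.DataFrame(scores, index=complete.index,
                            columns=[f"PC{k + 1}" for k in range(len(s))]),
        variance_share=share,
    )


# ---------------------------------------------------------------------------
# Backward-selected multiple regression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SelectionResult:
    """Outcome of backward selection of PC ~ height + age + plot."""

    retained: list[str]
    coefficients: pd.DataFrame    # term, estimate, std_err, p_value
    trail: pd.DataFrame           # step, dropped, lr_stat, df, p_value
    type2_table: pd.DataFrame     # companion Type-II F table (full model)


_TERMS = {"height": "height", "age": "age", "plot": "C(plot)"}


def _formula(terms: Sequence[str]) -> str:
    rhs = " + ".join(_TERMS[t] for t in terms) if terms else "1"
    return f"response ~ {rhs}"


def backward_select(response: Sequence[float], covariates: pd.DataFrame,
                    alpha: float = 0.05) -> SelectionResult:
    """Backward selection by nested likelihood-ratio tests.

    Starts from ``response ~ height + age + plot`` (plot categorical, tested
    as a block) and repeatedly drops the covariate whose removal gives the
    largest LRT p-value above ``alpha``; stops when every remaining drop has
    p <= alpha.
    """
    data = covariates[["height", "age", "plot"]].copy()
    data["response"] = np.asarray(response, dtype=float)
    full = smf.ols(_formula(["height", "age", "plot"]), data).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise CollinearityError("rank-deficient design matrix")
    if len(data) <= full.model.exog.shape[1]:
        raise InsufficientDataError(
            "need more observations than model parameters")

    from statsmodels.stats.anova import anova_lm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        type2 = anova_lm(full, typ=2)

    n_obs = len(data)
    tss = float(np.var(data["response"])) * n_obs

    def lr_stat(rss_full: float, rss_reduced: float) -> float:
        # Gaussian LRT from residual sums of squares; an exact fit in both
        # models (RSS ~ 0) counts as no evidence for the larger one.
        eps = 1e-12 * max(tss, 1.0)
        if rss_full <= eps and rss_reduced <= eps:
            return 0.0
        if rss_full <= eps:
            return math.inf
        return n_obs * math.log(rss_reduced / rss_full)

    remaining = ["height", "age", "plot"]
    trail_rows = []
    current = full
    step = 0
    while remaining:
        tests = []
        for term in remaining:
            reduced = smf.ols(
                _formula([t for t in remaining if t != term]), data).fit()
            stat = lr_stat(float(current.ssr), float(reduced.ssr))
            df = current.df_model - reduced.df_model
            p = float(chi2.sf(max(stat, 0.0), df))
            tests.append((term, float(stat), int(df), p, reduced))
        term, stat, df, p, reduced = max(tests, key=lambda t: t[3])
        if p <= alpha:
            break
        step += 1
        trail_rows.append({"step": step, "dropped": term,
                           "lr_stat": stat, "df": df, "p_value": p})
        remaining.remove(term)
        current = reduced

    coef = pd.DataFrame({
        "term": current.params.index,
        "estimate": current.params.to_numpy(),
        "std_err": current.bse.to_numpy(),
        "p_value": current.pvalues.to_numpy(),
    })
    trail = pd.DataFrame(trail_rows,
                         columns=["step", "dropped", "lr_stat", "df",
                                  "p_value"])
    return SelectionResult(retained=remaining, coefficients=coef,
                           trail=trail, type2_table=type2)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None


def _check_distance_matrix(d: np.ndarray, name: str) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")


def mantel_test(d_geo: np.ndarray, d_trait: np.ndarray,
                n_perm: int = 999, seed: int | None = None) -> MantelResult:
    """One-tailed (greater) Mantel test between two distance matrices.

    The statistic is the Pearson correlation over the strict lower
    triangles; the null permutes rows and columns of the second matrix
    simultaneously.
    """
    d_geo = np.asarray(d_geo, dtype=float)
    d_trait = np.asarray(d_trait, dtype=float)
    _check_distance_matrix(d_geo, "d_geo")
    _check_distance_matrix(d_trait, "d_trait")
    if d_geo.shape != d_trait.shape:
        raise ValueError("distance matrices must have the same order")
    n = d_geo.shape[0]
    rows, cols = np.tril_indices(n, k=-1)
    a = d_geo[rows, cols]

    def corr_with(perm: np.ndarray) -> float:
        b = d_trait[np.ix_(perm, perm)][rows, cols]
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr_with(np.arange(n))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if corr_with(rng.permutation(n)) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Procrustes / protest
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ProcrustesResult:
    r: float
    m_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


def _normalize_configuration(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    ss = (x ** 2).sum()
    if ss == 0:
        raise ComputationError("degenerate configuration (zero spread)")
    return x / math.sqrt(ss)


def procrustes_protest(x: np.ndarray, y: np.ndarray,
                       n_perm: int = 999,
                       seed: int | None = None) -> ProcrustesResult:
    """Symmetric Procrustes correlation with a permutation test (protest).

    Both configurations (rows = the same individuals in the same order) are
    centered and scaled to unit sum of squares; the optimal rotation comes
    from the SVD of Y'X, giving the residual statistic
    ``m^2 = 1 - (sum of singular values)^2`` and the correlation
    ``r = sqrt(1 - m^2)``.  The null permutes the rows of one configuration.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("configurations must have the same shape")
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D configuration with >= 2 rows")
    xn = _normalize_configuration(x)
    yn = _normalize_configuration(y)

    def proc_r(perm: np.ndarray | None) -> float:
        yp = yn if perm is None else _normalize_configuration(yn[perm])
        sigma = np.linalg.svd(yp.T @ xn, compute_uv=False)
        return float(min(sigma.sum(), 1.0))

    trace = proc_r(None)
    m2 = 1.0 - trace ** 2
    r_obs = math.sqrt(max(1.0 - m2, 0.0))
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    count = 0
    for _ in range(n_perm):
        if proc_r(rng.permutation(n)) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ProcrustesResult(r=r_obs, m_squared=m2, p_value=p,
                            n_permutations=n_perm, seed=seed)


def procrustes_year_pairs(models: Sequence[PCAModel], *, n_components: int = 2,
                          n_perm: int = 999,
                          seed: int | None = None) -> pd.DataFrame:
    """Protest over every pair of year-wise PCA score configurations."""
    rows = []
    rng = np.random.default_rng(seed)
    for ma, mb in itertools.combinations(models, 2):
        common = ma.scores.index.intersection(mb.scores.index)
        k = min(n_components, ma.n_components, mb.n_components)
        res = procrustes_protest(
            ma.scores.loc[common].iloc[:, :k].to_numpy(),
            mb.scores.loc[common].iloc[:, :k].to_numpy(),
            n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        rows.append({"year_a": ma.year, "year_b": mb.year, "r": res.r,
                     "m_squared": res.m_squared, "p_value": res.p_value,
                     "n": len(common)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trait stability (CV ranking)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StabilityReport:
    """Per-trait inter-annual stability summary.

    ``table`` has one row per trait: mean CV across individuals (percent),
    the range (max - min) of individual CVs, flags at the 10% (mean) and
    20% (range) thresholds, and the descending rank by mean CV."""

    table: pd.DataFrame

    def flagged(self) -> pd.DataFrame:
        t = self.table
        return t[t["flag_mean_gt10"] & t["flag_range_gt20"]]


def trait_cv(traits: pd.DataFrame,
             trait_columns: Sequence[str] | None = None) -> StabilityReport:
    """Coefficient-of-variation stability ranking across years.

    For each individual and trait, CV = 100 * SD / mean over years (SD with
    the n-1 denominator); per-trait summaries are the mean and the range of
    individual CVs.  Individuals observed in fewer than two years are
    dropped with a warning; a trait whose per-individual mean is ~0 gets a
    missing CV for that individual.
    """
    if trait_columns is None:
        trait_columns = [c for c in traits.columns
                         if c not in ("tree_id", "year")]
    counts = traits.groupby("tree_id")["year"].nunique()
    short = counts.index[counts < 2]
    if len(short) == len(counts):
        raise InsufficientDataError(
            "trait stability needs >= 2 years per individual")
    if len(short):
        warnings.warn(f"dropping individual(s) with < 2 years: "
                      f"{', '.join(map(str, short))}", stacklevel=2)
        traits = traits[~traits["tree_id"].isin(short)]

    grouped = traits.groupby("tree_id")[list(trait_columns)]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    near_zero = means.abs() <= 1e-12
    if near_zero.any().any():
        bad = sorted(means.columns[near_zero.any()])
        warnings.warn(f"CV undefined (zero mean) for trait(s): "
                      f"{', '.join(bad)}", stacklevel=2)
    cvs = 100.0 * sds / means.where(~near_zero)

    table = pd.DataFrame({
        "mean_cv": cvs.mean(),
        "cv_range": cvs.max() - cvs.min(),
    })
    table["flag_mean_gt10"] = table["mean_cv"] > 10.0
    table["flag_range_gt20"] = table["cv_range"] > 20.0
    table["rank"] = table["mean_cv"].rank(ascending=False, method="min")
    table = table.sort_values("rank")
    table.index.name = "trait"
    return StabilityReport(table=table)


# ---------------------------------------------------------------------------
# Geographic distances
# ---------------------------------------------------------------------------

def geographic_distances(meta: pd.DataFrame) -> np.ndarray:
    """Pairwise tree distances in metres (local equirectangular)."""
    lat = np.radians(meta["latitude"].to_numpy())
    lon = np.radians(meta["longitude"].to_numpy())
    lat0 = lat.mean()
    earth_r = 6_371_000.0
    x = earth_r * lon * math.cos(lat0)
    y = earth_r * lat
    xy = np.column_stack([x, y])
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def score_distances(scores: pd.DataFrame, n_components: int = 3) -> np.ndarray:
    """Euclidean distances between individuals over the leading PCs."""
    z = scores.iloc[:, :n_components].to_numpy()
    diff = z[:, None, :] - z[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))
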