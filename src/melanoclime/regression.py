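"""Trait-environment regression battery.

Assemblage- and species-level linear models with z-scaled predictors,
a penalized tensor-product spline trend surface over geographic
coordinates (GCV-tuned) to absorb spatially autocorrelated latent
variation, hierarchical partitioning of R^2 into independent predictor
contributions, grouped full-interaction models (realms, families,
activity classes), chytridiomycosis-severity models, and Moran's I
correlograms of residuals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .phylo import PGLSResult, pgls_fit

logger = logging.getLogger(__name__)

CI_Z = 1.96  # normal-approximation 95% interval half-width in SE units


# ---------------------------------------------------------------------------
# z-scaling

@dataclass
class ZScaler:
    means: pd.Series
    sds: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.means.index] - self.means) / self.sds

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        return df[self.means.index] * self.sds + self.means


def zscale(df: pd.DataFrame):
    """Centre and scale each column to mean 0, sd 1 (ddof=0).

    Returns (scaled frame, ZScaler holding the transform parameters).
    """
    df = pd.DataFrame(df).astype(float)
    sds = df.std(ddof=0)
    if (sds <= 0).any():
        bad = list(sds.index[sds <= 0])
        raise ValueError(f"constant column(s): {bad}")
    scaler = ZScaler(df.mean(), sds)
    return scaler.transform(df), scaler


# ---------------------------------------------------------------------------
# Ordinary least squares

@dataclass
class RegressionResult:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r_squared: float
    adj_r_squared: float
    n: int
    df_resid: int
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "slope": self.coef, "se": self.se,
                             "t": self.t, "p": self.p})

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {"slope": self.coef[i], "se": self.se[i], "t": self.t[i], "p": self.p[i]}


def ols_fit(y, X: pd.DataFrame, weights=None, add_intercept: bool = True) -> RegressionResult:
    """Least squares with intercept; two-sided t tests on each coefficient."""
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    terms = list(X.columns)
    M = X.to_numpy()
    if add_intercept:
        M = np.column_stack([np.ones(len(y)), M])
        terms = ["intercept"] + terms
    n, p = M.shape
    if n <= p:
        raise ValueError("need more observations than coefficients")
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Mw, yw = M * w[:, None], y * w
    else:
        Mw, yw = M, y
    if np.linalg.matrix_rank(Mw) < p:
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(Mw, yw, rcond=None)
    fitted = M @ beta
    resid = y - fitted
    rw = yw - Mw @ beta
    rss = float(rw @ rw)
    ybar = float(np.average(y, weights=weights)) if weights is not None else float(y.mean())
    if weights is not None:
        tss = float(np.sum(np.asarray(weights) * (y - ybar) ** 2))
    else:
        tss = float(np.sum((y - ybar) ** 2))
    df = n - p
    s2 = rss / df
    cov = s2 * np.linalg.inv(Mw.T @ Mw)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    pval = 2 * stats.t.sf(np.abs(tstat), df)
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / df if tss > 0 else np.nan
    return RegressionResult(terms, beta, se, tstat, pval, r2, adj, n, df, resid, fitted)


# ---------------------------------------------------------------------------
# Penalized tensor-product spline trend surface

def _bspline_basis(x: np.ndarray, n_basis: int) -> np.ndarray:
    """Cubic B-spline design matrix on [0, 1] with an open uniform knot vector."""
    if n_basis < 4:
        raise ValueError("need at least 4 basis functions per axis")
    t = np.r_[np.zeros(3), np.linspace(0.0, 1.0, n_basis - 2), np.ones(3)]
    x = np.clip(x, 1e-12, 1 - 1e-12)
    return BSpline.design_matrix(x, t, k=3).toarray()


def _unit_scale(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("degenerate coordinate axis")
    return (v - lo) / (hi - lo)


def _second_diff_penalty(k: int) -> np.ndarray:
    D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


@dataclass
class TrendSurfaceResult:
    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r_squared: float
    smoothing: float
    edf_surface: float
    edf_total: float
    n: int
    surface_coef: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)
    gcv_path: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "slope": self.coef, "se": self.se,
                             "t": self.t, "p": self.p})

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {"slope": self.coef[i], "se": self.se[i], "t": self.t[i], "p": self.p[i]}


def trend_surface_fit(y, X: pd.DataFrame, coords: np.ndarray,
                      n_basis: tuple[int, int] = (10, 10),
                      smoothing: float | None = None,
                      gcv_grid=None, gcv_slack: float = 1.1,
                      add_intercept: bool = True) -> TrendSurfaceResult:
    """Linear terms plus a penalized spline surface over 2-D coordinates.

    The surface is a tensor product of cubic B-splines (default 10x10)
    with a second-order difference penalty on each axis; its smoothing
    parameter is chosen by generalized cross-validation over a
    log-spaced grid unless given.  The surface is constrained to sum to
    zero over the data so it cannot absorb the intercept; the penalty's
    remaining null space spans planar trends (x, y, xy), which is the
    infinite-smoothing limit.  Linear-term inference uses the penalized
    fit's effective residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be n x 2")
    n = len(y)
    kx, ky = n_basis
    if kx * ky >= n:
        raise ValueError("surface basis must be smaller than n")

    terms = list(X.columns)
    M = X.to_numpy()
    if add_intercept:
        M = np.column_stack([np.ones(n), M])
        terms = ["intercept"] + terms
    p_lin = M.shape[1]

    Bx = _bspline_basis(_unit_scale(coords[:, 0]), kx)
    By = _bspline_basis(_unit_scale(coords[:, 1]), ky)
    Z = (Bx[:, :, None] * By[:, None, :]).reshape(n, kx * ky)
    P = np.kron(_second_diff_penalty(kx), np.eye(ky)) + np.kron(np.eye(kx), _second_diff_penalty(ky))

    # sum-to-zero constraint over the data: removes the constant direction
    c = Z.sum(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(c, full_matrices=True)
    Q = Vt[1:].T  # (K, K-1) basis of the constraint null space
    Zc = Z @ Q
    Pc = Q.T @ P @ Q

    D = np.column_stack([M, Zc])
    K = Zc.shape[1]
    DtD = D.T @ D
    Dty = D.T @ y
    Pfull = np.zeros_like(DtD)
    Pfull[p_lin:, p_lin:] = Pc
    yss = float(y @ y)

    def solve_at(lmb):
        A = DtD + lmb * Pfull
        Ainv = np.linalg.inv(A)
        beta = Ainv @ Dty
        rss = yss - 2 * beta @ Dty + beta @ DtD @ beta
        edf = float(np.trace(Ainv @ DtD))
        return beta, max(rss, 0.0), edf, Ainv

    if smoothing is None:
        scale = np.trace(DtD) / max(np.trace(Pfull), 1e-12)
        grid = gcv_grid if gcv_grid is not None else scale * np.logspace(-6, 6, 41)
        path = []
        for lmb in grid:
            _, rss, edf, _ = solve_at(lmb)
            gcv = n * rss / (n - edf) ** 2
            path.append({"smoothing": lmb, "rss": rss, "edf": edf, "gcv": gcv})
        gcv_path = pd.DataFrame(path)
        # one-SE-style rule: GCV minima are flat, and the exact minimiser
        # tends to undersmooth; take the largest smoothing whose GCV is
        # within `gcv_slack` of the minimum
        gmin = gcv_path["gcv"].min()
        ok = gcv_path[gcv_path["gcv"] <= gcv_slack * gmin]
        smoothing = float(ok["smoothing"].max())
    else:
        gcv_path = None

    beta, rss, edf, Ainv = solve_at(smoothing)
    fitted = D @ beta
    resid = y - fitted
    df_eff = n - edf
    s2 = rss / df_eff
    cov = s2 * (Ainv @ DtD @ Ainv)
    se = np.sqrt(np.clip(np.diag(cov)[:p_lin], 0, None))
    bl = beta[:p_lin]
    tstat = bl / se
    pval = 2 * stats.t.sf(np.abs(tstat), df_eff)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    # effective df of the surface block alone
    H_lin_edf = float(np.trace(Ainv[:, :p_lin] @ DtD[:p_lin, :]))
    return TrendSurfaceResult(terms, bl, se, tstat, pval, r2, smoothing,
                              edf - H_lin_edf, edf, n,
                              surface_coef=Q @ beta[p_lin:],
                              residuals=resid, fitted=fitted, gcv_path=gcv_path)


# ---------------------------------------------------------------------------
# Hierarchical partitioning

@dataclass
class HierPartResult:
    predictors: list[str]
    independent: np.ndarray  # IC_j in R^2 units
    full_r_squared: float
    shares: np.ndarray  # IC_j / sum(IC)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"predictor": self.predictors,
                             "independent_contribution": self.independent,
                             "share": self.shares})

    def ranking(self) -> list[str]:
        order = np.argsort(-self.independent)
        return [self.predictors[i] for i in order]


def _subset_r2(y: np.ndarray, X: pd.DataFrame) -> dict[frozenset, float]:
    cols = list(X.columns)
    out = {frozenset(): 0.0}
    for r in range(1, len(cols) + 1):
        for sub in itertools.combinations(cols, r):
            out[frozenset(sub)] = ols_fit(y, X[list(sub)]).r_squared
    return out


def hierarchical_partitioning(y, X: pd.DataFrame, max_k: int = 8) -> HierPartResult:
    """Independent contribution of each predictor to the full-model R^2.

    All 2^k subset models are fitted; predictor j's contribution is the
    average, over all orderings of entry, of the incremental R^2 when j
    joins — computed as the level-weighted mean of increments over
    subsets.  Contributions sum exactly to the full-model R^2.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    cols = list(X.columns)
    k = len(cols)
    if k < 1:
        raise ValueError("need at least one predictor")
    if k > max_k:
        raise ValueError(f"{k} predictors exceeds the combinatorial guard ({max_k})")
    r2 = _subset_r2(y, X)
    full = r2[frozenset(cols)]
    fact = [float(math.factorial(i)) for i in range(k + 1)]
    ic = np.zeros(k)
    for j, col in enumerate(cols):
        others = [c for c in cols if c != col]
        total = 0.0
        for r in range(0, k):
            w = fact[r] * fact[k - r - 1] / fact[k]
            for sub in itertools.combinations(others, r):
                s = frozenset(sub)
                total += w * (r2[s | {col}] - r2[s])
        ic[j] = total
    shares = ic / ic.sum() if ic.sum() != 0 else np.full(k, np.nan)
    return HierPartResult(cols, ic, full, shares)


# ---------------------------------------------------------------------------
# Grouped full-interaction models

@dataclass
class GroupedFitResult:
    """One slope per (environment term, group) from a full-interaction fit."""

    estimates: pd.DataFrame  # group, term, slope, se, ci_lo, ci_hi, t, p, n
    r_squared: float
    n: int
    excluded_groups: dict[str, str]
    ci_convention: str = "slope +/- 1.96*SE"


def grouped_interaction_fit(y, x_terms: pd.DataFrame, groups,
                            min_group_size: int = 1,
                            z_scale: bool = True) -> GroupedFitResult:
    """Full-interaction (cell-means) model: per-group intercepts and one
    slope per (term, group).

    Groups below `min_group_size` are excluded and logged.  Predictors
    are z-scaled over the retained rows before fitting (the default,
    mirroring scaled-and-centred predictors).
    """
    y = pd.Series(np.asarray(y, dtype=float))
    X = pd.DataFrame(x_terms).reset_index(drop=True).astype(float)
    g = pd.Series(list(groups)).astype(str).reset_index(drop=True)
    counts = g.value_counts()
    excluded = {lab: f"n={counts[lab]} < {min_group_size}"
                for lab in counts.index if counts[lab] < min_group_size}
    for lab, why in sorted(excluded.items()):
        logger.info("group %s excluded: %s", lab, why)
    keep = ~g.isin(excluded)
    if keep.sum() == 0 or g[keep].nunique() == 0:
        raise ValueError("no groups retained")
    yk, Xk, gk = y[keep].to_numpy(), X[keep].reset_index(drop=True), g[keep].reset_index(drop=True)
    if z_scale:
        Xk, _ = zscale(Xk)
    labels = sorted(gk.unique())
    design = {}
    for lab in labels:
        ind = (gk == lab).astype(float).to_numpy()
        design[f"group[{lab}]"] = ind
        for term in Xk.columns:
            design[f"{term}:group[{lab}]"] = Xk[term].to_numpy() * ind
    D = pd.DataFrame(design)
    res = ols_fit(yk, D, add_intercept=False)
    rows = []
    for lab in labels:
        nlab = int((gk == lab).sum())
        for term in Xk.columns:
            info = res.term(f"{term}:group[{lab}]")
            rows.append({"group": lab, "term": term, "slope": info["slope"],
                         "se": info["se"],
                         "ci_lo": info["slope"] - CI_Z * info["se"],
                         "ci_hi": info["slope"] + CI_Z * info["se"],
                         "t": info["t"], "p": info["p"], "n": nlab})
    # R^2 about the grand mean (the cell-means model has no global intercept)
    resid = res.residuals
    tss = float(np.sum((yk - yk.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    return GroupedFitResult(pd.DataFrame(rows), r2, int(keep.sum()), excluded)


# ---------------------------------------------------------------------------
# Chytridiomycosis severity models

SEVERITY_FAMILY_MIN = 9  # families with fewer species are excluded


def severity_models(data: pd.DataFrame, tree=None,
                    min_family_size: int = SEVERITY_FAMILY_MIN):
    """Severity ~ colour x productivity, per family and overall.

    `data` needs species_id, severity (unaffected co-occurring species
    coded 0), lightness, EVI and family.  Per family (>= min size) an
    OLS of severity on the z-scaled lightness-by-EVI product is fitted;
    if a tree is given, an overall PGLS with lambda estimated by ML is
    fitted on the same interaction.
    Returns (GroupedFitResult-like per-family table, PGLSResult | None).
    """
    d = data.dropna(subset=["severity", "lightness", "EVI", "family"]).copy()
    counts = d.groupby("family")["species_id"].nunique()
    excluded = {f: f"n={counts[f]} < {min_family_size}"
                for f in counts.index if counts[f] < min_family_size}
    d = d[~d["family"].isin(excluded)]
    if d.empty:
        raise ValueError("no family passes the size threshold")
    zl = (d["lightness"] - d["lightness"].mean()) / d["lightness"].std(ddof=0)
    ze = (d["EVI"] - d["EVI"].mean()) / d["EVI"].std(ddof=0)
    d["interaction"] = zl * ze
    rows = []
    for fam, grp in d.groupby("family", sort=True):
        if grp["interaction"].std(ddof=0) == 0 or len(grp) <= 2:
            excluded[fam] = "degenerate interaction term"
            continue
        res = ols_fit(grp["severity"].to_numpy(), grp[["interaction"]])
        info = res.term("interaction")
        rows.append({"group": fam, "term": "lightness:EVI", "slope": info["slope"],
                     "se": info["se"],
                     "ci_lo": info["slope"] - CI_Z * info["se"],
                     "ci_hi": info["slope"] + CI_Z * info["se"],
                     "t": info["t"], "p": info["p"], "n": len(grp),
                     "r_squared": res.r_squared})
    per_family = GroupedFitResult(pd.DataFrame(rows), np.nan, len(d), excluded)

    overall = None
    if tree is not None:
        ds = d.drop_duplicates("species_id").set_index("species_id")
        overall = pgls_fit(ds["severity"], ds[["interaction"]], tree, lam="estimated")
    return per_family, overall


# ---------------------------------------------------------------------------
# Spatial correlograms (Moran's I)

@dataclass
class Correlogram:
    bounds: np.ndarray  # (n_classes + 1,) distance class edges
    morans_i: np.ndarray
    n_pairs: np.ndarray
    expected: float  # -1/(n-1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"d_lo": self.bounds[:-1], "d_hi": self.bounds[1:],
                             "morans_i": self.morans_i, "n_pairs": self.n_pairs,
                             "expected": self.expected})


def _morans_i_from_pairs(z: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> float:
    n = len(z)
    s_zz = float(z @ z)
    if s_zz == 0:
        raise ValueError("constant residuals")
    w_sum = 2.0 * len(ii)  # symmetric binary weights
    cross = 2.0 * float(np.sum(z[ii] * z[jj]))
    return (n / w_sum) * (cross / s_zz)


def morans_correlogram(residuals, coords, n_classes: int = 10,
                       max_distance: float | None = None) -> Correlogram:
    """Moran's I in equal-width distance classes with binary weights."""
    z = np.asarray(residuals, dtype=float)
    z = z - z.mean()
    coords = np.asarray(coords, dtype=float)
    n = len(z)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu, ju = np.triu_indices(n, k=1)
    dvals = dist[iu, ju]
    if max_distance is None:
        max_distance = float(dvals.max())
    edges = np.linspace(0.0, max_distance, n_classes + 1)
    I = np.full(n_classes, np.nan)
    npairs = np.zeros(n_classes, dtype=int)
    for c in range(n_classes):
        lo, hi = edges[c], edges[c + 1]
        mask = (dvals > lo) & (dvals <= hi) if c > 0 else (dvals > 0) & (dvals <= hi)
        npairs[c] = int(mask.sum())
        if npairs[c] >= 1:
            I[c] = _morans_i_from_pairs(z, iu[mask], ju[mask])
    return Correlogram(edges, I, npairs, -1.0 / (n - 1))


def morans_first_class_permutation(residuals, coords, class_width: float,
                                   n_perm: int = 199, seed: int = 0):
    """Observed first-class Moran's I plus its permutation null mean/sd."""
    z = np.asarray(residuals, dtype=float)
    z = z - z.mean()
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu, ju = np.triu_indices(len(z), k=1)
    mask = (dist[iu, ju] > 0) & (dist[iu, ju] <= class_width)
    ii, jj = iu[mask], ju[mask]
    obs = _morans_i_from_pairs(z, ii, jj)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        zp = rng.permutation(z)
        null[b] = _morans_i_from_pairs(zp, ii, jj)
    return obs, float(null.mean()), float(null.std(ddof=1))
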