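"""Longitudinal statistics for cohort feature tables.

Implements the analysis layer applied to bile-acid concentrations, strain
abundances and model-derived quantities:

* per-factor explained variance (median univariate R2 across features, with
  the >10% confounder flag),
* random-intercept linear mixed models fit by REML with the between/within
  variance ratio profiled by a 1-D search (multivariable associations with
  age, gender, case status and diet covariates),
* per-timepoint ANCOVA differential analysis adjusted for diet covariates,
  with Benjamini-Hochberg FDR within each timepoint family and log2 fold
  changes on covariate-adjusted means,
* one-way ANOVA with Tukey's HSD (studentized-range adjusted p),
* Spearman cross-correlation matrices with BH FDR, and
* tricube locally weighted polynomial regression (loess) for age trends.

Feature tables move through an explicit transform state machine:
raw -> log2 (half-minimum pseudocount) -> autoscaled (zero mean, unit
variance per feature).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "EVResult",
    "DifferentialResult",
    "LMMResult",
    "TukeyResult",
    "PairwiseComparison",
    "SpearmanResult",
    "LoessFit",
    "log2_transform",
    "autoscale",
    "explained_variance",
    "lmm_association",
    "ancova_differential",
    "bh_fdr",
    "tukey_hsd",
    "spearman_fdr",
    "loess_fit",
]

DEFAULT_CONTRASTS = (("P1Ab", "CTR"), ("P2Ab", "CTR"), ("P2Ab", "P1Ab"))


@dataclass
class FeatureTable:
    """Sample x feature matrix plus its transform state."""

    data: pd.DataFrame
    transform_state: str = "raw"  # raw -> log2 -> autoscaled

    @property
    def samples(self) -> List[str]:
        return list(self.data.index)

    @property
    def features(self) -> List[str]:
        return list(self.data.columns)


def log2_transform(table: FeatureTable, pseudocount_rule: str = "half_min_positive") -> FeatureTable:
    """``x -> log2(x + delta_f)`` with a per-feature pseudocount.

    The default rule sets ``delta_f`` to half the smallest positive value of
    feature *f* (features with no positive values get delta 1, mapping their
    zeros to 0).  Only valid on raw, nonnegative tables.
    """
    if table.transform_state != "raw":
        raise ValueError(f"log2_transform requires raw state, got {table.transform_state!r}")
    values = table.data.to_numpy(dtype=float)
    if (values < 0).any():
        bad = table.data.columns[(values < 0).any(axis=0)].tolist()
        raise ValueError(f"negative values in features: {bad}")
    if pseudocount_rule == "half_min_positive":
        delta = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            pos = values[:, j][values[:, j] > 0]
            delta[j] = pos.min() / 2.0 if pos.size else 1.0
    elif pseudocount_rule == "none":
        if (values <= 0).any():
            raise ValueError("pseudocount_rule='none' requires strictly positive values")
        delta = np.zeros(values.shape[1])
    else:
        raise ValueError(f"unknown pseudocount rule {pseudocount_rule!r}")
    out = np.log2(values + delta[None, :])
    return FeatureTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns), "log2")


def autoscale(table: FeatureTable) -> FeatureTable:
    """Center each feature to mean 0 and scale to unit (sample) variance."""
    if table.transform_state != "log2":
        raise ValueError(f"autoscale requires log2 state, got {table.transform_state!r}")
    values = table.data.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning("constant features left at 0 after autoscaling: %s",
                       table.data.columns[zero].tolist())
        sd = np.where(zero, 1.0, sd)
    out = (values - mean) / sd
    out[:, zero] = 0.0
    return FeatureTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns), "autoscaled")


# ---------------------------------------------------------------------------
# Explained variance
# ---------------------------------------------------------------------------


@dataclass
class EVResult:
    factor: str
    median_marginal_r2: float
    per_feature_r2: pd.Series
    is_confounder: bool  # median explained variance above 10%


def _factor_design(values: pd.Series) -> Optional[np.ndarray]:
    """Intercept + encoding of one factor; None if the factor is constant."""
    if values.nunique(dropna=True) < 2:
        return None
    if pd.api.types.is_numeric_dtype(values):
        x = values.to_numpy(dtype=float)
        return np.column_stack([np.ones(len(x)), x])
    dummies = pd.get_dummies(values.astype(str), drop_first=True, dtype=float)
    return np.column_stack([np.ones(len(values)), dummies.to_numpy()])


def explained_variance(
    table: FeatureTable, metadata: pd.DataFrame, factors: Sequence[str]
) -> List[EVResult]:
    """Univariate per-factor R2 per feature; the factor summary is the median.

    Each feature is regressed on each factor alone; the median marginal R2
    across features measures the factor's overall contribution, and factors
    above 10% are flagged as confounders.
    """
    if table.transform_state != "autoscaled":
        raise ValueError("explained_variance requires an autoscaled table")
    meta = metadata.loc[table.data.index]
    Y = table.data.to_numpy(dtype=float)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    results = []
    for factor in factors:
        design = _factor_design(meta[factor])
        if design is None:
            logger.warning("factor %r has no variation; EV set to 0", factor)
            r2 = pd.Series(0.0, index=table.data.columns)
            results.append(EVResult(factor, 0.0, r2, False))
            continue
        ok = ~np.isnan(design).any(axis=1)
        Q, _ = np.linalg.qr(design[ok])
        Yok = Y[ok]
        fitted = Q @ (Q.T @ Yok)
        rss = ((Yok - fitted) ** 2).sum(axis=0)
        tss_ok = ((Yok - Yok.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(tss_ok > 0, 1.0 - rss / tss_ok, 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        med = float(np.median(r2))
        results.append(
            EVResult(factor, med, pd.Series(r2, index=table.data.columns), med > 0.10)
        )
    return results


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (REML, profiled variance ratio)
# ---------------------------------------------------------------------------


@dataclass
class LMMResult:
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    sigma_subject: float
    sigma_resid: float
    variance_ratio: float  # sigma_subject^2 / sigma_resid^2
    method: str  # "reml" or "ols"


def build_design(fixed: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric columns as-is + dummy-coded categoricals."""
    cols = [pd.Series(1.0, index=fixed.index, name="Intercept")]
    for name in fixed.columns:
        col = fixed[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c])
    return pd.concat(cols, axis=1)


def _reml_pieces(X, y, group_slices, lam):
    """X'V^-1X, X'V^-1y, y'V^-1y and log|V| for V = I + lam * J per group."""
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for idx in group_slices:
        Xg = X[idx]
        yg = y[idx]
        m = len(idx)
        shrink = lam / (1.0 + lam * m)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        xtvx += Xg.T @ Xg - shrink * np.outer(sx, sx)
        xtvy += Xg.T @ yg - shrink * sx * sy
        ytvy += yg @ yg - shrink * sy * sy
        logdet += math.log(1.0 + lam * m)
    return xtvx, xtvy, ytvy, logdet


def _reml_criterion(X, y, group_slices, lam):
    n, p = X.shape
    xtvx, xtvy, ytvy, logdet = _reml_pieces(X, y, group_slices, lam)
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    rss = max(ytvy - beta @ xtvy, 1e-300)
    sigma2 = rss / (n - p)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf, None, None, None
    crit = (n - p) * math.log(sigma2) + logdet + logdet_xtvx
    return crit, beta, sigma2, xtvx


def lmm_association(
    y: pd.Series | np.ndarray,
    fixed: pd.DataFrame,
    subjects: Sequence[str],
) -> LMMResult:
    """Random-intercept LMM: ``y = X beta + b_subject + e``.

    Fit by REML; the single variance ratio ``lam = sigma_b^2 / sigma_e^2``
    is profiled by a 1-D search (the criterion at ``lam = 0`` is OLS, so the
    model reduces to ordinary regression when the between-subject variance
    estimate hits the boundary).  Wald p-values per fixed effect.
    """
    X_df = build_design(fixed)
    X = X_df.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != len(yv):
        raise ValueError("y and fixed covariates have different lengths")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify collinear columns by rank-revealing QR on candidates
        keep, bad = [], []
        for j in range(p):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                bad.append(X_df.columns[j])
        raise ValueError(f"singular design; collinear columns: {bad}")

    subj = pd.Series(list(subjects))
    group_slices = [np.asarray(ix) for _, ix in subj.groupby(subj).indices.items()]
    multi_obs = sum(1 for g in group_slices if len(g) >= 2)
    method = "reml"
    if multi_obs == 0:
        warnings.warn(
            "every subject has a single observation; random intercept is "
            "unidentifiable, falling back to OLS"
        )
        method = "ols"

    if method == "reml":
        obj = lambda u: _reml_criterion(X, yv, group_slices, math.exp(u))[0]
        res = minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                              options={"xatol": 1e-6})
        lam_hat = math.exp(res.x)
        crit0 = _reml_criterion(X, yv, group_slices, 0.0)[0]
        if crit0 <= res.fun:
            lam_hat = 0.0
            method = "ols"
    else:
        lam_hat = 0.0

    crit, beta, sigma2, xtvx = _reml_criterion(X, yv, group_slices, lam_hat)
    cov = np.linalg.inv(xtvx) * sigma2
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    names = list(X_df.columns)
    return LMMResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma_subject=math.sqrt(lam_hat * sigma2),
        sigma_resid=math.sqrt(sigma2),
        variance_ratio=lam_hat,
        method=method,
    )


# ---------------------------------------------------------------------------
# ANCOVA differential analysis
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    feature: str
    timepoint: float
    contrast: Tuple[str, str]
    log2_fc: float
    F_stat: float
    p: float
    q: float


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: ``q_(i) = min_{j>=i} m p_(j)/j``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ancova_differential(
    table: FeatureTable,
    metadata: pd.DataFrame,
    timepoint: float,
    group_col: str = "group",
    covariates: Sequence[str] = ("bf_total_months", "bf_exclusive_months", "solid_food_intro_months"),
    age_col: str = "age_months",
    contrasts: Optional[Sequence[Tuple[str, str]]] = None,
    min_group_n: int = 3,
) -> List[DifferentialResult]:
    """Per-feature group F-test after diet covariates, at one timepoint.

    Fits ``feature ~ covariates + group`` by OLS on log2 data; the group
    effect is the partial F comparing the full model against the
    covariates-only model.  BH FDR is applied across features within the
    timepoint family; log2 fold changes per contrast come from the
    covariate-adjusted group means (common slopes).
    """
    if table.transform_state not in ("log2", "autoscaled"):
        raise ValueError("ancova_differential expects a log2 (or autoscaled) table")
    meta = metadata.loc[table.data.index]
    sel = (meta[age_col] == timepoint).to_numpy()
    meta_t = meta[sel]
    Y = table.data.to_numpy(dtype=float)[sel]

    counts = meta_t[group_col].value_counts()
    small = counts[counts < min_group_n].index.tolist()
    if small:
        warnings.warn(f"groups below n={min_group_n} dropped at t={timepoint}: {small}")
    keep_groups = sorted(counts[counts >= min_group_n].index)
    if len(keep_groups) < 2:
        raise ValueError(f"fewer than 2 usable groups at timepoint {timepoint}")
    row_keep = meta_t[group_col].isin(keep_groups).to_numpy()
    meta_t = meta_t[row_keep]
    Y = Y[row_keep]
    n = len(meta_t)

    cov_mat = meta_t[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))
    X0 = np.column_stack([np.ones(n), cov_mat])
    dummies = pd.get_dummies(
        pd.Categorical(meta_t[group_col], categories=keep_groups), drop_first=True, dtype=float
    )
    X1 = np.column_stack([X0, dummies.to_numpy()])
    k = len(keep_groups)
    df1 = k - 1
    df2 = n - X1.shape[1]
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom for ANCOVA")

    Q0, _ = np.linalg.qr(X0)
    Q1, _ = np.linalg.qr(X1)
    rss0 = ((Y - Q0 @ (Q0.T @ Y)) ** 2).sum(axis=0)
    rss1 = ((Y - Q1 @ (Q1.T @ Y)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(rss1 > 0, ((rss0 - rss1) / df1) / (rss1 / df2), np.inf)
    F = np.maximum(F, 0.0)
    p = sps.f.sf(F, df1, df2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)

    # covariate-adjusted group means: coefficients on the group dummies
    beta, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    g_index = {g: i for i, g in enumerate(keep_groups)}
    n_base = X0.shape[1]
    adj = np.zeros((k, Y.shape[1]))
    adj[1:, :] = beta[n_base:, :]

    if contrasts is None:
        contrasts = [c for c in DEFAULT_CONTRASTS if c[0] in keep_groups and c[1] in keep_groups]
    results: List[DifferentialResult] = []
    for j, feat in enumerate(table.data.columns):
        for a, b in contrasts:
            if a not in g_index or b not in g_index:
                continue
            lfc = float(adj[g_index[a], j] - adj[g_index[b], j])
            results.append(
                DifferentialResult(feat, timepoint, (a, b), lfc, float(F[j]), float(p[j]), float(q[j]))
            )
    return results


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q_stat: float
    p_adj: float


@dataclass
class TukeyResult:
    F_stat: float
    p_anova: float
    mse: float
    df_error: int
    comparisons: List[PairwiseComparison]

    def p_adj(self, group_a: str, group_b: str) -> float:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {group_a, group_b}:
                return c.p_adj
        raise KeyError(f"no comparison for {group_a!r} vs {group_b!r}")


def tukey_hsd(values: Sequence[float], labels: Sequence[str]) -> TukeyResult:
    """One-way ANOVA with Tukey-Kramer honestly-significant-difference p.

    The pairwise statistic is ``q = |mean_a - mean_b| /
    sqrt(MSE/2 (1/n_a + 1/n_b))`` referred to the studentized-range
    distribution with (k, N-k) parameters; for k = 2 this reduces exactly to
    the pooled two-sample t-test.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if len(v) != len(lab):
        raise ValueError("values and labels differ in length")
    groups = sorted(pd.unique(lab))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    data = [v[lab == g] for g in groups]
    ns = np.array([len(d) for d in data])
    if (ns < 2).any():
        small = [g for g, n in zip(groups, ns) if n < 2]
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    k = len(groups)
    N = len(v)
    means = np.array([d.mean() for d in data])
    sse = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_error = N - k
    mse = sse / df_error
    if mse <= 0:
        raise ValueError("zero within-group variance; Tukey HSD undefined")
    grand = v.mean()
    ssb = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    F = (ssb / (k - 1)) / mse
    p_anova = float(sps.f.sf(F, k - 1, df_error))
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_error))
            comparisons.append(
                PairwiseComparison(groups[i], groups[j], float(diff), float(q), min(p_adj, 1.0))
            )
    return TukeyResult(float(F), p_anova, float(mse), int(df_error), comparisons)


# ---------------------------------------------------------------------------
# Spearman cross-correlation with FDR
# ---------------------------------------------------------------------------


@dataclass
class SpearmanResult:
    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n: int


def spearman_fdr(X: pd.DataFrame, Y: pd.DataFrame) -> SpearmanResult:
    """Average-rank Spearman correlation of every X column with every Y column.

    Samples are paired on the shared index; p-values use the t
    approximation and BH FDR is applied across the whole matrix.  Constant
    columns give missing (NaN) entries.
    """
    common = X.index.intersection(Y.index)
    if len(common) < 5:
        raise ValueError(f"need >= 5 paired samples, got {len(common)}")
    Xv = X.loc[common].to_numpy(dtype=float)
    Yv = Y.loc[common].to_numpy(dtype=float)
    n = len(common)
    Rx = sps.rankdata(Xv, axis=0)
    Ry = sps.rankdata(Yv, axis=0)
    Rx = Rx - Rx.mean(axis=0)
    Ry = Ry - Ry.mean(axis=0)
    ssx = (Rx**2).sum(axis=0)
    ssy = (Ry**2).sum(axis=0)
    denom = np.sqrt(np.outer(ssx, ssy))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (Rx.T @ Ry) / denom
    rho[np.broadcast_to(ssx[:, None] == 0, rho.shape)] = np.nan
    rho[np.broadcast_to(ssy[None, :] == 0, rho.shape)] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = np.finfo(float).tiny
    p[np.isnan(rho)] = np.nan
    q = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        q[finite] = bh_fdr(np.clip(p[finite], np.finfo(float).tiny, 1.0))
    idx, cols = X.columns, Y.columns
    return SpearmanResult(
        pd.DataFrame(rho, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
        pd.DataFrame(q, index=idx, columns=cols),
        n,
    )


# ---------------------------------------------------------------------------
# Loess
# ---------------------------------------------------------------------------


@dataclass
class LoessFit:
    span: float
    degree: int
    x: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    @property
    def curve(self) -> List[Tuple[float, float]]:
        return list(zip(self.x.tolist(), self.fitted.tolist()))


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 2,
    eval_x: Optional[Sequence[float]] = None,
    n_grid: int = 50,
) -> LoessFit:
    """Tricube-weighted local polynomial regression with pointwise 95% bands.

    At each evaluation point the ``ceil(span * n)`` nearest observations are
    fit with a weighted polynomial of the given degree; the pointwise
    interval uses the local weighted residual variance.  Evaluation is
    restricted to the observed x-range (interpolation only).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.ndim != 1 or xv.shape != yv.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not np.isfinite(xv).all():
        raise ValueError("x must be finite")
    n = len(xv)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if n < max(5, degree + 2):
        raise ValueError(f"need at least {max(5, degree + 2)} points")
    if not (0.0 < span <= 1.0):
        raise ValueError("span must lie in (0, 1]")
    k = int(math.ceil(span * n))
    if k < degree + 2:
        raise ValueError(
            f"span {span} covers only {k} points; need at least {degree + 2}"
        )
    if eval_x is None:
        grid = np.linspace(xv.min(), xv.max(), n_grid)
    else:
        grid = np.asarray(eval_x, dtype=float)
        if (grid < xv.min() - 1e-12).any() or (grid > xv.max() + 1e-12).any():
            raise ValueError("eval_x outside the observed x-range (no extrapolation)")

    fitted = np.empty(len(grid))
    lower = np.empty(len(grid))
    upper = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(xv - x0)
        ds = np.sort(d)
        h = ds[k - 1]
        # widen the window until enough points carry positive weight
        j = k - 1
        while True:
            hh = h if h > 0 else 1.0
            u = d / hh
            w = np.clip(1.0 - u**3, 0.0, None) ** 3
            if h == 0:
                w = (d == 0).astype(float)
            if (w > 0).sum() >= degree + 1 or j >= n - 1:
                break
            j += 1
            h = ds[j] * (1.0 + 1e-9)
        if (w > 0).sum() < degree + 1:
            w = np.ones(n)  # fully degenerate x layout: global fit
        sw = np.sqrt(w)
        V = np.vander(xv - x0, degree + 1, increasing=True)
        A = V * sw[:, None]
        b = yv * sw
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        fitted[i] = coef[0]
        # l(x0) row: prediction as linear combination of y
        G = A.T @ A
        try:
            l_row = np.linalg.solve(G, (V * w[:, None]).T)[0]
        except np.linalg.LinAlgError:
            l_row = np.zeros(n)
        resid = yv - V @ coef
        wsum = w.sum()
        dfl = max(wsum - (degree + 1), 1.0)
        sigma2 = float((w * resid**2).sum() / dfl)
        se = math.sqrt(max(sigma2, 0.0) * float((l_row**2).sum()))
        fitted_i = fitted[i]
        lower[i] = fitted_i - 1.96 * se
        upper[i] = fitted_i + 1.96 * se
    return LoessFit(span, degree, grid, fitted, lower, upper)
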