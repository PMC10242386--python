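"""Per-gene stage models with empirical-Bayes moderation and FDR control.

Two models are fitted gene by gene on voom log2-CPM values with voom
precision weights:

* the *stage-indicator* (linear) model
  ``Y = alpha + beta1*x1 + beta2*x2 + beta3*x3 + beta4*x4``, where
  ``x_s`` indicates pathologic stage ``s`` and the intercept is the
  control baseline, so each ``beta_s`` is the log2 fold-change of stage
  ``s`` versus controls;
* the *ordinal* model ``Y = a*X + b`` treating stage as a numeric
  covariate ``X in {0..4}``.

Residual variances are shrunk across genes toward a common prior by
moment-matching the scaled-F distribution of log variances (the
``squeezeVar`` scheme of moderated-t analysis).  The linear model is
summarized by a moderated F statistic over its four stage coefficients,
the ordinal model by the moderated t of its slope; p-values use
``d0 + df`` residual degrees of freedom and are Benjamini-Hochberg
adjusted.  Gene ranking and the top-n consensus between the two models
follow a deterministic tie-break chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import StageDesign
from .errors import ConfigurationError
from .preprocess import VoomResult


# ---------------------------------------------------------------------------
# per-gene weighted least squares


@dataclass
class LinearStageFit:
    """Per-gene weighted fit of the stage-indicator design."""

    genes: pd.Index
    coefficients: pd.DataFrame = field(repr=False)  # alpha, beta1..beta4
    sigma2: np.ndarray = field(repr=False)          # residual variance s^2
    df_resid: int
    cov_unscaled: np.ndarray = field(repr=False)    # (genes, 5, 5) (X'WX)^-1

    @property
    def stage_coef(self) -> np.ndarray:
        return self.coefficients[["beta1", "beta2", "beta3", "beta4"]].to_numpy()

    @property
    def lfc(self) -> np.ndarray:
        """Largest-magnitude stage coefficient per gene (signed)."""
        b = self.stage_coef
        idx = np.argmax(np.abs(b), axis=1)
        return b[np.arange(b.shape[0]), idx]


@dataclass
class OrdinalFit:
    """Per-gene weighted simple regression on the numeric stage."""

    genes: pd.Index
    slope: np.ndarray = field(repr=False)
    intercept: np.ndarray = field(repr=False)
    sigma2: np.ndarray = field(repr=False)
    df_resid: int
    coef_unscaled_var: np.ndarray = field(repr=False)  # var(a)/sigma^2 per gene


def fit_linear_stage_model(v: VoomResult, d: StageDesign) -> LinearStageFit:
    """Weighted least squares of log2 CPM on intercept + four stage indicators."""
    counts = d.stage_counts()
    for s, n in counts.items():
        if n == 0:
            raise ConfigurationError(f"stage {s} has no samples: design is rank-deficient")
    X = np.column_stack([np.ones(len(d.sample_ids)), d.stage_indicators])
    return _wls_fit(v, d, X)


def _wls_fit(v: VoomResult, d: StageDesign, X: np.ndarray) -> LinearStageFit:
    Y = v.log_cpm[d.sample_ids].to_numpy()
    W = v.weights[d.sample_ids].to_numpy()
    if (W <= 0).any():
        raise ConfigurationError("voom weights must be positive")
    n, p = X.shape
    if n <= p:
        raise ConfigurationError(f"need more than {p} samples to fit {p} coefficients")
    xtwx = np.einsum("ni,gn,nj->gij", X, W, X)
    xtwy = np.einsum("ni,gn->gi", X, W * Y)
    beta = np.linalg.solve(xtwx, xtwy[:, :, None])[:, :, 0]
    resid = Y - beta @ X.T
    rss = np.einsum("gn,gn->g", W, resid**2)
    df = n - p
    sigma2 = rss / df
    cov_unscaled = np.linalg.inv(xtwx)
    coef = pd.DataFrame(
        beta, index=v.log_cpm.index,
        columns=["alpha", "beta1", "beta2", "beta3", "beta4"],
    )
    return LinearStageFit(v.log_cpm.index, coef, sigma2, df, cov_unscaled)


def fit_ordinal_model(v: VoomResult, d: StageDesign) -> OrdinalFit:
    """Weighted simple regression of log2 CPM on the numeric stage X."""
    x = d.numeric_stage
    if np.unique(x).size < 2:
        raise ConfigurationError("ordinal model needs >= 2 distinct stage values")
    Y = v.log_cpm[d.sample_ids].to_numpy()
    W = v.weights[d.sample_ids].to_numpy()
    if (W <= 0).any():
        raise ConfigurationError("voom weights must be positive")
    n = x.size
    sw = W.sum(axis=1)
    xbar = (W * x).sum(axis=1) / sw
    ybar = (W * Y).sum(axis=1) / sw
    xc = x[None, :] - xbar[:, None]
    sxx = (W * xc**2).sum(axis=1)
    sxy = (W * xc * (Y - ybar[:, None])).sum(axis=1)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    fitted = intercept[:, None] + slope[:, None] * x[None, :]
    rss = (W * (Y - fitted) ** 2).sum(axis=1)
    df = n - 2
    sigma2 = rss / df
    return OrdinalFit(v.log_cpm.index, slope, intercept, sigma2, df, 1.0 / sxx)


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation (squeezeVar / fitFDist scheme)


@dataclass
class ModerationParams:
    """Estimated prior (d0, s0^2) and the per-gene posterior variances."""

    prior_df: float            # d0; may be inf
    prior_var: float           # s0^2
    posterior_var: np.ndarray = field(repr=False)

    @property
    def total_df(self) -> float:
        return self.prior_df


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on the log scale, as in the standard eBayes fit
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def squeeze_variances(sigma2: np.ndarray, df: float) -> ModerationParams:
    """Shrink per-gene variances toward a common prior.

    Moment-matches ``log(s^2)`` against the scaled-F model
    ``s^2 ~ s0^2 * F(df, d0)``.  When the observed spread of log variances
    does not exceed what sampling alone explains, ``d0`` is infinite and
    every posterior variance equals the common prior (the mean observed
    variance).
    """
    s2 = np.asarray(sigma2, dtype=float)
    if s2.size < 2:
        raise ConfigurationError("moderation needs >= 2 genes")
    if df <= 0:
        raise ConfigurationError("residual df must be positive")
    if np.all(s2 <= 0):
        raise ConfigurationError("all residual variances are zero: nothing to moderate")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = math.inf
        s02 = float(s2.mean())
        post = np.full_like(s2, s02)
    return ModerationParams(d0, s02, post)


def _total_df(params: ModerationParams, df_resid: float) -> float:
    return df_resid if math.isinf(params.prior_df) else params.prior_df + df_resid


@dataclass
class ModelStats:
    """Per-gene moderated statistic, p-value, and reported log fold-change."""

    table: pd.DataFrame = field(repr=False)  # columns: lfc, stat, p
    params: ModerationParams


def moderate_linear(fit: LinearStageFit, params: ModerationParams | None = None) -> ModelStats:
    """Moderated F over the four stage coefficients (joint stage contrast)."""
    if params is None:
        params = squeeze_variances(fit.sigma2, fit.df_resid)
    b = fit.stage_coef
    v = fit.cov_unscaled[:, 1:, 1:]
    quad = np.einsum("gi,gij,gj->g", b, np.linalg.inv(v), b)
    r = b.shape[1]
    f = quad / (r * params.posterior_var)
    df2 = _total_df(params, fit.df_resid)
    if math.isinf(df2):
        p = stats.chi2.sf(r * f, r)
    else:
        p = stats.f.sf(f, r, df2)
    table = pd.DataFrame({"lfc": fit.lfc, "stat": f, "p": p}, index=fit.genes)
    return ModelStats(table, params)


def moderate_ordinal(fit: OrdinalFit, params: ModerationParams | None = None) -> ModelStats:
    """Moderated t of the ordinal slope."""
    if params is None:
        params = squeeze_variances(fit.sigma2, fit.df_resid)
    se = np.sqrt(params.posterior_var * fit.coef_unscaled_var)
    t = fit.slope / se
    df2 = _total_df(params, fit.df_resid)
    if math.isinf(df2):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df2)
    table = pd.DataFrame({"lfc": fit.slope, "stat": t, "p": p}, index=fit.genes)
    return ModelStats(table, params)


def ordinary_t(fit: OrdinalFit) -> np.ndarray:
    """Unmoderated slope t statistic (the d0 = 0 limit of the moderated t)."""
    se = np.sqrt(fit.sigma2 * fit.coef_unscaled_var)
    return fit.slope / se


# ---------------------------------------------------------------------------
# multiplicity correction, ranking, consensus


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _rank_genes(table: pd.DataFrame) -> np.ndarray:
    """Ranks 1..n by ascending adj. p, then raw p, then descending |lfc|, then id."""
    order = np.lexsort((
        table.index.to_numpy(),
        -np.abs(table["lfc"].to_numpy()),
        table["p"].to_numpy(),
        table["adj_p"].to_numpy(),
    ))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    return ranks


def build_stat_table(linear: ModelStats, ordinal: ModelStats) -> pd.DataFrame:
    """Combined per-gene table with BH-adjusted p-values and per-model ranks."""
    if not linear.table.index.equals(ordinal.table.index):
        raise ConfigurationError("linear and ordinal tables must cover the same genes")
    lin = linear.table.assign(adj_p=bh_adjust(linear.table["p"]))
    ord_ = ordinal.table.assign(adj_p=bh_adjust(ordinal.table["p"]))
    out = pd.DataFrame({
        "lfc": lin["lfc"],
        "slope": ord_["lfc"],
        "p_linear": lin["p"],
        "adjp_linear": lin["adj_p"],
        "p_ordinal": ord_["p"],
        "adjp_ordinal": ord_["adj_p"],
    }, index=lin.index)
    out["rank_linear"] = _rank_genes(lin)
    out["rank_ordinal"] = _rank_genes(ord_)
    out.index.name = "gene"
    return out


def rank_and_consensus(
    table: pd.DataFrame, top_n: int = 15, alpha: float = 1e-5
) -> list[str]:
    """Intersection of the two models' top-``top_n`` genes, gated at adj. p < alpha.

    Returns gene ids ordered by their linear-model rank.
    """
    if top_n > len(table):
        raise ConfigurationError(f"top_n={top_n} exceeds the {len(table)} ranked genes")
    top_lin = set(table.index[table["rank_linear"] <= top_n])
    top_ord = set(table.index[table["rank_ordinal"] <= top_n])
    both = top_lin & top_ord
    passing = [
        g for g in both
        if table.at[g, "adjp_linear"] < alpha and table.at[g, "adjp_ordinal"] < alpha
    ]
    return sorted(passing, key=lambda g: table.at[g, "rank_linear"])
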