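"""Staged time-course differential expression with empirical-Bayes moderation.

Per gene, a one-way (cell-means) least-squares fit over time-point levels
gives level means and a residual variance s2_g on d_g degrees of freedom.
The variances are shrunk towards a common prior: the hierarchical model
s2_g | sigma2_g ~ sigma2_g * chi2(d_g)/d_g with 1/sigma2_g ~ chi2(d0)/(d0*s0^2)
is fitted by moment-matching log s2_g against the log scaled-F distribution
(digamma/trigamma inversion), and the posterior variance
s2_tilde = (d0*s0^2 + d_g*s2_g)/(d0 + d_g) replaces s2_g in the t statistics,
which then carry d0 + d_g degrees of freedom.

Differential expression is tested between every pair of time points (DEV2 and
DEV3 merged for autogamy); per-gene p-values are the Bonferroni-combined
minimum across contrasts, adjusted across genes by Benjamini-Hochberg.  The
fold-change-threshold variant replaces the point null by |logFC| <= tau
(TREAT), and its DE call additionally requires a fitted fold change above the
threshold.

The module exposes both the operation functions and a statsmodels-style
``TimecourseModel`` whose ``fit`` returns a ``DEResults`` with a ``summary``
table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneMatrix

#: Autogamy stages merged into one level for contrast testing.
MERGED_LEVEL = "DEV2-3"


@dataclass
class DEConfig:
    """Thresholds of a differential-expression run.

    ``fold_change`` is on the natural scale (1.5 or 2 in the headline
    analyses) and is converted to a log2 threshold internally; None selects
    the ordinary moderated test.
    """

    fdr: float = 0.05
    fold_change: float | None = None
    merge_dev23: bool = True

    @property
    def tau(self) -> float:
        if self.fold_change is None:
            return 0.0
        if self.fold_change < 1.0:
            raise ValueError("fold_change threshold must be >= 1")
        return math.log2(self.fold_change)


@dataclass
class LinearFit:
    """Per-gene one-way least squares over time-point levels."""

    coef: pd.DataFrame  # genes x levels (level means)
    s2: pd.Series  # residual variance per gene
    df_residual: int
    level_counts: pd.Series  # samples per level
    contrasts: list[tuple[str, str]]

    def contrast_sd_unscaled(self) -> pd.Series:
        """sqrt(1/n_i + 1/n_j) per contrast (multiplies the residual sd)."""
        n = self.level_counts
        return pd.Series(
            {
                f"{a}-{b}": math.sqrt(1.0 / n[a] + 1.0 / n[b])
                for a, b in self.contrasts
            }
        )


@dataclass
class EBayesParams:
    """Empirical-Bayes variance prior and per-gene posterior variances."""

    d0: float  # prior degrees of freedom (inf allowed)
    s02: float  # prior variance
    s2_post: pd.Series

    def total_df(self, df_residual: int) -> float:
        return self.d0 + df_residual if np.isfinite(self.d0) else np.inf


@dataclass
class DEResult:
    """Per-gene, per-contrast moderated statistics and the gene-level call."""

    logfc: pd.DataFrame  # genes x contrasts
    t: pd.DataFrame
    p: pd.DataFrame
    gene_p: pd.Series
    fdr: pd.Series
    de: pd.Series  # boolean call
    max_abs_logfc: pd.Series
    method: str
    config: DEConfig

    def de_genes(self) -> set[str]:
        return set(self.de.index[self.de])

    def table(self) -> pd.DataFrame:
        out = self.logfc.add_prefix("logFC.")
        out["max_abs_logFC"] = self.max_abs_logfc
        out["p_value"] = self.gene_p
        out["fdr"] = self.fdr
        out["de"] = self.de
        return out


# ---------------------------------------------------------------------------
# operations


def timepoint_levels(gene_matrix: GeneMatrix, merge_dev23: bool = True) -> pd.Series:
    """Sample -> contrast level, merging DEV2/DEV3 for autogamy designs."""
    tps = gene_matrix.timepoints().astype(str)
    if merge_dev23:
        tps = tps.replace({"DEV2": MERGED_LEVEL, "DEV3": MERGED_LEVEL})
    return tps


def fit_timecourse(gene_matrix: GeneMatrix, config: DEConfig | None = None) -> LinearFit:
    """Cell-means OLS per gene: coefficients are level means, s2 = RSS/df."""
    config = config or DEConfig()
    levels = timepoint_levels(gene_matrix, config.merge_dev23)
    level_names = list(dict.fromkeys(levels))  # design order
    counts = levels.value_counts()
    x = gene_matrix.values.to_numpy(dtype=float)
    n = x.shape[1]
    df_residual = n - len(level_names)
    if df_residual < 1:
        raise ValueError(
            f"design leaves no residual degrees of freedom "
            f"({n} samples, {len(level_names)} levels)"
        )
    coef = np.empty((x.shape[0], len(level_names)))
    rss = np.zeros(x.shape[0])
    for k, lev in enumerate(level_names):
        cols = np.flatnonzero((levels == lev).to_numpy())
        if len(cols) == 0:
            raise ValueError(f"level {lev!r} has no samples")
        sub = x[:, cols]
        coef[:, k] = sub.mean(axis=1)
        rss += ((sub - coef[:, [k]]) ** 2).sum(axis=1)
    return LinearFit(
        coef=pd.DataFrame(coef, index=gene_matrix.values.index, columns=level_names),
        s2=pd.Series(rss / df_residual, index=gene_matrix.values.index, name="s2"),
        df_residual=df_residual,
        level_counts=counts,
        contrasts=list(combinations(level_names, 2)),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on x, as in the standard
    moment-matching estimator)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def estimate_ebayes(fit: LinearFit) -> EBayesParams:
    """Moment-match (d0, s0^2) from the spread of log residual variances.

    With z = log s2_g, E[z] and Var[z] under the hierarchical model are
    digamma/trigamma expressions in d_g and d0; the excess of the observed
    variance of z over trigamma(d_g/2) identifies d0, and the mean identifies
    s0^2.  Zero variances are shifted by 1e-2 x the smallest positive variance
    before taking logs.
    """
    s2 = fit.s2.to_numpy(dtype=float).copy()
    if len(s2) < 2:
        raise ValueError("need at least 2 genes to estimate the variance prior")
    if (s2 < 0).any():
        raise ValueError("negative residual variances")
    if (s2 == 0).any():
        positive = s2[s2 > 0]
        offset = (positive.min() if len(positive) else 1.0) * 1e-2
        s2 = s2 + np.where(s2 == 0, offset, 0.0)
    dg = fit.df_residual
    z = np.log(s2)
    e = z - float(digamma(dg / 2.0)) + math.log(dg / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(polygamma(1, dg / 2.0))
    if excess <= 0:
        # no excess dispersion: all true variances equal; MLE of the common
        # value is the plain mean of the observed variances
        d0 = np.inf
        s02 = float(np.mean(s2))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    if np.isfinite(d0):
        post = (d0 * s02 + dg * fit.s2.to_numpy()) / (d0 + dg)
    else:
        post = np.full(len(fit.s2), s02)
    return EBayesParams(d0=d0, s02=s02, s2_post=pd.Series(post, index=fit.s2.index))


def _t_sf(x: np.ndarray, df: float) -> np.ndarray:
    from scipy.stats import norm

    if np.isinf(df):
        return norm.sf(x)
    return t_dist.sf(x, df)


def _contrast_stats(
    fit: LinearFit, ebayes: EBayesParams
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    sd_u = fit.contrast_sd_unscaled()
    s_tilde = np.sqrt(ebayes.s2_post.to_numpy(dtype=float))
    logfc = {}
    se = {}
    for a, b in fit.contrasts:
        name = f"{a}-{b}"
        logfc[name] = fit.coef[a] - fit.coef[b]
        se[name] = pd.Series(sd_u[name] * s_tilde, index=fit.coef.index)
    df_total = ebayes.total_df(fit.df_residual)
    return pd.DataFrame(logfc), pd.DataFrame(se), df_total


def _combine_and_call(
    logfc: pd.DataFrame,
    t_stats: pd.DataFrame,
    p: pd.DataFrame,
    config: DEConfig,
    method: str,
    require_fc: bool,
) -> DEResult:
    gene_p = (p.min(axis=1) * p.shape[1]).clip(upper=1.0)
    fdr = adjust_bh(gene_p)
    max_abs = logfc.abs().max(axis=1)
    de = fdr < config.fdr
    if require_fc and config.tau > 0:
        de &= max_abs > config.tau
    return DEResult(
        logfc=logfc,
        t=t_stats,
        p=p,
        gene_p=gene_p,
        fdr=fdr,
        de=de,
        max_abs_logfc=max_abs,
        method=method,
        config=config,
    )


def moderated_tests(
    fit: LinearFit, ebayes: EBayesParams, config: DEConfig | None = None
) -> DEResult:
    """Moderated t-tests for every time-point contrast, combined per gene by
    Bonferroni-over-contrasts then BH across genes."""
    config = config or DEConfig()
    logfc, se, df_total = _contrast_stats(fit, ebayes)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = logfc / se
    t_stats = t_stats.fillna(0.0)
    p = pd.DataFrame(
        2.0 * _t_sf(np.abs(t_stats.to_numpy()), df_total),
        index=t_stats.index,
        columns=t_stats.columns,
    )
    return _combine_and_call(logfc, t_stats, p, config, "ebayes", require_fc=False)


def treat_tests(
    fit: LinearFit, ebayes: EBayesParams, config: DEConfig
) -> DEResult:
    """Fold-change-threshold tests: the null is |logFC| <= tau, with
    p = P(T >= (|logFC|-tau)/se) + P(T >= (|logFC|+tau)/se).

    The DE call requires both FDR < threshold and a fitted |logFC| above tau
    (the "model fold-change" rule).  tau = 0 reduces exactly to the ordinary
    moderated test.
    """
    tau = config.tau
    if tau == 0.0:
        return moderated_tests(fit, ebayes, config)
    logfc, se, df_total = _contrast_stats(fit, ebayes)
    abs_fc = np.abs(logfc.to_numpy())
    se_arr = se.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (abs_fc - tau) / se_arr
        t_hi = (abs_fc + tau) / se_arr
        t_stats = logfc / se
    t_lo = np.nan_to_num(t_lo)
    t_hi = np.nan_to_num(t_hi)
    p = pd.DataFrame(
        _t_sf(t_lo, df_total) + _t_sf(t_hi, df_total),
        index=logfc.index,
        columns=logfc.columns,
    ).clip(upper=1.0)
    return _combine_and_call(
        logfc, t_stats.fillna(0.0), p, config, "treat", require_fc=True
    )


def adjust_bh(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("p-values contain NaN")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values outside [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(adjusted, index=p.index, name="fdr")
    return pd.Series(adjusted, name="fdr")


def call_de(result: DEResult) -> set[str]:
    """The flagged gene set of a DE run."""
    return result.de_genes()


# ---------------------------------------------------------------------------
# model/results front end


class TimecourseModel:
    """Staged time-course DE model over a gene matrix and its sample sheet.

    Examples
    --------
    >>> model = TimecourseModel(gene_matrix)           # doctest: +SKIP
    >>> res = model.fit(method="treat", fold_change=2)  # doctest: +SKIP
    >>> res.summary()                                   # doctest: +SKIP
    """

    def __init__(self, gene_matrix: GeneMatrix, merge_dev23: bool = True):
        self.gene_matrix = gene_matrix
        self.merge_dev23 = merge_dev23

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, sample_sheet: pd.DataFrame, **kwargs
    ) -> "TimecourseModel":
        return cls(GeneMatrix(values=values, sample_sheet=sample_sheet), **kwargs)

    def fit(
        self,
        method: str = "ebayes",
        fold_change: float | None = None,
        fdr: float = 0.05,
    ) -> "DEResults":
        config = DEConfig(fdr=fdr, fold_change=fold_change, merge_dev23=self.merge_dev23)
        linfit = fit_timecourse(self.gene_matrix, config)
        ebayes = estimate_ebayes(linfit)
        if method == "ebayes":
            result = moderated_tests(linfit, ebayes, config)
        elif method == "treat":
            if fold_change is None:
                raise ValueError("treat requires a fold_change threshold")
            result = treat_tests(linfit, ebayes, config)
        else:
            raise ValueError(f"unknown method {method!r}")
        return DEResults(self, linfit, ebayes, result)


class DEResults:
    """Fitted DE results: estimates, moderation parameters, calls."""

    def __init__(
        self,
        model: TimecourseModel,
        fit: LinearFit,
        ebayes: EBayesParams,
        result: DEResult,
    ):
        self.model = model
        self.linear_fit = fit
        self.ebayes = ebayes
        self.result = result

    @property
    def d0(self) -> float:
        return self.ebayes.d0

    @property
    def s02(self) -> float:
        return self.ebayes.s02

    def de_genes(self) -> set[str]:
        return self.result.de_genes()

    def table(self) -> pd.DataFrame:
        return self.result.table()

    def summary(self) -> str:
        cfg = self.result.config
        n = len(self.result.gene_p)
        n_de = int(self.result.de.sum())
        lines = [
            "Time-course differential expression",
            "===================================",
            f"method:            {self.result.method}",
            f"genes:             {n}",
            f"levels:            {', '.join(self.linear_fit.coef.columns)}",
            f"contrasts:         {len(self.linear_fit.contrasts)}",
            f"residual df:       {self.linear_fit.df_residual}",
            f"prior df (d0):     {self.ebayes.d0:.3g}",
            f"prior var (s0^2):  {self.ebayes.s02:.4g}",
            f"FDR threshold:     {cfg.fdr}",
            f"fold-change:       {cfg.fold_change if cfg.fold_change else 'none'}",
            f"DE genes:          {n_de} ({100.0 * n_de / n:.1f}%)",
        ]
        return "\n".join(lines)
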