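"""Trait models: Poisson GLM on area, one-way ANOVAs, publication-bias meta-analysis.

The structural-importance index is regressed on accumulated geographic area
with a log-link Poisson-family GLM.  The response is continuous and
non-negative, so the fit is a quasi-likelihood one: the IRLS estimating
equations do not require an integer response, and the point estimates equal
the Poisson MLE whenever the response happens to be integer.  Morphology and
taxonomic-order effects are tested with one-way ANOVAs, and publication
effort across ecoregions is screened for heterogeneity and small-study bias
with a meta-analysis of proportions (logit transform, ML tau², Cochran Q,
Thompson–Sharp regression test).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger("reefguest")

MORPHOLOGY_CLASSES = ("Crust-like", "Massive", "Cup-like", "Erect")


class ConvergenceError(RuntimeError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass(frozen=True)
class GlmFit:
    """Log-link Poisson-family fit of importance on accumulated area."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    z_intercept: float
    z_slope: float
    p_slope: float
    deviance: float
    null_deviance: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_stats: pd.DataFrame  # mean, se, sd, n per group

    def as_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
            "groups": self.group_stats.to_dict(orient="index"),
        }


@dataclass(frozen=True)
class MetaBiasResult:
    pooled_proportion: float
    tau2: float
    heterogeneity_q: float
    heterogeneity_p: float
    bias_test_statistic: float
    bias_p: float
    n_regions: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def poisson_glm(
    response: np.ndarray | pd.Series,
    predictor: np.ndarray | pd.Series,
) -> GlmFit:
    """Fit importance ~ area with a log-link Poisson-family GLM (IRLS)."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.ndim != 1 or x.shape != y.shape:
        raise ValueError("response and predictor must be 1-D and aligned")
    if np.any(y < 0):
        raise ValueError("Poisson-family response must be non-negative")
    if not np.isfinite(x).all():
        raise ValueError("predictor must be finite")
    if np.all(y == 0):
        raise DegenerateFitError("all-zero response: log-link mean is unbounded below")
    exog = sm.add_constant(x)
    model = sm.GLM(y, exog, family=sm.families.Poisson())
    try:
        fit = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # pragma: no cover - defensive
        raise ConvergenceError(f"IRLS failed: {exc}") from exc
    if not fit.converged:
        raise ConvergenceError(
            f"IRLS did not converge in 100 iterations (deviance {fit.deviance})"
        )
    null_dev = sm.GLM(y, np.ones_like(y), family=sm.families.Poisson()).fit().deviance
    coef, se = fit.params, fit.bse
    z_slope = float(coef[1] / se[1]) if se[1] > 0 else float("nan")
    return GlmFit(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        z_intercept=float(coef[0] / se[0]) if se[0] > 0 else float("nan"),
        z_slope=z_slope,
        p_slope=float(2 * scipy.stats.norm.sf(abs(z_slope))),
        deviance=float(fit.deviance),
        null_deviance=float(null_dev),
        n=len(y),
    )


def anova_oneway(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    dispersion: str = "se",
) -> AnovaResult:
    """One-way ANOVA of importance across trait groups.

    Group dispersion is reported as the standard error of the mean by
    default; ``dispersion='sd'`` is accepted for symmetry but both columns
    are always present in ``group_stats``.
    """
    if dispersion not in ("se", "sd"):
        raise ValueError("dispersion must be 'se' or 'sd'")
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups, dtype=object), index=s.index)
    by = s.groupby(g)
    sizes = by.size()
    if len(sizes) < 2:
        raise ValueError("ANOVA needs at least two groups")
    n = len(s)
    k = len(sizes)
    arrays = [vals.to_numpy() for _, vals in by]
    if np.ptp(s.to_numpy()) == 0:
        # identical values everywhere: no between- or within-group variance
        f_stat, p = 0.0, 1.0
    else:
        ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
        if ss_within == 0 and (sizes == 1).any():
            raise ValueError(
                "zero within-group variance with singleton groups: F undefined"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = scipy.stats.f_oneway(*arrays)
        if np.isnan(f_stat):
            f_stat, p = 0.0, 1.0
    stats = pd.DataFrame(
        {
            "mean": by.mean(),
            "sd": by.std(ddof=1),
            "se": by.std(ddof=1) / np.sqrt(sizes),
            "n": sizes,
        }
    )
    return AnovaResult(
        F=float(f_stat),
        df_between=k - 1,
        df_within=n - k,
        p=float(p),
        group_stats=stats,
    )


# ---------------------------------------------------------------------------
# Meta-analysis of publication proportions
# ---------------------------------------------------------------------------

def _logit_effects(events: np.ndarray, total: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-region logit proportions and their large-sample variances.

    Regions with 0 events (or all events) get the 0.5 continuity correction.
    """
    events = events.astype(float)
    n = float(total)
    corrected = (events == 0) | (events == n)
    if corrected.any():
        logger.info("continuity correction 0.5 applied to %d region(s)", corrected.sum())
    e = np.where(corrected, events + 0.5, events)
    nn = np.where(corrected, n + 1.0, n)
    y = np.log(e / (nn - e))
    v = 1.0 / e + 1.0 / (nn - e)
    return y, v


def _ml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """Maximum-likelihood between-region variance of the logit proportions."""

    def nll(log_tau2: float) -> float:
        tau2 = np.exp(log_tau2)
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * np.sum(np.log(v + tau2) + w * (y - mu) ** 2)

    res = scipy.optimize.minimize_scalar(nll, bounds=(-30.0, 10.0), method="bounded")
    tau2 = float(np.exp(res.x))
    return 0.0 if tau2 < 1e-10 else tau2


def publication_bias(
    publications_per_region: dict[str, int] | pd.Series,
    total_publications: int,
) -> MetaBiasResult:
    """Heterogeneity and small-study bias of publication effort across regions.

    Emulates a meta-analysis of proportions: per-region proportion =
    publications / total, logit transform, inverse-variance random-effects
    pooling with ML tau², Cochran-Q heterogeneity test, and the
    Thompson–Sharp regression test (weighted regression of the effect on its
    standard error with multiplicative overdispersion), reporting the slope
    test p-value.
    """
    events = pd.Series(publications_per_region).astype(int)
    if len(events) < 3:
        raise ValueError("bias regression needs at least 3 regions")
    if (events < 0).any() or total_publications <= 0:
        raise ValueError("counts must be non-negative and total positive")
    y, v = _logit_effects(events.to_numpy(), total_publications)
    k = len(y)
    # fixed-effect pooling and Cochran Q
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    het_p = float(scipy.stats.chi2.sf(q, df=k - 1))
    # random-effects pooling with ML tau2
    tau2 = _ml_tau2(y, v)
    w_re = 1.0 / (v + tau2)
    mu_re = float(np.sum(w_re * y) / np.sum(w_re))
    pooled = float(1.0 / (1.0 + np.exp(-mu_re)))
    # Thompson–Sharp: WLS of y on its SE, weights 1/(v + tau2),
    # multiplicative overdispersion phi estimated from the residuals
    se = np.sqrt(v)
    x_mat = np.column_stack([np.ones(k), se])
    ww = np.diag(w_re)
    xtwx = x_mat.T @ ww @ x_mat
    beta = np.linalg.solve(xtwx, x_mat.T @ ww @ y)
    resid = y - x_mat @ beta
    phi = float((resid @ ww @ resid) / (k - 2))
    phi = max(phi, 1e-12)
    cov = np.linalg.inv(xtwx) * phi
    t_stat = float(beta[1] / np.sqrt(cov[1, 1]))
    bias_p = float(2 * scipy.stats.t.sf(abs(t_stat), df=k - 2))
    return MetaBiasResult(
        pooled_proportion=pooled,
        tau2=tau2,
        heterogeneity_q=q,
        heterogeneity_p=het_p,
        bias_test_statistic=t_stat,
        bias_p=bias_p,
        n_regions=k,
    )
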