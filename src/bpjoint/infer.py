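"""Post-fit statistics: VPCs, residual correlations, equality tests, model comparison.

Everything here consumes a :class:`~bpjoint.bivml.FitResult` (or raw records)
and returns small result objects that serialize to the tabular layouts of the
analysis report:

* the variance partition coefficient (VPC, equal to the household intraclass
  correlation under a random-intercept model),
* the household-level and woman-level residual correlations between SBP and
  DBP,
* Wald chi-square tests of "same effect on SBP as on DBP" per covariate level
  (possible only under the joint model, which estimates the cross-outcome
  coefficient covariance),
* the likelihood-ratio test of the multilevel model against the single-level
  null, AIC/BIC, Wald confidence intervals, the empirical SBP/DBP
  correlation, and normal QQ data for residual diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .bivml import FitResult, VarianceComponents

__all__ = [
    "VPCResult",
    "ResidualCorrelations",
    "WaldResult",
    "LRTResult",
    "vpc",
    "residual_correlations",
    "wald_equality",
    "wald_equality_table",
    "likelihood_ratio_test",
    "information_criteria",
    "empirical_outcome_correlation",
    "residual_qq_data",
    "coefficient_table",
]


@dataclass(frozen=True)
class VPCResult:
    """Household-level share of total variance, per outcome (proportions)."""

    vpc_sbp: float
    vpc_dbp: float | None

    @property
    def percent_sbp(self) -> int:
        return _round_half_away_int(100.0 * self.vpc_sbp)

    @property
    def percent_dbp(self) -> int | None:
        return None if self.vpc_dbp is None else _round_half_away_int(100.0 * self.vpc_dbp)


@dataclass(frozen=True)
class ResidualCorrelations:
    """SBP-DBP correlation of household effects and of woman-level residuals."""

    household_r: float
    woman_r: float


@dataclass(frozen=True)
class WaldResult:
    level: str
    chi2: float
    df: int
    p_value: float


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_value: float
    note: str = ""


def _round_half_away_int(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def vpc(varcomp: VarianceComponents) -> VPCResult:
    """Variance partition coefficient per outcome: var_h / (var_h + var_e).

    The percent properties round to the nearest integer, the precision at
    which such shares are customarily reported.
    """
    sh = np.diag(varcomp.sigma_h)
    se = np.diag(varcomp.sigma_e)
    total = sh + se
    if np.any(total <= 0):
        raise ValueError("total variance must be positive for each outcome")
    rho = sh / total
    if varcomp.n_outcomes == 1:
        return VPCResult(vpc_sbp=float(rho[0]), vpc_dbp=None)
    return VPCResult(vpc_sbp=float(rho[0]), vpc_dbp=float(rho[1]))


def residual_correlations(varcomp: VarianceComponents) -> ResidualCorrelations:
    """Cross-outcome correlation at each level: cov / sqrt(var1 * var2)."""
    if varcomp.n_outcomes != 2:
        raise ValueError("residual correlations require bivariate components")

    def corr(mat: np.ndarray) -> float:
        v1, v2 = mat[0, 0], mat[1, 1]
        if v1 <= 0 or v2 <= 0:
            raise ValueError("zero variance: correlation undefined")
        return float(mat[0, 1] / math.sqrt(v1 * v2))

    return ResidualCorrelations(household_r=corr(varcomp.sigma_h),
                                woman_r=corr(varcomp.sigma_e))


# ---------------------------------------------------------------------------
# Cross-outcome equality tests
# ---------------------------------------------------------------------------

def wald_equality(fit: FitResult, level_name: str) -> WaldResult:
    """Wald test of H0: effect of ``level_name`` on SBP equals its effect on DBP.

    Uses the joint coefficient covariance, so it is only defined for a
    bivariate fit: ``chi2 = (b1k - b2k)^2 / (V11 + V22 - 2 V12)`` on 1 df.
    """
    if fit.params.beta2 is None:
        raise ValueError(
            "equality testing requires a bivariate fit with a joint coefficient "
            "covariance; univariate fits cannot supply the cross-outcome term")
    try:
        k = list(fit.design_labels).index(level_name)
    except ValueError:
        raise KeyError(f"level {level_name!r} not among design columns "
                       f"{list(fit.design_labels)}") from None
    p = len(fit.design_labels)
    d = fit.params.beta1[k] - fit.params.beta2[k]
    v = fit.vcov_fixed
    var = v[k, k] + v[p + k, p + k] - 2.0 * v[k, p + k]
    if var <= 0:
        raise ValueError("non-positive variance of the coefficient difference")
    chi2 = float(d * d / var)
    return WaldResult(level=level_name, chi2=chi2, df=1,
                      p_value=float(sps.chi2.sf(chi2, df=1)))


def wald_equality_table(fit: FitResult, levels=None) -> pd.DataFrame:
    """Equality tests for every non-reference level (or a provided subset).

    No multiple-testing adjustment is applied; the ``note`` column flags that
    the p-values are per-row.
    """
    if levels is None:
        levels = [lb for lb in fit.design_labels if lb != "intercept"]
    rows = []
    for lb in levels:
        res = wald_equality(fit, lb)
        rows.append({"level": res.level, "df": res.df, "chi2": res.chi2,
                     "p_value": res.p_value})
    table = pd.DataFrame(rows)
    table.attrs["note"] = "per-row tests; no multiple-testing adjustment applied"
    return table


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

_NESTED_PAIRS = {
    ("bivariate_multilevel", "single_level_multivariate"),
    ("bivariate_multilevel", "univariate_multilevel"),
    ("bivariate_multilevel", "bivariate_multilevel"),
    ("univariate_multilevel", "univariate_multilevel"),
    ("single_level_multivariate", "single_level_multivariate"),
}


def likelihood_ratio_test(fit_full: FitResult, fit_nested: FitResult) -> LRTResult:
    """LRT of a nested model pair fitted to the same data.

    ``chi2 = 2 (ll_full - ll_nested)`` clipped at zero; df is the parameter
    count difference (3 when dropping the bivariate household covariance).
    The p-value uses the plain chi-square reference distribution; when the
    nested model sits on the variance boundary (household variance = 0) this
    is conservative relative to the chi-bar-square mixture, which is noted on
    the result rather than applied.
    """
    if (fit_full.model_tag, fit_nested.model_tag) not in _NESTED_PAIRS:
        raise ValueError(
            f"models {fit_full.model_tag!r} / {fit_nested.model_tag!r} are not "
            "a supported nested pair")
    if fit_full.n_women != fit_nested.n_women:
        raise ValueError("fits were not computed on the same data")
    df = fit_full.n_params - fit_nested.n_params
    if df < 0:
        raise ValueError("full model must have at least as many parameters")
    chi2 = max(0.0, 2.0 * (fit_full.loglik - fit_nested.loglik))
    note = ""
    if fit_nested.model_tag == "single_level_multivariate" and df > 0:
        note = ("null constrains variance components to the boundary; the plain "
                "chi-square p-value is conservative")
    if df == 0:
        # degenerate comparison (e.g. a model against itself)
        p = 1.0 if chi2 <= 1e-10 else 0.0
    else:
        p = float(sps.chi2.sf(chi2, df=df))
    return LRTResult(chi2=float(chi2), df=int(df), p_value=p, note=note)


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(AIC, BIC) with BIC's sample size N = number of women (level-1 units)."""
    k = fit.n_params
    aic = -2.0 * fit.loglik + 2.0 * k
    bic = -2.0 * fit.loglik + k * math.log(fit.n_women)
    return float(aic), float(bic)


# ---------------------------------------------------------------------------
# Descriptive association and diagnostics
# ---------------------------------------------------------------------------

def empirical_outcome_correlation(records: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of (SBP, DBP) across women, with its two-sided p-value."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    sbp = records["sbp"].to_numpy(float)
    dbp = records["dbp"].to_numpy(float)
    if np.std(sbp) == 0 or np.std(dbp) == 0:
        raise ValueError("zero variance in an outcome")
    r, p = sps.pearsonr(sbp, dbp)
    return float(r), float(p)


def residual_qq_data(fit: FitResult, data: pd.DataFrame, design: np.ndarray
                     ) -> pd.DataFrame:
    """Ordered standardized marginal residuals with theoretical normal quantiles.

    Raw residuals ``y - X beta_hat`` are standardized by the marginal SD
    ``sqrt(var_h + var_e)`` per outcome and paired with ``Phi^{-1}((i-0.5)/N)``.
    Returns one row per (outcome, order statistic), ready for QQ plotting.
    """
    design = np.asarray(design, dtype=float)
    outcomes = (["sbp", "dbp"] if fit.params.beta2 is not None
                else [fit.outcome or "sbp"])
    betas = [fit.params.beta1] + ([fit.params.beta2] if fit.params.beta2 is not None else [])
    sh = np.diag(fit.params.varcomp.sigma_h)
    se = np.diag(fit.params.varcomp.sigma_e)
    frames = []
    for idx, (out_name, beta) in enumerate(zip(outcomes, betas)):
        resid = data[out_name].to_numpy(float) - design @ beta
        std = resid / math.sqrt(sh[idx] + se[idx])
        std.sort()
        n = len(std)
        theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        frames.append(pd.DataFrame({
            "outcome": out_name,
            "theoretical_quantile": theo,
            "sample_quantile": std,
        }))
    return pd.concat(frames, ignore_index=True)


def coefficient_table(fit: FitResult, z: float = 1.96) -> pd.DataFrame:
    """Estimates with Wald 95% intervals, one row per (outcome, design column)."""
    se_all = fit.standard_errors()
    p = len(fit.design_labels)
    outcomes = (["sbp"] if fit.params.beta2 is None else ["sbp", "dbp"])
    if fit.outcome is not None:
        outcomes = [fit.outcome]
    rows = []
    for block, out_name in enumerate(outcomes):
        beta = fit.params.beta1 if block == 0 else fit.params.beta2
        for k, label in enumerate(fit.design_labels):
            est = float(beta[k])
            se = float(se_all[block * p + k])
            rows.append({
                "outcome": out_name, "term": label, "estimate": est, "se": se,
                "ci_low": est - z * se, "ci_high": est + z * se,
            })
    return pd.DataFrame(rows)
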