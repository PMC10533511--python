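"""Statistical battery for cohort comparisons.

Two-sample t-tests (Welch by default), two-proportion z-tests, Bonferroni
family correction, crude 2x2 odds ratios with Woolf confidence intervals,
maximum-likelihood logistic odds ratios with Wald intervals, Pearson
correlation, and multiple linear regression.  Each procedure returns a
:class:`ComparisonResult` carrying the estimate, a 95% CI, raw and
family-adjusted p-values and the method name, so report renderers never
recompute statistics.

Standard fits go through scipy/statsmodels; only the 2x2 closed forms are
written out here because they double as the oracle for the logistic route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.proportion import proportions_ztest
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ComparisonResult",
    "ContingencyTable2x2",
    "RegressionSpec",
    "two_sample_t",
    "proportion_test",
    "bonferroni_adjust",
    "crude_or",
    "fit_logistic_or",
    "pearson_corr",
    "fit_linear",
]

Z95 = sps.norm.ppf(0.975)


@dataclass
class ComparisonResult:
    estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_raw: Optional[float]
    method: str
    p_adjusted: Optional[float] = None
    family_size: int = 1
    label: str = ""
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.p_adjusted is None and self.p_raw is not None:
            self.p_adjusted = min(1.0, self.p_raw * self.family_size)

    def adjust(self, family_size: int) -> "ComparisonResult":
        self.family_size = family_size
        if self.p_raw is not None:
            self.p_adjusted = min(1.0, self.p_raw * family_size)
        return self


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (exposed-event, exposed-nonevent,
    unexposed-event, unexposed-nonevent)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("cell counts must be non-negative integers")

    @classmethod
    def from_arrays(cls, exposed, event) -> "ContingencyTable2x2":
        exposed = np.asarray(exposed, bool)
        event = np.asarray(event, bool)
        return cls(int(np.sum(exposed & event)), int(np.sum(exposed & ~event)),
                   int(np.sum(~exposed & event)), int(np.sum(~exposed & ~event)))


@dataclass(frozen=True)
class RegressionSpec:
    """Declarative model: outcome ~ exposure (+ covariates), with the
    exposure's reference level for categorical contrasts."""

    outcome: str
    exposure: str
    covariates: tuple = ()
    reference: Optional[str] = None

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError("exposure duplicated among covariates")


def two_sample_t(x, y, pooled: bool = False) -> ComparisonResult:
    """Two-sided two-sample t-test; Welch unless ``pooled``.  Estimate is
    mean(x) - mean(y) with the matching 95% CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        # degenerate but well-defined: no evidence of any difference
        return ComparisonResult(0.0, 0.0, 0.0, 1.0, "t_pooled" if pooled else "t_welch")
    t, p = sps.ttest_ind(x, y, equal_var=pooled)
    diff = float(np.mean(x) - np.mean(y))
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    nx, ny = len(x), len(y)
    if pooled:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    tcrit = sps.t.ppf(0.975, df)
    return ComparisonResult(diff, diff - tcrit * se, diff + tcrit * se,
                            float(p), "t_pooled" if pooled else "t_welch")


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> ComparisonResult:
    """Two-sided two-proportion z-test on the pooled proportion; estimate is
    p1 - p2 with an unpooled Wald 95% CI."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("event counts out of range")
    p1, p2 = k1 / n1, k2 / n2
    diff = p1 - p2
    if (k1 + k2 == 0) or (k1 + k2 == n1 + n2):
        z, p = 0.0, 1.0
    else:
        z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    se = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return ComparisonResult(diff, diff - Z95 * se, diff + Z95 * se,
                            float(p), "proportion_z")


def bonferroni_adjust(p_values: Sequence[float], family_size: int) -> list[float]:
    """min(1, p * m); order-preserving."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"invalid p-value {p}")
        out.append(min(1.0, p * family_size))
    return out


def crude_or(table: ContingencyTable2x2) -> ComparisonResult:
    """Cross-product odds ratio with Woolf (log-scale Wald) 95% CI.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all four
    cells, flagged in the result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    flags = ()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags = ("haldane_correction",)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return ComparisonResult(float(or_), float(np.exp(log_or - Z95 * se)),
                            float(np.exp(log_or + Z95 * se)), float(p),
                            "crude_or", flags=flags)


def _design_matrix(data: pd.DataFrame, spec: RegressionSpec):
    """Complete-case design matrix: exposure dummies vs reference (if the
    exposure column is non-numeric), covariates as numeric columns."""
    cols = [spec.outcome, spec.exposure, *spec.covariates]
    df = data[cols].dropna()
    y = df[spec.outcome].astype(float)
    parts = []
    exposure_levels: list[str] = []
    exp = df[spec.exposure]
    if exp.dtype.kind in "OUSb" or isinstance(exp.dtype, pd.CategoricalDtype):
        levels = sorted(exp.astype(str).unique())
        ref = spec.reference if spec.reference is not None else levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from exposure")
        for lev in levels:
            if lev == ref:
                continue
            parts.append(pd.Series((exp.astype(str) == lev).astype(float),
                                   name=f"{spec.exposure}[{lev}]"))
            exposure_levels.append(lev)
    else:
        parts.append(exp.astype(float))
        exposure_levels.append(spec.exposure)
    for c in spec.covariates:
        col = df[c]
        if col.dtype.kind in "OUSb":
            for lev in sorted(col.astype(str).unique())[1:]:
                parts.append(pd.Series((col.astype(str) == lev).astype(float),
                                       name=f"{c}[{lev}]"))
        else:
            parts.append(col.astype(float))
    X = sm.add_constant(pd.concat(parts, axis=1))
    return y, X, exposure_levels


def fit_logistic_or(data: pd.DataFrame, spec: RegressionSpec) -> list[ComparisonResult]:
    """Maximum-likelihood logistic fit; one exponentiated coefficient (odds
    ratio) with Wald 95% CI per exposure level relative to the reference.

    Separation (monotone likelihood) is flagged with no estimate rather
    than reporting a divergent OR.
    """
    y, X, exposure_levels = _design_matrix(data, spec)
    if y.nunique() != 2:
        raise ValueError("outcome must be binary with both levels present")
    n_params = X.shape[1]
    if len(y) < 10 * n_params:
        raise ValueError(
            f"too few complete-case rows ({len(y)}) for {n_params} parameters"
        )
    try:
        with warnings.catch_warnings():
            # non-convergence and separation are detected and flagged below
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        separated = not fit.mle_retvals.get("converged", False) or \
            np.any(np.abs(fit.params) > 15)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        fit, separated = None, True
    out = []
    for lev in exposure_levels:
        name = f"{spec.exposure}[{lev}]" if fit is not None and \
            f"{spec.exposure}[{lev}]" in X.columns else lev
        if separated or name not in getattr(fit, "params", {}):
            out.append(ComparisonResult(None, None, None, None, "logistic_or",
                                        label=str(lev), flags=("separation",)))
            continue
        beta = fit.params[name]
        se = fit.bse[name]
        out.append(ComparisonResult(
            float(np.exp(beta)), float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)), float(fit.pvalues[name]),
            "logistic_or", label=str(lev)))
    return out


def pearson_corr(x, y) -> ComparisonResult:
    """Pearson r with two-sided p (t transform) and Fisher-z 95% CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need paired samples with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("degenerate variance")
    r, p = sps.pearsonr(x, y)
    n = len(x)
    if abs(r) < 1:
        z = np.arctanh(r)
        half = Z95 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo = hi = r
    return ComparisonResult(float(r), float(lo), float(hi), float(p), "pearson")


def fit_linear(data: pd.DataFrame, spec: RegressionSpec) -> list[ComparisonResult]:
    """Ordinary least squares; coefficients with 95% CIs for the exposure
    (and covariates).  Rank-deficient designs are flagged."""
    y, X, exposure_levels = _design_matrix(data, spec)
    if len(y) <= X.shape[1]:
        raise ValueError("complete-case rows must exceed parameter count")
    rank = np.linalg.matrix_rank(X.to_numpy())
    flags = ("rank_deficient",) if rank < X.shape[1] else ()
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = []
    for name in X.columns:
        if name == "const":
            continue
        out.append(ComparisonResult(
            float(fit.params[name]), float(ci.loc[name, 0]), float(ci.loc[name, 1]),
            float(fit.pvalues[name]), "linear", label=name, flags=flags))
    return out
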