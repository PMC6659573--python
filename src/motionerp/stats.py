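"""The statistical layer: paired comparisons with effect sizes and FDR,
Pearson screening, collinearity checks, stepwise forward regression, and
residual diagnostics.

Conventions (each pinned down by the printed worked examples it must
reproduce):

* Cohen's d for the paired test is mean(diff)/sd(diff), algebraically equal
  to t/sqrt(n).
* FDR is the Benjamini-Hochberg step-up adjustment.
* Adjusted R^2 is 1 - (1 - R^2)(n - 1)/(n - k - 1); from a printed
  F(k, n-k-1) it follows via R^2 = kF / (kF + n - k - 1).
* Normality is tested with the Lilliefors-corrected Kolmogorov-Smirnov test
  (parameters estimated from the data; the uncorrected test would be
  anticonservative).
* Stepwise forward selection adds the candidate with the smallest
  partial-F p-value while that p-value is below the entry threshold
  (default 0.05); there is no removal step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan, lilliefors
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.stattools import durbin_watson

from .errors import MotionErpError


@dataclass(frozen=True)
class PairedTestResult:
    variable: str
    t: float
    df: int
    p_raw: float
    d: float
    n: int
    p_fdr: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    predictor: str
    outcome: str
    r: float
    p: float
    n: int


@dataclass
class RegressionResult:
    """Final stepwise model with diagnostics and the full step log."""

    outcome: str
    predictors: list
    coefficients: dict            # name -> beta (incl. "const")
    f_stat: float
    df_model: int
    df_resid: int
    r2: float
    r2_adjusted: float
    p_model: float
    tolerance: dict = field(default_factory=dict)
    vif: dict = field(default_factory=dict)
    breusch_pagan_p: float | None = None
    durbin_watson: float | None = None
    ks_resid_p: float | None = None
    step_log: list = field(default_factory=list)
    flags: list = field(default_factory=list)


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size d = t / sqrt(n)."""
    return t / np.sqrt(n)


def r2_adjusted_from_f(f: float, k: int, n: int) -> float:
    """Adjusted R^2 implied by a printed F(k, n-k-1) statistic."""
    df_resid = n - k - 1
    r2 = k * f / (k * f + df_resid)
    return 1.0 - (1.0 - r2) * (n - 1) / df_resid


def paired_ttest(x_a, x_b, variable: str = "") -> PairedTestResult:
    """Two-tailed paired t-test of ``x_a`` vs ``x_b`` with Cohen's d.

    d is mean(diff)/sd(diff) = t/sqrt(n).  Raises on zero-variance
    differences (the statistic is undefined, not zero).
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape or x_a.ndim != 1:
        raise MotionErpError("paired test needs two equal-length vectors")
    n = x_a.size
    if n < 3:
        raise MotionErpError("paired test needs n >= 3")
    if not (np.isfinite(x_a).all() and np.isfinite(x_b).all()):
        raise MotionErpError("non-finite values in paired test input")
    diff = x_a - x_b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise MotionErpError("degenerate paired test: zero-variance differences")
    t, p = sp_stats.ttest_rel(x_a, x_b)
    d = float(diff.mean() / sd)
    return PairedTestResult(variable, float(t), n - 1, float(p), d, n)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise MotionErpError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_screen(
    predictors: pd.DataFrame,
    outcomes: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list, list, list]:
    """Pearson r of every predictor against every outcome.

    Returns ``(results, screened, dropped)``: the per-pair correlation
    results, the predictors significantly (p < alpha) correlated with at
    least one outcome (the regression candidate set), and a log of
    constant predictors dropped because r is undefined for them.
    """
    results, screened, dropped = [], [], []
    for pname in predictors.columns:
        x = predictors[pname].to_numpy(dtype=float)
        keep = False
        if np.std(x) == 0 or not np.isfinite(x).all():
            dropped.append(pname)
            continue
        for oname in outcomes.columns:
            y = outcomes[oname].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 4:
                raise MotionErpError("need >= 4 complete pairs for screening")
            r, p = sp_stats.pearsonr(x[mask], y[mask])
            results.append(CorrelationResult(pname, oname, float(r), float(p),
                                             int(mask.sum())))
            if p < alpha:
                keep = True
        if keep:
            screened.append(pname)
    return results, screened, dropped


def check_collinearity(
    predictors: pd.DataFrame,
    tol_thresh: float = 0.4,
) -> tuple[list, pd.DataFrame]:
    """Iteratively drop the most collinear predictor while any tolerance
    (1 - R^2 of that predictor on the others; 1/VIF) is below ``tol_thresh``.

    A single predictor has tolerance 1 by convention.  Returns the kept
    predictor names and a table with the final tolerance/VIF values (the
    dropped ones keep the value that caused their removal).
    """
    kept = list(predictors.columns)
    records = {}

    def tolerances(cols):
        out = {}
        for c in cols:
            others = [o for o in cols if o != c]
            if not others:
                out[c] = 1.0
                continue
            x = sm.add_constant(predictors[others].to_numpy(dtype=float))
            y = predictors[c].to_numpy(dtype=float)
            r2 = sm.OLS(y, x).fit().rsquared
            out[c] = max(1.0 - r2, 0.0)
        return out

    while kept:
        tols = tolerances(kept)
        records.update(tols)
        worst = min(tols, key=tols.get)
        if tols[worst] >= tol_thresh or len(kept) == 1:
            break
        kept.remove(worst)
    table = pd.DataFrame(
        {
            "predictor": list(records),
            "tolerance": [records[c] for c in records],
            "vif": [np.inf if records[c] == 0 else 1.0 / records[c]
                    for c in records],
            "kept": [c in kept for c in records],
        }
    )
    return kept, table


def stepwise_forward(
    y,
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    outcome_name: str = "y",
) -> RegressionResult:
    """Forward stepwise OLS: at each step add the candidate with the
    smallest partial-F p-value, while that p-value is below ``entry_p``.

    The partial F for adding one predictor equals the squared t of its
    coefficient in the augmented model, so the candidate evaluation uses
    the augmented-model t-test p-value directly.  Every candidate
    evaluation is recorded in the step log.  If no candidate enters, an
    intercept-only model is returned flagged ``"no-predictor-entered"``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    selected: list = []
    log: list = []
    while True:
        best_name, best_p = None, np.inf
        for name in candidates.columns:
            if name in selected:
                continue
            cols = selected + [name]
            x = sm.add_constant(candidates[cols].to_numpy(dtype=float))
            fit = sm.OLS(y, x).fit()
            p_add = float(fit.pvalues[-1])
            log.append({"step": len(selected) + 1, "candidate": name,
                        "partial_p": p_add})
            if p_add < best_p:
                best_name, best_p = name, p_add
        if best_name is None or best_p >= entry_p:
            break
        selected.append(best_name)

    if selected:
        x = sm.add_constant(candidates[selected].to_numpy(dtype=float))
        fit = sm.OLS(y, x).fit()
        coefs = {"const": float(fit.params[0])}
        coefs.update({nm: float(b) for nm, b in zip(selected, fit.params[1:])})
        res = RegressionResult(
            outcome=outcome_name,
            predictors=list(selected),
            coefficients=coefs,
            f_stat=float(fit.fvalue),
            df_model=int(fit.df_model),
            df_resid=int(fit.df_resid),
            r2=float(fit.rsquared),
            r2_adjusted=float(fit.rsquared_adj),
            p_model=float(fit.f_pvalue),
            step_log=log,
        )
        if len(selected) > 1:
            _, tol_table = check_collinearity(candidates[selected],
                                              tol_thresh=0.0)
            res.tolerance = dict(zip(tol_table["predictor"], tol_table["tolerance"]))
            res.vif = dict(zip(tol_table["predictor"], tol_table["vif"]))
        else:
            res.tolerance = {selected[0]: 1.0}
            res.vif = {selected[0]: 1.0}
        res = residual_diagnostics(res, y, candidates)
        return res
    return RegressionResult(
        outcome=outcome_name, predictors=[],
        coefficients={"const": float(y.mean())},
        f_stat=np.nan, df_model=0, df_resid=n - 1,
        r2=0.0, r2_adjusted=0.0, p_model=np.nan,
        step_log=log, flags=["no-predictor-entered"],
    )


def residual_diagnostics(result: RegressionResult, y, candidates: pd.DataFrame) -> RegressionResult:
    """Attach Breusch-Pagan (homoskedasticity), Durbin-Watson
    (autocorrelation), and Lilliefors-KS (residual normality) statistics."""
    y = np.asarray(y, dtype=float)
    k = len(result.predictors)
    if y.size < k + 3:
        raise MotionErpError("too few observations for residual diagnostics")
    x = sm.add_constant(candidates[result.predictors].to_numpy(dtype=float))
    fit = sm.OLS(y, x).fit()
    resid = fit.resid
    result.durbin_watson = float(durbin_watson(resid))
    if k >= 1:
        result.breusch_pagan_p = float(het_breuschpagan(resid, x)[1])
    if resid.std() > 0:
        result.ks_resid_p = float(lilliefors(resid, dist="norm")[1])
    return result
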