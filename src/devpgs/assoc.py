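"""Phenotype association models for polygenic scores.

Mixed-effects regressions of psychopathology scales on PGS columns (site as
a random intercept; ordinary least squares when only one site is present),
marginal delta-R2, nested model comparisons, top-versus-bottom-quintile
logistic odds ratios at the clinical cutoff, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "sex", "PC1", "PC2", "PC3", "PC4", "PC5"]


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1.  ``m`` defaults to the number of p-values but
    can be set larger when the declared comparison grid exceeds the tests
    actually run.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = m if m is not None else p.size
    if m < p.size:
        raise ValueError("m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class AssocResult:
    outcome: str
    predictor: str
    beta: float
    se: float
    p: float
    delta_r2: float
    delta_r2_conditional: float | None = None
    model: str = "mixed"
    q: float | None = None


def _design(
    pheno: pd.DataFrame, scores: pd.DataFrame | None, columns: list[str]
) -> pd.DataFrame:
    frames = [pheno.reset_index(drop=True)]
    if scores is not None:
        aligned = scores.reindex(pheno["sample_id"]).reset_index(drop=True)
        frames.append(aligned)
    merged = pd.concat(frames, axis=1)
    missing = [c for c in columns if c not in merged.columns]
    if missing:
        raise ValueError(f"columns not found: {missing}")
    x = merged[columns].astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x.to_numpy()]))
    if rank < x.shape[1] + 1:
        corr = np.corrcoef(x.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        worst = [
            columns[i]
            for i in range(len(columns))
            if np.any(np.abs(corr[i]) > 0.999) or x.iloc[:, i].std() == 0
        ]
        raise ValueError(f"design matrix is rank-deficient; collinear: {worst}")
    return merged


def _fit_model(y: np.ndarray, x: pd.DataFrame, site: pd.Series):
    """REML mixed model with site random intercept, or OLS for one site.

    Returns (params, bse, pvalues, marginal_r2, conditional_r2, kind).
    """
    exog = sm.add_constant(x.astype(float))
    if site.nunique() <= 1:
        fit = sm.OLS(y, exog).fit()
        fitted = fit.fittedvalues
        r2 = float(np.var(fitted) / np.var(y)) if np.var(y) > 0 else 0.0
        return fit.params, fit.bse, fit.pvalues, r2, r2, "ols"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=site.to_numpy())
        fit = model.fit(reml=True)
    params = fit.params[exog.columns]
    fixed = exog.to_numpy() @ params.to_numpy()
    var_f = float(np.var(fixed))
    var_u = float(fit.cov_re.iloc[0, 0])
    var_e = float(fit.scale)
    total = var_f + var_u + var_e
    marg = var_f / total if total > 0 else 0.0
    cond = (var_f + var_u) / total if total > 0 else 0.0
    zstats = params / fit.bse[exog.columns]
    pvals = pd.Series(
        2 * stats.norm.sf(np.abs(zstats.to_numpy())), index=params.index
    )
    return params, fit.bse[exog.columns], pvals, marg, cond, "mixed"


def pgs_phenotype_regression(
    pheno: pd.DataFrame,
    scores: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: list[str] | None = None,
) -> AssocResult:
    """Mixed-model association of one phenotype scale with one PGS column.

    Covariates default to age, sex and five ancestry PCs as fixed effects
    with site as a random intercept; single-site data fall back to OLS.
    ``delta_r2`` is the marginal (fixed-effects) R2 of the full model minus
    the covariates-only model; the conditional counterpart (adding the site
    variance to the numerator) is reported alongside.
    """
    covariates = covariates if covariates is not None else DEFAULT_COVARIATES
    merged = _design(pheno, scores, covariates + [predictor])
    y = merged[outcome].to_numpy(float)
    site = merged["site"] if "site" in merged.columns else pd.Series(["s"] * len(merged))

    params, bse, pvals, r2_full, r2c_full, kind = _fit_model(
        y, merged[covariates + [predictor]], site
    )
    _, _, _, r2_base, r2c_base, _ = _fit_model(y, merged[covariates], site)
    return AssocResult(
        outcome=outcome,
        predictor=predictor,
        beta=float(params[predictor]),
        se=float(bse[predictor]),
        p=float(pvals[predictor]),
        delta_r2=r2_full - r2_base,
        delta_r2_conditional=r2c_full - r2c_base,
        model=kind,
    )


def nested_pgs_comparison(
    pheno: pd.DataFrame,
    scores: pd.DataFrame,
    outcome: str,
    base_pgs: str,
    added_pgs: str,
    covariates: list[str] | None = None,
) -> dict:
    """Does ``added_pgs`` explain variance beyond ``base_pgs``?

    Fits covariates + base, then adds the second score; reports the added
    term's Wald p and the marginal-R2 increment.
    """
    if base_pgs == added_pgs:
        raise ValueError("base and added PGS must differ")
    covariates = covariates if covariates is not None else DEFAULT_COVARIATES
    base_design = _design(pheno, scores, covariates + [base_pgs])
    probe = pd.concat(
        [
            base_design[covariates + [base_pgs]],
            scores.reindex(pheno["sample_id"])[[added_pgs]].reset_index(drop=True),
        ],
        axis=1,
    ).astype(float)
    with_const = np.column_stack([np.ones(len(probe)), probe.to_numpy()])
    if np.linalg.matrix_rank(with_const) < with_const.shape[1]:
        # the added score is an affine combination of what is already in
        # the model: it cannot add variance
        return {
            "outcome": outcome,
            "base": base_pgs,
            "added": added_pgs,
            "beta_added": 0.0,
            "p_added": 1.0,
            "delta_r2": 0.0,
            "model": "degenerate",
        }
    merged = _design(pheno, scores, covariates + [base_pgs, added_pgs])
    y = merged[outcome].to_numpy(float)
    site = merged["site"] if "site" in merged.columns else pd.Series(["s"] * len(merged))
    params, bse, pvals, r2_full, _, kind = _fit_model(
        y, merged[covariates + [base_pgs, added_pgs]], site
    )
    _, _, _, r2_base, _, _ = _fit_model(y, merged[covariates + [base_pgs]], site)
    return {
        "outcome": outcome,
        "base": base_pgs,
        "added": added_pgs,
        "beta_added": float(params[added_pgs]),
        "p_added": float(pvals[added_pgs]),
        "delta_r2": r2_full - r2_base,
        "model": kind,
    }


def quintile_logistic_or(
    pheno: pd.DataFrame,
    quintiles: pd.DataFrame,
    score_col: str,
    outcome_flag: str = "clinical",
    covariates: list[str] | None = None,
    exclude_flag: str | None = None,
) -> dict:
    """Odds of clinical-range psychopathology, top versus bottom quintile.

    Restricts to individuals in the top or bottom quintile of
    ``score_col``, then fits a logistic regression of the outcome flag on
    the top-quintile indicator plus covariates (pass ``covariates=[]`` for
    the unadjusted cross-product OR with Woolf confidence limits).
    ``exclude_flag`` supports the emergent-psychopathology design: rows
    with that flag set are removed before modelling (e.g., exclude
    baseline-clinical children and test year-2 flags).
    """
    covariates = covariates if covariates is not None else DEFAULT_COVARIATES
    merged = _design(pheno, None, [])
    q = quintiles.reindex(merged["sample_id"])[score_col].to_numpy()
    merged = merged.assign(_q=q)
    if exclude_flag is not None:
        merged = merged[~merged[exclude_flag].astype(bool)]
    sub = merged[(merged["_q"] == 1) | (merged["_q"] == 5)].copy()
    sub["top"] = (sub["_q"] == 5).astype(float)
    y = sub[outcome_flag].astype(float).to_numpy()

    # unadjusted zero-cell fallback: Haldane-Anscombe 0.5 correction
    a = float(((sub["top"] == 1) & (y == 1)).sum())
    b = float(((sub["top"] == 1) & (y == 0)).sum())
    c = float(((sub["top"] == 0) & (y == 1)).sum())
    d = float(((sub["top"] == 0) & (y == 0)).sum())
    if not covariates and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        logor = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return {
            "or": float(np.exp(logor)),
            "ci": (float(np.exp(logor - 1.96 * se)), float(np.exp(logor + 1.96 * se))),
            "p": float(2 * stats.norm.sf(abs(logor / se))),
            "corrected": True,
            "n": len(sub),
        }
    cols = ["top"] + covariates
    exog = sm.add_constant(sub[cols].astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    logor = float(fit.params["top"])
    se = float(fit.bse["top"])
    return {
        "or": float(np.exp(logor)),
        "ci": (float(np.exp(logor - 1.96 * se)), float(np.exp(logor + 1.96 * se))),
        "p": float(fit.pvalues["top"]),
        "corrected": False,
        "n": len(sub),
    }


def association_grid(
    pheno: pd.DataFrame,
    scores: pd.DataFrame,
    outcomes: list[str],
    predictors: list[str],
    covariates: list[str] | None = None,
    fdr_m: int | None = None,
) -> pd.DataFrame:
    """All (outcome, predictor) regressions with grid-wide BH q-values."""
    results = [
        pgs_phenotype_regression(pheno, scores, out, pred, covariates=covariates)
        for out in outcomes
        for pred in predictors
    ]
    df = pd.DataFrame([r.__dict__ for r in results])
    df["q"] = bh_fdr(df["p"].to_numpy(), m=fdr_m)
    return df
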