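"""Cohort statistics: metabolite screening, compositional abundance tests,
flux comparisons, and multiple-testing correction.

The regressions delegate to statsmodels: OLS with heteroscedasticity-robust
(sandwich, HC3 by default) covariances for metabolite and flux screens, and
a fractional (quasi-binomial logit) GLM for relative abundances, matching
the econometric "fractional regression" estimator. Welch's t-test and the
Benjamini–Hochberg step-up come from scipy/statsmodels.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_CONFIG
from .errors import ValidationError

logger = logging.getLogger(__name__)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _design(
    n: int,
    groups: pd.Series,
    covariates: Optional[pd.DataFrame],
    reference: Optional[str],
) -> pd.DataFrame:
    groups = pd.Series(groups).astype("category")
    if reference is not None:
        if reference not in groups.cat.categories:
            raise ValidationError(f"reference group {reference!r} not present")
        groups = groups.cat.reorder_categories(
            [reference] + [c for c in groups.cat.categories if c != reference]
        )
    dummies = pd.get_dummies(groups, prefix="group", drop_first=True, dtype=float)
    X = dummies
    if covariates is not None and len(covariates.columns):
        cov = covariates.copy()
        for col in list(cov.columns):
            if cov[col].dtype == object or str(cov[col].dtype) == "category":
                cov = pd.concat(
                    [cov.drop(columns=[col]),
                     pd.get_dummies(cov[col], prefix=col, drop_first=True, dtype=float)],
                    axis=1,
                )
        constant = [c for c in cov.columns if cov[c].nunique() <= 1]
        if constant:
            logger.warning("dropping constant covariate columns: %s", constant)
            cov = cov.drop(columns=constant)
        X = pd.concat([X, cov.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    return X


def screen_metabolites(
    concentrations: pd.DataFrame,
    groups: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    min_nonzero: float = DEFAULT_CONFIG.min_nonzero,
    reference: str = "control",
    case: Optional[str] = None,
    robust: str = DEFAULT_CONFIG.robust_cov,
) -> pd.DataFrame:
    """Screen sample × metabolite concentrations for group differences.

    Zero measurements are treated as missing; metabolites with fewer than
    ``min_nonzero`` non-zero values are excluded (recorded with
    ``excluded=True``). For each retained metabolite the log concentration
    is regressed on the group factor plus covariates by OLS; the global
    group effect is a robust joint Wald test of all group dummies, and the
    case-vs-reference contrast is the corresponding dummy's robust test.
    q-values are Benjamini–Hochberg across the retained metabolites.
    """
    if (concentrations.values[np.isfinite(concentrations.values)] < 0).any():
        raise ValidationError("concentrations must be non-negative")
    groups = pd.Series(groups).loc[concentrations.index]
    group_levels = sorted(set(groups))
    if case is None:
        case = next(g for g in group_levels if g != reference)
    rows = []
    for met in concentrations.columns:
        y = concentrations[met].replace(0.0, np.nan)
        frac = y.notna().mean()
        if frac < min_nonzero:
            rows.append({"metabolite": met, "n_used": int(y.notna().sum()),
                         "excluded": True, "estimate": np.nan, "se": np.nan,
                         "p_global": np.nan, "p_case": np.nan})
            continue
        mask = y.notna()
        X = _design(mask.sum(), groups[mask],
                    covariates.loc[mask] if covariates is not None else None,
                    reference)
        fit = sm.OLS(np.log(y[mask].astype(float)), X).fit(cov_type=robust)
        gcols = [c for c in X.columns if c.startswith("group_")]
        constraint = ", ".join(f"{c} = 0" for c in gcols)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_global = float(np.squeeze(fit.wald_test(constraint, use_f=True, scalar=True).pvalue))
        case_col = f"group_{case}"
        if case_col in fit.params.index:
            est = float(fit.params[case_col])
            se = float(fit.bse[case_col])
            p_case = float(fit.pvalues[case_col])
        else:
            est = se = p_case = np.nan
        rows.append({"metabolite": met, "n_used": int(mask.sum()),
                     "excluded": False, "estimate": est, "se": se,
                     "p_global": p_global, "p_case": p_case})
    out = pd.DataFrame(rows).set_index("metabolite")
    kept = ~out["excluded"]
    out["q_case"] = np.nan
    out.loc[kept, "q_case"] = bh_fdr(out.loc[kept, "p_case"])
    out["q_global"] = np.nan
    out.loc[kept, "q_global"] = bh_fdr(out.loc[kept, "p_global"])
    return out


def fractional_regression(
    abundances: pd.DataFrame,
    outcome: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    min_presence: float = DEFAULT_CONFIG.min_nonzero,
    reference: str = "control",
    robust: str = DEFAULT_CONFIG.robust_cov,
) -> pd.DataFrame:
    """Fractional (quasi-binomial logit) regression of each species' relative
    abundance on case/control status plus covariates.

    Species present (non-zero) in fewer than ``min_presence`` of the samples
    are excluded. Standard errors are sandwich-robust; non-converged fits
    are flagged, not raised.
    """
    vals = abundances.values.astype(float)
    if np.any(vals < 0) or np.any(vals > 1 + 1e-9):
        raise ValidationError("relative abundances must lie in [0, 1]")
    outcome = pd.Series(outcome).loc[abundances.index]
    rows = []
    for sp in abundances.columns:
        y = abundances[sp].astype(float)
        presence = (y > 0).mean()
        if presence < min_presence:
            rows.append({"species": sp, "excluded": True, "converged": False,
                         "estimate": np.nan, "se": np.nan, "p": np.nan})
            continue
        X = _design(len(y), outcome, covariates, reference)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(y, X, family=sm.families.Binomial())
                fit = glm.fit(cov_type=robust, maxiter=100)
            converged = bool(fit.converged)
        except Exception as exc:  # noqa: BLE001 - separation etc.
            logger.warning("fractional regression failed for %r: %s", sp, exc)
            rows.append({"species": sp, "excluded": False, "converged": False,
                         "estimate": np.nan, "se": np.nan, "p": np.nan})
            continue
        gcols = [c for c in X.columns if c.startswith("group_")]
        col = gcols[0] if gcols else None
        rows.append({
            "species": sp, "excluded": False, "converged": converged,
            "estimate": float(fit.params[col]) if col else np.nan,
            "se": float(fit.bse[col]) if col else np.nan,
            "p": float(fit.pvalues[col]) if (col and converged) else np.nan,
        })
    out = pd.DataFrame(rows).set_index("species")
    ok = (~out["excluded"]) & out["converged"] & out["p"].notna()
    out["q"] = np.nan
    out.loc[ok, "q"] = bh_fdr(out.loc[ok, "p"])
    return out


def log_ratio_test(
    counts: pd.DataFrame,
    up_set: Sequence[str],
    down_set: Sequence[str],
    groups: pd.Series,
    pseudocount: float = DEFAULT_CONFIG.pseudocount,
) -> Dict[str, object]:
    """Per-sample log ratio of summed up-set vs down-set counts, compared
    between groups with Welch's t-test.

    The pseudocount is added to every count before summation so empty sets
    of reads do not produce infinities; a zero denominator with pseudocount
    0 is an error.
    """
    up_set, down_set = list(up_set), list(down_set)
    if not up_set or not down_set:
        raise ValidationError("up and down species sets must be non-empty")
    missing = [s for s in up_set + down_set if s not in counts.columns]
    if missing:
        raise ValidationError(f"species not in the count table: {missing}")
    shifted = counts.astype(float) + pseudocount
    num = shifted[up_set].sum(axis=1)
    den = shifted[down_set].sum(axis=1)
    if (den <= 0).any():
        raise ValidationError(
            "zero down-set counts with zero pseudocount; increase the pseudocount"
        )
    lr = np.log(num / den)
    groups = pd.Series(groups).loc[counts.index]
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValidationError(f"log-ratio test needs exactly two groups, got {levels}")
    a = lr[groups == levels[0]]
    b = lr[groups == levels[1]]
    if lr.std(ddof=1) == 0:
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = sps.ttest_ind(a, b, equal_var=False)
    return {
        "log_ratio": lr,
        "group_means": {levels[0]: float(a.mean()), levels[1]: float(b.mean())},
        "t": float(t_stat),
        "p": float(p),
    }


def compare_fluxes(
    fluxes: pd.Series,
    groups: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    reference: str = "control",
    robust: str = DEFAULT_CONFIG.robust_cov,
) -> pd.DataFrame:
    """OLS of one flux per sample on case/control status plus covariates
    (APOE genotype, sex), with robust standard errors.

    Returns one row per model term with estimate, robust SE, 95% CI and p.
    """
    fluxes = pd.Series(fluxes).astype(float)
    groups = pd.Series(groups).loc[fluxes.index]
    X = _design(len(fluxes), groups, covariates, reference)
    fit = sm.OLS(fluxes, X).fit(cov_type=robust)
    ci = fit.conf_int()
    out = pd.DataFrame({
        "estimate": fit.params,
        "se": fit.bse,
        "stat": fit.tvalues,
        "p": fit.pvalues,
        "ci_low": ci[0],
        "ci_high": ci[1],
    })
    out.index.name = "term"
    return out


def welch_t(a: Sequence[float], b: Sequence[float]):
    """Welch two-sample t-test (unequal variances)."""
    t, p = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(t), float(p)
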