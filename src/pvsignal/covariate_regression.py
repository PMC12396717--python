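"""Logistic-regression sensitivity analysis of per-report event occurrence.

Within the target drug's reports, the occurrence of one event term is
regressed on sex (male vs female), age (continuous years by default) and
body weight (≥50 kg vs <50 kg), univariately and multivariately.  The
multivariate fit is complete-case: a report missing any covariate is
excluded; univariate fits drop only rows missing that covariate.  Fits are
maximum likelihood via iteratively reweighted least squares (statsmodels),
tolerance 1e-8, at most 100 iterations; failures (non-convergence,
complete separation, no contrast) are flagged, never silently numeric.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .faers_ingest import CaseRecord
from .target_selection import normalize_pt

logger = logging.getLogger(__name__)

__all__ = ["CovariateRow", "RegressionResult", "DesignError",
           "build_design", "fit_logistic", "regression_frame",
           "TERMS", "AGE_CODING_CONTINUOUS", "AGE_CODING_BINNED"]

TERMS = ["sex_male", "age_years", "weight_ge50"]
AGE_CODING_CONTINUOUS = "continuous"
AGE_CODING_BINNED = "binned"  # indicator per reporting stratum, <18 reference

_Z95 = 1.959963984540054


class DesignError(ValueError):
    """The design cannot support a fit (too few rows, single-class outcome)."""


@dataclass(frozen=True)
class CovariateRow:
    """One report encoded for regression.

    outcome is 1 when the report contains the target term, 0 for any other
    report of the target drug.  Reference levels: female, weight <50 kg.
    """

    caseid: str
    outcome: int
    sex_male: Optional[int]
    age_years: Optional[float]
    weight_ge50: Optional[int]


@dataclass
class RegressionResult:
    term: str
    model: str  # univariate | multivariate
    odds_ratio: Optional[float]
    ci95: Optional[tuple]
    p_value: Optional[float]
    n_used: int
    status: str = "ok"  # ok | no-contrast | separation | non-convergence

    @property
    def estimable(self) -> bool:
        return self.status == "ok"


def build_design(cases: Sequence[CaseRecord], target_pt: str) -> List[CovariateRow]:
    """Encode each target-drug report against one event term.

    Missing covariates stay None here; each fit applies its own
    complete-case rule and logs what it dropped.
    """
    pt = normalize_pt(target_pt)
    rows = []
    for case in cases:
        events = {normalize_pt(p) for p in case.events}
        rows.append(
            CovariateRow(
                caseid=case.caseid,
                outcome=int(pt in events),
                sex_male={"M": 1, "F": 0}.get(case.sex),
                age_years=case.age_years,
                weight_ge50=None if case.weight_kg is None else int(case.weight_kg >= 50),
            )
        )
    return rows


def _frame(rows: Sequence[CovariateRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.caseid, r.outcome, r.sex_male, r.age_years, r.weight_ge50) for r in rows],
        columns=["caseid", "outcome", "sex_male", "age_years", "weight_ge50"],
    )


def _fit_one(df: pd.DataFrame, terms: List[str], model_label: str) -> List[RegressionResult]:
    n = len(df)
    if n < 10:
        raise DesignError(f"{model_label} design has {n} usable rows (< 10)")
    y = df["outcome"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise DesignError(f"{model_label} outcome is single-class; nothing to fit")
    degenerate = [t for t in terms if df[t].nunique() < 2]
    results = [
        RegressionResult(t, model_label, None, None, None, n, status="no-contrast")
        for t in degenerate
    ]
    live = [t for t in terms if t not in degenerate]
    if not live:
        return results
    x = sm.add_constant(df[live].to_numpy(dtype=float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            fit = sm.Logit(y, x).fit(method="newton", tol=1e-8, maxiter=100, disp=False)
    except PerfectSeparationError:
        logger.warning("%s fit: complete separation", model_label)
        return results + [
            RegressionResult(t, model_label, None, None, None, n, status="separation")
            for t in live
        ]
    except (ConvergenceWarning, np.linalg.LinAlgError, ValueError, RuntimeError) as exc:
        logger.warning("%s fit failed: %s", model_label, exc)
        return results + [
            RegressionResult(t, model_label, None, None, None, n, status="non-convergence")
            for t in live
        ]
    if not fit.mle_retvals.get("converged", True):
        return results + [
            RegressionResult(t, model_label, None, None, None, n, status="non-convergence")
            for t in live
        ]
    for i, t in enumerate(live, start=1):
        coef, se = fit.params[i], fit.bse[i]
        results.append(
            RegressionResult(
                term=t,
                model=model_label,
                odds_ratio=math.exp(coef),
                ci95=(math.exp(coef - _Z95 * se), math.exp(coef + _Z95 * se)),
                p_value=float(fit.pvalues[i]),
                n_used=n,
            )
        )
    return results


def fit_logistic(
    rows: Sequence[CovariateRow],
    terms: Optional[List[str]] = None,
    models: Sequence[str] = ("univariate", "multivariate"),
) -> List[RegressionResult]:
    """Univariate (one covariate at a time) and multivariate logistic fits.

    Returns one RegressionResult per (model, term); inestimable terms carry
    a status instead of numbers.
    """
    terms = terms or TERMS
    df = _frame(rows)
    out: List[RegressionResult] = []
    if "univariate" in models:
        for t in terms:
            sub = df.dropna(subset=[t])
            dropped = len(df) - len(sub)
            if dropped:
                logger.info("univariate %s: dropped %d row(s) missing the covariate", t, dropped)
            out.extend(_fit_one(sub, [t], "univariate"))
    if "multivariate" in models:
        sub = df.dropna(subset=terms)
        dropped = len(df) - len(sub)
        if dropped:
            logger.info("multivariate: dropped %d row(s) with any missing covariate", dropped)
        out.extend(_fit_one(sub, list(terms), "multivariate"))
    return out


def regression_frame(results: Sequence[RegressionResult], pt: str) -> pd.DataFrame:
    """TSV-shaped frame: PT, model, term, OR, CI_low, CI_high, P, N, status."""
    rows = []
    for r in results:
        lo, hi = r.ci95 if r.ci95 else (None, None)
        rows.append((pt, r.model, r.term, r.odds_ratio, lo, hi, r.p_value, r.n_used, r.status))
    return pd.DataFrame(
        rows, columns=["PT", "model", "term", "OR", "CI_low", "CI_high", "P", "N", "status"]
    )
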