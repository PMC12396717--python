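"""The four disproportionality statistics and the consensus signal call.

Given the 2×2 table (a, b, c, d) of one drug–event pair:

*   ROR  = ad/bc, with a lognormal Wald interval
    exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d));
*   PRR  = [a/(a+b)] / [c/(c+d)], interval
    exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)));
*   BCPNN information component IC = log₂ aN/((a+b)(a+c)), with a
    closed-form posterior expectation E(IC) and variance V(IC) under
    Dirichlet priors, and the credibility bound IC025 = E(IC) − 2√V(IC);
*   MGPS observed/expected ratio EBGM = aN/((a+b)(a+c)) — the closed
    relative-reporting form, without gamma-mixture shrinkage — with
    EBGM05 = exp(ln EBGM − 1.96·√(1/a + 1/b + 1/c + 1/d)).

A term is a *consensus signal* when all four methods fire at once:
a ≥ 3, both frequentist lower 95% limits > 1, IC025 > 0 and EBGM05 > 2.
Wald p-values on ln ROR / ln PRR support a Bonferroni screen whose
default multiplicity is the drug's event-record total.

Note IC ≡ log₂ EBGM by construction; the two methods differ only in
their interval rules.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .contingency import A_MIN, ContingencyTable

__all__ = [
    "BcpnnPriors", "Thresholds", "SignalEstimate", "BonferroniClass",
    "ror", "prr", "chi2", "ic", "ic_credible", "ebgm",
    "wald_p", "bonferroni", "consensus", "evaluate", "signal_table",
    "P_FLOOR", "SIGNAL_TABLE_COLUMNS",
]

P_FLOOR = 1e-300  # reported p-values are floored here, never printed as 0
_Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class BcpnnPriors:
    """Dirichlet hyper-parameters of the BCPNN posterior (canonical defaults)."""

    alpha: float = 2.0
    alpha1: float = 1.0
    beta: float = 2.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def gamma(self, t: ContingencyTable) -> float:
        """Joint prior scale, tuned so that E(IC) ≈ 0 under independence."""
        n = t.n
        return (
            self.gamma11
            * (n + self.alpha) * (n + self.beta)
            / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1))
        )


@dataclass(frozen=True)
class Thresholds:
    """Per-method positivity rules; all four must hold for consensus."""

    a_min: int = A_MIN
    ror_prr_lower: float = 1.0  # 95% CI lower limit must exceed this
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


class BonferroniClass(str, enum.Enum):
    STRONG = "strong"
    POTENTIAL = "potential"
    NON_SIGNIFICANT = "non-significant"


def _se_log_or(t: ContingencyTable) -> float:
    return math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)


def _has_zero_cell(t: ContingencyTable) -> bool:
    return min(t.a, t.b, t.c, t.d) == 0


def ror(t: ContingencyTable) -> Tuple[float, Tuple[float, float]]:
    """Reporting odds ratio with its lognormal 95% CI.

    Returns (nan, (nan, nan)) on a zero cell: undefined rather than
    continuity-corrected (use ContingencyTable.with_continuity to opt in).
    """
    if _has_zero_cell(t):
        return math.nan, (math.nan, math.nan)
    est = (t.a * t.d) / (t.b * t.c)
    half = _Z95 * _se_log_or(t)
    log = math.log(est)
    return est, (math.exp(log - half), math.exp(log + half))


def prr(t: ContingencyTable) -> Tuple[float, Tuple[float, float]]:
    """Proportional reporting ratio with its lognormal 95% CI."""
    if t.a == 0 or t.c == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return math.nan, (math.nan, math.nan)
    est = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    var = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
    if var < 0:  # numerically impossible for valid counts; guard regardless
        return est, (math.nan, math.nan)
    half = _Z95 * math.sqrt(var)
    log = math.log(est)
    return est, (math.exp(log - half), math.exp(log + half))


def chi2(t: ContingencyTable) -> float:
    """Pearson chi-squared without continuity correction."""
    a, b, c, d = (float(t.a), float(t.b), float(t.c), float(t.d))  # avoid int overflow
    margins = (a + b, c + d, a + c, b + d)
    if min(margins) == 0:
        return math.nan
    num = (a + b + c + d) * (a * d - b * c) ** 2
    den = margins[0] * margins[1] * margins[2] * margins[3]
    return num / den


def ic(t: ContingencyTable) -> float:
    """Information component: log₂ of the observed/expected joint probability."""
    if t.a == 0 or t.a + t.b == 0 or t.a + t.c == 0:
        return math.nan
    return math.log2(t.a * t.n / ((t.a + t.b) * (t.a + t.c)))


def ic_credible(
    t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()
) -> Tuple[float, float, float]:
    """(E(IC), V(IC), IC025) under the closed-form BCPNN posterior.

    Defined for any table, including a = 0, because the priors keep every
    term positive.  IC025 = E(IC) − 2√V(IC).
    """
    a, n = t.a, t.n
    ab, ac = t.a + t.b, t.a + t.c
    g = priors.gamma(t)
    e_ic = math.log2(
        (a + priors.gamma11) * (n + priors.alpha) * (n + priors.beta)
        / ((n + g) * (ab + priors.alpha1) * (ac + priors.beta1))
    )
    v_ic = (
        (n - a + g - priors.gamma11) / ((a + priors.gamma11) * (1 + n + g))
        + (n - ab + priors.alpha - priors.alpha1)
        / ((ab + priors.alpha1) * (1 + n + priors.alpha))
        + (n - ac + priors.beta - priors.beta1)
        / ((ac + priors.beta1) * (1 + n + priors.beta))
    ) / (math.log(2) ** 2)
    return e_ic, v_ic, e_ic - 2 * math.sqrt(v_ic)


def ebgm(t: ContingencyTable) -> Tuple[float, float]:
    """(EBGM, EBGM05): the observed/expected ratio and its lower 95% bound."""
    if t.a == 0 or t.a + t.b == 0 or t.a + t.c == 0:
        return math.nan, math.nan
    est = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    if _has_zero_cell(t):
        return est, math.nan
    lo = math.exp(math.log(est) - _Z95 * _se_log_or(t))
    return est, lo


def wald_p(log_estimate: float, se: float) -> float:
    """Two-sided normal p on a log-scale estimate, floored at 1e-300."""
    if not math.isfinite(log_estimate) or not math.isfinite(se) or se <= 0:
        return math.nan
    p = 2.0 * _sps.norm.sf(abs(log_estimate) / se)
    return min(1.0, max(P_FLOOR, float(p)))


def bonferroni(p: float, m: int) -> BonferroniClass:
    """Classify a p-value under Bonferroni multiplicity m.

    strong: p < 0.05/m;  potential: 0.05/m <= p < 0.05;  else non-significant.
    """
    if m < 1:
        raise ValueError("multiplicity m must be >= 1")
    if not math.isfinite(p):
        return BonferroniClass.NON_SIGNIFICANT
    if p < 0.05 / m:
        return BonferroniClass.STRONG
    if p < 0.05:
        return BonferroniClass.POTENTIAL
    return BonferroniClass.NON_SIGNIFICANT


@dataclass
class SignalEstimate:
    """Every statistic, interval and flag for one (drug, term) pair."""

    term: str
    level: str
    a: float
    frequency: float  # a / drug event total
    ror: float
    ror_ci95: Tuple[float, float]
    prr: float
    prr_ci95: Tuple[float, float]
    chi2: float
    ic: float
    e_ic: float
    v_ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    p_ror: float
    p_prr: float
    bonferroni_class: BonferroniClass = BonferroniClass.NON_SIGNIFICANT
    bonferroni_significant: bool = False
    consensus_signal: bool = False
    defined: bool = True  # False when a zero cell left estimates undefined
    soc: Optional[str] = None


def consensus(e: SignalEstimate, th: Thresholds = Thresholds()) -> bool:
    """All-methods positivity: a≥3 ∧ ROR/PRR lower limits >1 ∧ IC025>0 ∧ EBGM05>2."""
    checks = (e.ror_ci95[0], e.prr_ci95[0], e.ic025, e.ebgm05)
    if any(not math.isfinite(x) for x in checks):
        return False
    return (
        e.a >= th.a_min
        and e.ror_ci95[0] > th.ror_prr_lower
        and e.prr_ci95[0] > th.ror_prr_lower
        and e.ic025 > th.ic025_min
        and e.ebgm05 > th.ebgm05_min
    )


def evaluate(
    t: ContingencyTable,
    term: str = "",
    level: str = "PT",
    priors: BcpnnPriors = BcpnnPriors(),
    thresholds: Thresholds = Thresholds(),
    m: int = 1,
    soc: Optional[str] = None,
) -> SignalEstimate:
    """Full evaluation of one table: points, intervals, p-values, flags."""
    ror_est, ror_ci = ror(t)
    prr_est, prr_ci = prr(t)
    ic_est = ic(t)
    e_ic, v_ic, ic025 = ic_credible(t, priors)
    ebgm_est, ebgm05 = ebgm(t)
    p_r = wald_p(math.log(ror_est), _se_log_or(t)) if not _has_zero_cell(t) else math.nan
    if math.isfinite(prr_est):
        var_prr = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
        p_p = wald_p(math.log(prr_est), math.sqrt(var_prr)) if var_prr > 0 else math.nan
    else:
        p_p = math.nan
    est = SignalEstimate(
        term=term,
        level=level,
        a=t.a,
        frequency=t.a / (t.a + t.b) if t.a + t.b > 0 else math.nan,
        ror=ror_est,
        ror_ci95=ror_ci,
        prr=prr_est,
        prr_ci95=prr_ci,
        chi2=chi2(t),
        ic=ic_est,
        e_ic=e_ic,
        v_ic=v_ic,
        ic025=ic025,
        ebgm=ebgm_est,
        ebgm05=ebgm05,
        p_ror=p_r,
        p_prr=p_p,
        defined=not _has_zero_cell(t),
        soc=soc,
    )
    cls = bonferroni(p_r, m) if math.isfinite(p_r) else BonferroniClass.NON_SIGNIFICANT
    est.bonferroni_class = cls
    est.bonferroni_significant = cls is BonferroniClass.STRONG
    est.consensus_signal = consensus(est, thresholds)
    return est


SIGNAL_TABLE_COLUMNS = [
    "SOC", "PT", "a", "frequency",
    "ROR", "ROR_L95", "ROR_U95", "P_ROR",
    "PRR", "PRR_L95", "PRR_U95", "P_PRR",
    "P_BONF_CLASS", "CHI2", "EBGM", "EBGM05", "IC", "IC025", "CONSENSUS",
]


def signal_table(
    tables: Mapping[str, ContingencyTable],
    level: str = "PT",
    priors: BcpnnPriors = BcpnnPriors(),
    thresholds: Thresholds = Thresholds(),
    m: int = 1,
    soc_of: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Evaluate every table and return the report-shaped frame.

    Sorted by EBGM descending, ties by a descending, then term; point
    estimates are carried at full precision (round only at export).
    """
    rows = []
    for term, t in tables.items():
        soc = (soc_of or {}).get(term)
        e = evaluate(t, term=term, level=level, priors=priors,
                     thresholds=thresholds, m=m, soc=soc)
        rows.append({
            "SOC": e.soc if e.soc is not None else (term if level == "SOC" else "UNMAPPED"),
            "PT": e.term,
            "a": e.a,
            "frequency": e.frequency,
            "ROR": e.ror, "ROR_L95": e.ror_ci95[0], "ROR_U95": e.ror_ci95[1],
            "P_ROR": e.p_ror,
            "PRR": e.prr, "PRR_L95": e.prr_ci95[0], "PRR_U95": e.prr_ci95[1],
            "P_PRR": e.p_prr,
            "P_BONF_CLASS": e.bonferroni_class.value,
            "CHI2": e.chi2,
            "EBGM": e.ebgm, "EBGM05": e.ebgm05,
            "IC": e.ic, "IC025": e.ic025,
            "CONSENSUS": e.consensus_signal,
        })
    df = pd.DataFrame(rows, columns=SIGNAL_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["EBGM", "a", "PT"], ascending=[False, False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df
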