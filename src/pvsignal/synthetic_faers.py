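"""Synthetic FAERS-dialect data with known ground truth.

The generator emulates the structure of a spontaneous-report database —
one primary-suspect drug per report, a handful of distinct MedDRA-style
event terms, demographics with realistic missingness, therapy-start /
event / receipt dates, case duplication across report versions — while
keeping every signal parameter explicit:

*   a *planted association* (drug, PT, rate ratio) multiplies that PT's
    inclusion odds on that drug's reports, so the drug over-reports the
    term by a known factor;
*   a *covariate effect* (PT, covariate, odds ratio) multiplies the PT's
    inclusion odds on reports where the covariate holds, giving the
    logistic sensitivity analysis a known target;
*   a configured fraction of cases is re-emitted as a follow-up version
    (later FDA receipt date, higher primaryid) to exercise deduplication.

Each PT enters a report by an independent Bernoulli draw with probability
λ·w_j (odds-multiplied where planted), conditioned on at least one PT per
report; the per-report distinct-PT count is then approximately Poisson
with mean λ, and every planted pair has the exact closed-form expectation
E[a] = n·P(drug)·p′_j / (1 − Π_i(1 − p′_i)) that ``truth_table`` reports.

Defaults mirror the reporting profile of an ultrasound contrast agent's
FAERS corpus: ≈2.75 distinct PTs per report, onset heavily concentrated
in the first month, weight missing for almost half the reports.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .faers_ingest import QuarterlyFileSet

__all__ = ["SyntheticConfig", "PlantedAssociation", "CovariateEffect",
           "SimulatedReports", "simulate", "generate", "truth_table"]

COVARIATES = ("male", "weight_ge50", "age_ge65")


@dataclass(frozen=True)
class PlantedAssociation:
    drug: str
    pt: str
    rate_ratio: float
    covariate: Optional[str] = None  # restrict the multiplier to a stratum

    def __post_init__(self):
        if self.rate_ratio <= 0:
            raise ValueError("rate_ratio must be positive")
        if self.covariate is not None and self.covariate not in COVARIATES:
            raise ValueError(f"unknown covariate {self.covariate!r}")


@dataclass(frozen=True)
class CovariateEffect:
    pt: str
    covariate: str
    odds_ratio: float

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if self.covariate not in COVARIATES:
            raise ValueError(f"unknown covariate {self.covariate!r}")


def _zipf(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


@dataclass
class SyntheticConfig:
    """Generator parameters; the same seed yields byte-identical files."""

    n_reports: int = 20_000
    n_drugs: int = 20
    n_pts: int = 150
    pts_per_report_mean: float = 2.75  # mean distinct PTs per report
    drug_weights: Optional[Sequence[float]] = None  # default: Zipf over drugs
    pt_weights: Optional[Sequence[float]] = None  # default: Zipf over PTs
    planted_associations: List[PlantedAssociation] = field(default_factory=list)
    covariate_effects: List[CovariateEffect] = field(default_factory=list)
    duplicate_fraction: float = 0.10
    # missingness, onset and demographics mirror the target corpus profile
    missing_sex: float = 0.059
    missing_age: float = 0.206
    missing_weight: float = 0.459
    missing_therapy_start: float = 0.297
    p_male: float = 0.486  # among reports with known sex
    age_mean: float = 60.0
    age_sd: float = 13.0
    weight_mean: float = 95.0
    weight_sd: float = 22.0
    onset_mean_days: float = 25.0  # exponential mean; ~70% of onsets <= 30 d
    outcome_probs: Dict[str, float] = field(default_factory=lambda: {
        "HO": 0.048, "LT": 0.034, "DE": 0.017, "DS": 0.002, "RI": 0.002, "OT": 0.18,
    })
    reporter_probs: Dict[str, float] = field(default_factory=lambda: {
        "CN": 0.678, "OT": 0.150, "HP": 0.102, "PH": 0.029, "MD": 0.026,
        "RN": 0.001, "": 0.014,
    })
    country_probs: Dict[str, float] = field(default_factory=lambda: {
        "US": 0.962, "": 0.032, "CA": 0.002, "FR": 0.002, "AU": 0.002,
    })
    date_start: _dt.date = _dt.date(2004, 1, 1)
    date_end: _dt.date = _dt.date(2024, 3, 31)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.duplicate_fraction < 1):
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        if self.pts_per_report_mean < 1:
            raise ValueError("pts_per_report_mean must be >= 1")
        if self.pts_per_report_mean > self.n_pts:
            raise ValueError("mean PTs per report exceeds the PT vocabulary")
        for rate in (self.missing_sex, self.missing_age, self.missing_weight,
                     self.missing_therapy_start, self.p_male):
            if not (0 <= rate <= 1):
                raise ValueError("probabilities must lie in [0, 1]")

    # -- vocabulary -------------------------------------------------------
    def drug_names(self) -> List[str]:
        return [f"DRUG_{i:03d}" for i in range(self.n_drugs)]

    def pt_names(self) -> List[str]:
        return [f"PT_{i:03d}" for i in range(self.n_pts)]

    def drug_w(self) -> np.ndarray:
        if self.drug_weights is not None:
            w = np.asarray(self.drug_weights, dtype=float)
            return w / w.sum()
        return _zipf(self.n_drugs)

    def pt_w(self) -> np.ndarray:
        if self.pt_weights is not None:
            w = np.asarray(self.pt_weights, dtype=float)
            return w / w.sum()
        return _zipf(self.n_pts)


def _streams(seed: int) -> Dict[str, np.random.Generator]:
    """Named, independent RNG streams: extending one table's generation
    never perturbs another's draws."""
    names = ["drugs", "pts", "demo", "dates", "outcomes", "duplicates"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _odds_multiply(p: np.ndarray, factor: float) -> np.ndarray:
    return factor * p / (1.0 - p + factor * p)


@dataclass
class SimulatedReports:
    """In-memory realisation: core report table plus FAERS-shaped frames."""

    config: SyntheticConfig
    core: pd.DataFrame  # caseid, drug, sex, age, weight, covariate flags, dates
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    rpsr: pd.DataFrame
    truth: List[dict]

    def event_frame(self) -> pd.DataFrame:
        """Deduplicated event records (caseid, drug, pt): the version-1 REAC
        rows joined to the core report table.  Duplicate case versions carry
        identical events, so this equals the post-dedup event-record set."""
        base = self.reac[self.reac["primaryid"].isin(self.core["primaryid"])]
        return base.merge(
            self.core[["primaryid", "caseid", "drug"]], on="primaryid"
        )[["caseid", "drug", "pt"]]

    def write(self, outdir) -> QuarterlyFileSet:
        if self.demo.empty:
            raise ValueError("events-only simulation carries no FAERS tables to write")
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("demo", "drug", "reac", "ther", "outc", "indi", "rpsr"):
            path = outdir / f"{name.upper()}.txt"
            getattr(self, name).to_csv(path, sep="$", index=False)
            paths[name] = path
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))
        return QuarterlyFileSet(layout_version="modern", **paths)


def _covariate_flags(core: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Boolean covariate indicators; a missing covariate counts as False."""
    return {
        "male": (core["sex"] == "M").to_numpy(),
        "weight_ge50": (core["weight"].fillna(-1) >= 50).to_numpy(),
        "age_ge65": (core["age"].fillna(-1) >= 65).to_numpy(),
    }


def simulate(config: SyntheticConfig, events_only: bool = False) -> SimulatedReports:
    """Draw one synthetic corpus (in memory; ``generate`` also writes it).

    With ``events_only`` the FAERS table serialisation (and duplicate
    re-emission) is skipped: only the core report table and the event
    records are materialised.  That is the full statistical content, and it
    is what simulation studies over many replicates need.
    """
    rng = _streams(config.seed)
    n = config.n_reports
    drugs = config.drug_names()
    pts = config.pt_names()
    drug_w, pt_w = config.drug_w(), config.pt_w()

    drug_idx = rng["drugs"].choice(config.n_drugs, size=n, p=drug_w)

    # demographics -------------------------------------------------------
    g = rng["demo"]
    sex = np.where(g.random(n) < config.p_male, "M", "F")
    sex = np.where(g.random(n) < config.missing_sex, "", sex)
    age = np.clip(g.normal(config.age_mean, config.age_sd, n), 1.0, 120.0).round(0)
    age = np.where(g.random(n) < config.missing_age, np.nan, age)
    weight = np.clip(g.normal(config.weight_mean, config.weight_sd, n), 30.0, 400.0).round(0)
    weight = np.where(g.random(n) < config.missing_weight, np.nan, weight)
    reporter = g.choice(list(config.reporter_probs), size=n,
                        p=np.array(list(config.reporter_probs.values()))
                        / sum(config.reporter_probs.values()))
    country = g.choice(list(config.country_probs), size=n,
                       p=np.array(list(config.country_probs.values()))
                       / sum(config.country_probs.values()))

    # dates --------------------------------------------------------------
    gd = rng["dates"]
    span = (config.date_end - config.date_start).days
    start_offsets = gd.integers(0, max(span, 1), size=n)
    onset = np.floor(gd.exponential(config.onset_mean_days, size=n)).astype(int)
    lag = gd.integers(0, 90, size=n)
    start_missing = gd.random(n) < config.missing_therapy_start

    base = np.datetime64(config.date_start)
    start_dt = base + start_offsets.astype("timedelta64[D]")
    event_dt = start_dt + onset.astype("timedelta64[D]")
    fda_dt = event_dt + lag.astype("timedelta64[D]")

    core = pd.DataFrame({
        "caseid": np.arange(10_000_001, 10_000_001 + n).astype(str),
        "drug": np.asarray(drugs)[drug_idx],
        "drug_idx": drug_idx,
        "sex": sex,
        "age": age,
        "weight": weight,
        "reporter": reporter,
        "country": country,
        "start_dt": start_dt,
        "event_dt": event_dt,
        "fda_dt": fda_dt,
        "start_missing": start_missing,
    })
    core["primaryid"] = core["caseid"] + "1"  # FAERS style: caseid + version

    # PT inclusion -------------------------------------------------------
    flags = _covariate_flags(core)
    base_p = np.minimum(config.pts_per_report_mean * pt_w, 0.95)
    p = np.tile(base_p, (n, 1))
    pt_index = {name: j for j, name in enumerate(pts)}
    drug_index = {name: i for i, name in enumerate(drugs)}
    for eff in config.covariate_effects:
        rows = flags[eff.covariate]
        j = pt_index[eff.pt]
        p[rows, j] = _odds_multiply(p[rows, j], eff.odds_ratio)
    for assoc in config.planted_associations:
        rows = drug_idx == drug_index[assoc.drug]
        if assoc.covariate is not None:
            rows = rows & flags[assoc.covariate]
        j = pt_index[assoc.pt]
        p[rows, j] = _odds_multiply(p[rows, j], assoc.rate_ratio)

    gp = rng["pts"]
    inc = gp.random((n, config.n_pts)) < p
    empty = np.flatnonzero(~inc.any(axis=1))
    while empty.size:  # condition on >= 1 PT per report
        redraw = gp.random((empty.size, config.n_pts)) < p[empty]
        inc[empty] = redraw
        empty = empty[~redraw.any(axis=1)]

    rep_idx, pt_idx = np.nonzero(inc)
    reac_core = pd.DataFrame({
        "primaryid": core["primaryid"].to_numpy()[rep_idx],
        "pt": np.asarray(pts)[pt_idx],
    })

    if events_only:
        empty_tbl = pd.DataFrame()
        return SimulatedReports(
            config=config, core=core.assign(**{k: v for k, v in flags.items()}),
            demo=empty_tbl, drug=empty_tbl, reac=reac_core, ther=empty_tbl,
            outc=empty_tbl, indi=empty_tbl, rpsr=empty_tbl,
            truth=truth_table(config),
        )

    # outcomes -----------------------------------------------------------
    go = rng["outcomes"]
    outc_rows = []
    for code, prob in config.outcome_probs.items():
        hit = np.flatnonzero(go.random(n) < prob)
        outc_rows.append(pd.DataFrame({
            "primaryid": core["primaryid"].to_numpy()[hit], "outc_cod": code,
        }))
    outc_core = pd.concat(outc_rows, ignore_index=True) if outc_rows else \
        pd.DataFrame(columns=["primaryid", "outc_cod"])

    # FAERS-shaped frames -------------------------------------------------
    def _datestr(col) -> np.ndarray:
        iso = np.datetime_as_string(
            pd.Series(col).to_numpy().astype("datetime64[D]"), unit="D"
        )
        return np.char.replace(iso, "-", "")

    demo = pd.DataFrame({
        "primaryid": core["primaryid"],
        "caseid": core["caseid"],
        "fda_dt": _datestr(core["fda_dt"]),
        "event_dt": _datestr(core["event_dt"]),
        "sex": core["sex"],
        "age": core["age"].map(lambda v: "" if pd.isna(v) else f"{v:.0f}"),
        "age_cod": np.where(core["age"].isna(), "", "YR"),
        "wt": core["weight"].map(lambda v: "" if pd.isna(v) else f"{v:.0f}"),
        "wt_cod": np.where(core["weight"].isna(), "", "KG"),
        "occp_cod": core["reporter"],
        "reporter_country": core["country"],
        "occr_country": core["country"],
    })
    drug_tbl = pd.DataFrame({
        "primaryid": core["primaryid"],
        "drug_seq": 1,
        "role_cod": "PS",
        "drugname": core["drug"],
        "prod_ai": core["drug"],
    })
    ther = pd.DataFrame({
        "primaryid": core.loc[~core["start_missing"], "primaryid"],
        "dsg_drug_seq": 1,
        "start_dt": _datestr(core.loc[~core["start_missing"], "start_dt"]),
    }).reset_index(drop=True)
    indi = pd.DataFrame({
        "primaryid": core["primaryid"],
        "indi_drug_seq": 1,
        "indi_pt": "Product used for unknown indication",
    })
    rpsr = pd.DataFrame({"primaryid": core["primaryid"], "rpsr_cod": "FGN"})

    # duplicate case versions --------------------------------------------
    n_dup = int(math.floor(config.duplicate_fraction * n))
    dup_sel = np.sort(rng["duplicates"].choice(n, size=n_dup, replace=False))
    if n_dup:
        dup_ids = core["caseid"].to_numpy()[dup_sel]
        dup_pid = pd.Series(dup_ids) + "2"  # version 2: higher primaryid
        remap = dict(zip(core["primaryid"].to_numpy()[dup_sel], dup_pid))

        ddemo = demo.iloc[dup_sel].copy()
        ddemo["primaryid"] = dup_pid.to_numpy()
        ddemo["fda_dt"] = _datestr(core["fda_dt"].iloc[dup_sel] + np.timedelta64(30, "D"))

        def _dup_child(df: pd.DataFrame) -> pd.DataFrame:
            sub = df[df["primaryid"].isin(remap)].copy()
            sub["primaryid"] = sub["primaryid"].map(remap)
            return sub

        demo = pd.concat([demo, ddemo], ignore_index=True)
        drug_tbl = pd.concat([drug_tbl, _dup_child(drug_tbl)], ignore_index=True)
        reac_out = pd.concat([reac_core, _dup_child(reac_core)], ignore_index=True)
        ther = pd.concat([ther, _dup_child(ther)], ignore_index=True)
        outc_core = pd.concat([outc_core, _dup_child(outc_core)], ignore_index=True)
        indi = pd.concat([indi, _dup_child(indi)], ignore_index=True)
        rpsr = pd.concat([rpsr, _dup_child(rpsr)], ignore_index=True)
    else:
        reac_out = reac_core

    return SimulatedReports(
        config=config,
        core=core.assign(**{k: v for k, v in flags.items()}),
        demo=demo,
        drug=drug_tbl,
        reac=reac_out,
        ther=ther,
        outc=outc_core,
        indi=indi,
        rpsr=rpsr,
        truth=truth_table(config),
    )


def generate(config: SyntheticConfig, outdir) -> QuarterlyFileSet:
    """Simulate and write the seven FAERS-dialect files plus truth.json."""
    return simulate(config).write(outdir)


# ---------------------------------------------------------------------------
# ground truth


def _stratum_probs(config: SyntheticConfig, covs: Tuple[str, ...]) -> List[Tuple[dict, float]]:
    """Joint prevalence of the referenced covariate indicators (independent
    draws in the generator; a missing value never satisfies an indicator)."""
    marginals = {
        "male": (1 - config.missing_sex) * config.p_male,
        "weight_ge50": (1 - config.missing_weight)
        * float(_sps.norm.sf(50, config.weight_mean, config.weight_sd)),
        "age_ge65": (1 - config.missing_age)
        * float(_sps.norm.sf(65, config.age_mean, config.age_sd)),
    }
    strata: List[Tuple[dict, float]] = [({}, 1.0)]
    for cov in covs:
        m = marginals[cov]
        strata = [
            ({**s, cov: flag}, w * (m if flag else 1 - m))
            for s, w in strata
            for flag in (True, False)
        ]
    return strata


def truth_table(config: SyntheticConfig) -> List[dict]:
    """Closed-form expected 2×2 cells for every planted association.

    For a report of drug g in covariate stratum s the probability that PT
    j appears is p′_j / (1 − Π_i(1 − p′_i)) (Bernoulli inclusion
    conditioned on a non-empty report), and cells follow by mixing over
    strata and drugs.  Expectations refer to the deduplicated corpus.
    """
    n = config.n_reports
    drugs, pts = config.drug_names(), config.pt_names()
    drug_w, pt_w = config.drug_w(), config.pt_w()
    base_p = np.minimum(config.pts_per_report_mean * pt_w, 0.95)
    pt_index = {name: j for j, name in enumerate(pts)}
    covs = tuple(sorted(
        {a.covariate for a in config.planted_associations if a.covariate}
        | {e.covariate for e in config.covariate_effects}
    ))
    strata = _stratum_probs(config, covs)

    def _p_vector(drug: str, stratum: dict) -> np.ndarray:
        p = base_p.copy()
        for eff in config.covariate_effects:
            if stratum.get(eff.covariate, False):
                j = pt_index[eff.pt]
                p[j] = _odds_multiply(np.array(p[j]), eff.odds_ratio)
        for assoc in config.planted_associations:
            if assoc.drug != drug:
                continue
            if assoc.covariate is not None and not stratum.get(assoc.covariate, False):
                continue
            j = pt_index[assoc.pt]
            p[j] = _odds_multiply(np.array(p[j]), assoc.rate_ratio)
        return p

    # per-drug, per-stratum inclusion probabilities and report totals
    per_drug: Dict[str, Tuple[np.ndarray, float]] = {}
    for gi, drug in enumerate(drugs):
        inc = np.zeros(config.n_pts)
        per_report = 0.0
        for stratum, w in strata:
            p = _p_vector(drug, stratum)
            p0 = np.prod(1.0 - p)
            inc += w * p / (1.0 - p0)
            per_report += w * p.sum() / (1.0 - p0)
        per_drug[drug] = (inc, per_report)

    exp_drug_total = {d: n * drug_w[gi] * per_drug[d][1] for gi, d in enumerate(drugs)}
    exp_term_total = np.zeros(config.n_pts)
    for gi, d in enumerate(drugs):
        exp_term_total += n * drug_w[gi] * per_drug[d][0]
    exp_n = float(sum(exp_drug_total.values()))

    rows = []
    for assoc in config.planted_associations:
        gi = drugs.index(assoc.drug)
        j = pt_index[assoc.pt]
        a = float(n * drug_w[gi] * per_drug[assoc.drug][0][j])
        b = float(exp_drug_total[assoc.drug] - a)
        c = float(exp_term_total[j] - a)
        d = float(exp_n - a - b - c)
        rows.append({
            "drug": assoc.drug,
            "pt": assoc.pt,
            "rate_ratio": assoc.rate_ratio,
            "covariate": assoc.covariate,
            "expected_a": a,
            "expected_b": b,
            "expected_c": c,
            "expected_d": d,
            "expected_n": exp_n,
        })
    return rows
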