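"""End-to-end orchestration: ingest → select → count → test → describe → regress.

``run`` executes the whole analysis for one target drug over a directory
of quarterly extracts and writes the report bundle:

    signal_table_pt.csv / signal_table_soc.csv  — disproportionality tables
    demographics.tsv                            — descriptive sections
    annual_counts.tsv                           — reports per receipt year
    regression.tsv                              — logistic sensitivity fits
    run_summary.json                            — counts at every filter stage
    run_config.json                             — the configuration as run
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import contingency, covariate_regression, disproportionality, faers_ingest
from . import onset_descriptives, target_selection

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run", "discover_quarters", "stats_for_cells"]

_TABLE_PREFIXES = ("DEMO", "DRUG", "REAC", "THER", "OUTC", "INDI", "RPSR")


class PipelineError(RuntimeError):
    """A stage failed fatally; the message names the stage."""


@dataclass
class RunConfig:
    quarters_dir: Path
    synonyms_path: Path
    out_dir: Path
    ptsoc_path: Optional[Path] = None
    exclusions_path: Optional[Path] = None
    layout_version: str = "modern"
    comparator: str = "ps-only"  # ps-only | all-roles
    bonferroni_m: str = "event-total"  # event-total | n-terms
    thresholds: disproportionality.Thresholds = field(
        default_factory=disproportionality.Thresholds
    )
    priors: disproportionality.BcpnnPriors = field(
        default_factory=disproportionality.BcpnnPriors
    )
    regression_top: int = 3  # regress the top consensus PTs by EBGM
    seed: int = 0

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def discover_quarters(quarters_dir: Path, layout_version: str = "modern") -> List:
    """Group the directory's FAERS files into quarterly file sets.

    Files are matched by table prefix (DEMO*, DRUG*, ...); whatever follows
    the prefix (e.g. 24Q1) labels the quarter and groups the seven tables.
    """
    quarters_dir = Path(quarters_dir)
    by_quarter: Dict[str, Dict[str, Path]] = {}
    for path in sorted(quarters_dir.glob("*.txt")):
        stem = path.stem.upper()
        for prefix in _TABLE_PREFIXES:
            if stem.startswith(prefix):
                by_quarter.setdefault(stem[len(prefix):], {})[prefix.lower()] = path
                break
    filesets = []
    for label in sorted(by_quarter):
        tables = by_quarter[label]
        missing = [t for t in ("demo", "drug", "reac") if t not in tables]
        if missing:
            raise PipelineError(
                f"ingest: quarter {label or '(unlabelled)'} lacks required "
                f"table(s): {', '.join(m.upper() for m in missing)}"
            )
        filesets.append(
            faers_ingest.QuarterlyFileSet(layout_version=layout_version, **tables)
        )
    if not filesets:
        raise PipelineError(f"ingest: no FAERS tables found under {quarters_dir}")
    return filesets


def stats_for_cells(a: float, b: float, c: float, d: float,
                    m: int = 1) -> disproportionality.SignalEstimate:
    """One-shot evaluation of a single 2×2 table (the `stats` subcommand)."""
    t = contingency.ContingencyTable(a, b, c, d)
    return disproportionality.evaluate(t, term="(ad hoc)", m=m)


def _export_signal_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in ("frequency", "ROR", "ROR_L95", "ROR_U95", "PRR", "PRR_L95",
                "PRR_U95", "CHI2", "EBGM", "EBGM05", "IC", "IC025"):
        out[col] = out[col].round(2)
    for col in ("P_ROR", "P_PRR"):
        out[col] = out[col].map(lambda p: "" if pd.isna(p) else f"{p:.2E}")
    out.to_csv(path, index=False)


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the run summary (also written as JSON)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ingest + dedup -----------------------------------------------------
    try:
        filesets = discover_quarters(config.quarters_dir, config.layout_version)
        ingest = faers_ingest.read_quarters(filesets)
    except faers_ingest.IngestError as exc:
        raise PipelineError(f"ingest: {exc}") from exc
    cases = faers_ingest.deduplicate(ingest.records)

    # target selection ---------------------------------------------------
    try:
        synonyms = target_selection.SynonymList.from_file(config.synonyms_path)
    except target_selection.ConfigError as exc:
        raise PipelineError(f"selection: {exc}") from exc
    ptsoc = (target_selection.PtSocMap.from_file(config.ptsoc_path)
             if config.ptsoc_path else None)
    exclusions = (target_selection.ExclusionList.from_file(config.exclusions_path)
                  if config.exclusions_path else target_selection.ExclusionList())
    target_cases = target_selection.select_primary_suspect(cases, synonyms)
    extraction = target_selection.extract_event_records(target_cases, ptsoc, exclusions)
    pre_exclusion_records = extraction.total + extraction.n_excluded

    # contingency + statistics ------------------------------------------
    summary_signals = {}
    signal_frames = {}
    m = None
    for level in ("PT", "SOC"):
        totals = contingency.database_totals(
            cases, level=level, ptsoc=ptsoc, comparator=config.comparator
        )
        try:
            tables = contingency.build_tables(extraction.records, totals, level=level)
        except contingency.IntegrityError as exc:
            raise PipelineError(f"contingency: {exc}") from exc
        if level == "PT":
            m = (extraction.total if config.bonferroni_m == "event-total"
                 else max(len(tables), 1))
        soc_of = (extraction.records.drop_duplicates("pt").set_index("pt")["soc"].to_dict()
                  if level == "PT" else None)
        df = disproportionality.signal_table(
            tables, level=level, priors=config.priors,
            thresholds=config.thresholds, m=m, soc_of=soc_of,
        )
        signal_frames[level] = df
        _export_signal_csv(df, out_dir / f"signal_table_{level.lower()}.csv")
        summary_signals[level] = {
            "terms_observed": int(len(df)),
            "terms_eligible": int((df["a"] >= config.thresholds.a_min).sum()),
            "consensus_signals": int(df["CONSENSUS"].sum()),
            "bonferroni_strong": int((df["P_BONF_CLASS"] == "strong").sum()),
        }

    # descriptives -------------------------------------------------------
    summary = onset_descriptives.summarize(target_cases, synonyms)
    onset_descriptives.summary_frame(summary).to_csv(
        out_dir / "demographics.tsv", sep="\t", index=False
    )
    pd.DataFrame(summary.annual.items(), columns=["year", "reports"]).to_csv(
        out_dir / "annual_counts.tsv", sep="\t", index=False
    )

    # regression sensitivity --------------------------------------------
    pt_df = signal_frames["PT"]
    top_pts = pt_df.loc[pt_df["CONSENSUS"], "PT"].head(config.regression_top)
    reg_frames = []
    for pt in top_pts:
        rows = covariate_regression.build_design(target_cases, pt)
        try:
            results = covariate_regression.fit_logistic(rows)
        except covariate_regression.DesignError as exc:
            logger.warning("regression for %s refused: %s", pt, exc)
            continue
        reg_frames.append(covariate_regression.regression_frame(results, pt))
    reg_df = (pd.concat(reg_frames, ignore_index=True) if reg_frames
              else pd.DataFrame(columns=["PT", "model", "term", "OR", "CI_low",
                                         "CI_high", "P", "N", "status"]))
    reg_df.to_csv(out_dir / "regression.tsv", sep="\t", index=False)

    # summary ------------------------------------------------------------
    run_summary = {
        "raw_reports": len(ingest.records),
        "malformed_lines": {k: len(v) for k, v in ingest.malformed.items()},
        "orphan_rows": dict(ingest.orphans),
        "keyless_dropped": ingest.keyless_dropped,
        "deduplicated_cases": len(cases),
        "target_cases": len(target_cases),
        "event_records_pre_exclusion": int(pre_exclusion_records),
        "event_records": int(extraction.total),
        "excluded_event_records": int(extraction.n_excluded),
        "unmapped_pts": len(extraction.unmapped_pts),
        "bonferroni_m": int(m),
        "signals": summary_signals,
        "regressed_pts": list(top_pts),
    }
    (out_dir / "run_summary.json").write_text(json.dumps(run_summary, indent=2))
    (out_dir / "run_config.json").write_text(json.dumps(config.to_json(), indent=2))
    return run_summary
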