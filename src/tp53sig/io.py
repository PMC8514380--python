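"""Table parsing, validation, report writing and end-to-end pipeline wiring.

Canonical on-disk dialect is TSV (CSV is accepted; the delimiter is sniffed;
decimal points only).  The expression table has samples in rows, a
``sample_id`` first column and one column per gene.  The clinical table
carries the covariate and endpoint columns documented in
``CLINICAL_COLUMNS``; ``NA`` (or an empty cell) marks a missing grade or
Ki-67 value.  Endpoint column pairs (``rfs_time``/``rfs_event``, ...) may be
absent; absent endpoints are skipped by the pipeline with a notice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import LabeledScore, agreement_rate, roc_auc, select_cutoff
from .cohort import ENDPOINTS, CohortRecord
from .errors import (
    AlignmentError,
    InvalidInputError,
    MissingGeneError,
    ParseError,
    VocabularyError,
)
from .panel import GenePanel, default_panel, load_panel
from .scoring import PAPER_CUTOFF, ExpressionProfile, SignatureCall, score_cohort
from .survival import (
    characteristics_table,
    kaplan_meier,
    log_rank,
    run_table3,
    subgroup_rfs,
)

log = logging.getLogger(__name__)

#: Clinical-table column dictionary: name -> (dtype description, allowed values).
CLINICAL_COLUMNS = {
    "sample_id": ("text", None),
    "age": ("years", None),
    "p_stage": ("category", ("I", "IIA", "IIB")),
    "p_ln": ("category", ("positive", "negative")),
    "tumor_size_cm": ("cm", None),
    "grade": ("category or NA", ("1", "2", "3", "NA")),
    "er": ("category", ("positive", "negative")),
    "pgr": ("category", ("positive", "negative")),
    "her2": ("category", ("positive", "negative")),
    "ki67_pct": ("percent or NA", None),
    "adj_chemo": ("category", ("yes", "no")),
    "adj_endocrine": ("category", ("yes", "no")),
    "tp53_status": ("category", ("mutant", "wild")),
}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise ParseError(f"{path}: empty input file")
    sep = "\t" if "\t" in header else ","
    cols = header.split(sep)
    dup = sorted({c for c in cols if cols.count(c) > 1})
    if dup:
        raise ParseError(f"{path}: duplicate column(s): {dup}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty input file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def read_expression_table(path: str | Path,
                          input_scale: str = "linear") -> list[ExpressionProfile]:
    """Parse a samples-by-genes expression table into validated profiles.

    ``input_scale="log2"`` exponentiates values (2**x) before scoring, for
    tables stored on the log scale; the default assumes linear units.
    """
    if input_scale not in ("linear", "log2"):
        raise InvalidInputError(f"input_scale must be linear or log2, got {input_scale!r}")
    df = _read_table(path)
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    genes = list(df.columns[1:])
    dup = [g for g in set(genes) if genes.count(g) > 1]
    if dup:
        raise ParseError(f"{path}: duplicate gene column(s): {sorted(dup)}")
    if not genes:
        raise ParseError(f"{path}: no gene columns")

    profiles = []
    for i, row in df.iterrows():
        values = {}
        for g in genes:
            cell = row[g]
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: row {i + 2}, column {g!r}: non-numeric cell {cell!r}") from None
            if input_scale == "log2":
                v = float(2.0 ** v)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(
                    f"{path}: row {i + 2}, column {g!r}: invalid expression value {cell!r}")
            values[g] = v
        profiles.append(ExpressionProfile(str(row["sample_id"]), values))
    return profiles


def _parse_optional(cell: str, caster, path, rownum, col):
    if cell in ("NA", "", "nan", "NaN"):
        return None
    try:
        return caster(cell)
    except ValueError:
        raise ParseError(f"{path}: row {rownum}, column {col!r}: bad value {cell!r}") from None


def read_clinical_table(path: str | Path) -> tuple[list[CohortRecord], list[str]]:
    """Parse and validate a clinical table.

    Returns the records plus the list of endpoints whose time/event column
    pairs were present.  Absent endpoints are backfilled with zero-length
    censored follow-up so the record stays well-formed, and are excluded
    from analysis by the pipeline.
    """
    df = _read_table(path)
    required = [c for c in CLINICAL_COLUMNS if c != "tp53_status"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing clinical column(s): {missing_cols}")

    available = [ep for ep in ENDPOINTS
                 if f"{ep}_time" in df.columns and f"{ep}_event" in df.columns]
    if not available:
        raise ParseError(f"{path}: no endpoint column pair present "
                         f"(need <endpoint>_time and <endpoint>_event)")

    records = []
    for i, row in df.iterrows():
        rownum = i + 2
        def cellf(col, caster=float):
            try:
                return caster(row[col])
            except ValueError:
                raise ParseError(
                    f"{path}: row {rownum}, column {col!r}: bad value {row[col]!r}") from None

        ep_vals = {}
        for ep in ENDPOINTS:
            if ep in available:
                ep_vals[f"{ep}_time"] = cellf(f"{ep}_time")
                ev = cellf(f"{ep}_event", int)
                if ev not in (0, 1):
                    raise InvalidInputError(
                        f"{path}: row {rownum}: {ep}_event must be 0 or 1, got {ev}")
                ep_vals[f"{ep}_event"] = ev
        # backfill absent endpoints so invariants (rfs <= os, bcss => os) hold
        if "rfs" not in available:
            ep_vals["rfs_time"], ep_vals["rfs_event"] = 0.0, 0
        if "os" not in available:
            ep_vals["os_time"] = max(ep_vals["rfs_time"],
                                     ep_vals.get("bcss_time", 0.0))
            ep_vals["os_event"] = 0
        if "bcss" not in available:
            ep_vals["bcss_time"], ep_vals["bcss_event"] = ep_vals["os_time"], 0

        grade = _parse_optional(row["grade"], lambda s: int(float(s)), path, rownum, "grade")
        ki67 = _parse_optional(row["ki67_pct"], float, path, rownum, "ki67_pct")
        try:
            rec = CohortRecord(
                sample_id=str(row["sample_id"]),
                age=cellf("age"),
                p_stage=row["p_stage"], p_ln=row["p_ln"],
                tumor_size_cm=cellf("tumor_size_cm"),
                grade=grade, er=row["er"], pgr=row["pgr"], her2=row["her2"],
                ki67_pct=ki67, adj_chemo=row["adj_chemo"],
                adj_endocrine=row["adj_endocrine"],
                tp53_status=row.get("tp53_status", "wild"),
                **ep_vals)
        except VocabularyError as exc:
            raise VocabularyError(f"{path}: row {rownum}: {exc}") from None
        records.append(rec)
    return records, available


def write_scores(calls: list[SignatureCall], cutoff: float,
                 path: str | Path) -> None:
    """Write the score/status report TSV."""
    df = pd.DataFrame({
        "sample_id": [c.sample_id for c in calls],
        "tp53_signature_score": [f"{c.score:.6g}" for c in calls],
        "tp53_status": [c.status for c in calls],
        "cutoff_used": [f"{cutoff:g}"] * len(calls),
    })
    df.to_csv(path, sep="\t", index=False)


def write_expression_table(profiles: list[ExpressionProfile],
                           path: str | Path) -> None:
    genes = list(profiles[0].values)
    df = pd.DataFrame([{"sample_id": p.sample_id, **{g: repr(p.values[g]) for g in genes}}
                       for p in profiles])
    df.to_csv(path, sep="\t", index=False)


def write_clinical_table(records: list[CohortRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["grade"] = "NA" if r.grade is None else str(r.grade)
        d["ki67_pct"] = "NA" if r.ki67_pct is None else repr(r.ki67_pct)
        for c in ("age", "tumor_size_cm", "rfs_time", "os_time", "bcss_time"):
            d[c] = repr(float(d[c]))
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level pipeline settings (published constants as defaults)."""

    panel_path: str | None = None
    cutoff: float = PAPER_CUTOFF
    input_scale: str = "linear"
    multivariate_entry_p: float = 0.05
    endpoints: tuple[str, ...] = ENDPOINTS
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.cutoff <= 0:
            raise InvalidInputError("cutoff must be > 0")
        if not (0 < self.multivariate_entry_p <= 1):
            raise InvalidInputError("multivariate_entry_p must be in (0, 1]")

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return {str(i): _jsonify(row.to_dict()) for i, row in obj.iterrows()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else repr(f)
    return obj


def analyze_cohort(profiles: list[ExpressionProfile],
                   records: list[CohortRecord],
                   panel: GenePanel,
                   config: PipelineConfig,
                   available_endpoints: list[str] | None = None) -> dict:
    """Score, classify and run the full prognostic analysis in memory."""
    available = list(available_endpoints if available_endpoints is not None else ENDPOINTS)
    prof_ids = {p.sample_id for p in profiles}
    rec_ids = {r.sample_id for r in records}
    if prof_ids != rec_ids:
        raise AlignmentError(prof_ids ^ rec_ids,
                             "expression/clinical sample_id mismatch")

    calls = score_cohort(profiles, panel, config.cutoff)
    call_by_id = {c.sample_id: c for c in calls}
    records = [dataclasses.replace(r, tp53_status=call_by_id[r.sample_id].status)
               for r in records]
    n_mut = sum(c.status == "mutant" for c in calls)
    log.info("scored %d samples at cutoff %g: %d mutant, %d wild",
             len(calls), config.cutoff, n_mut, len(calls) - n_mut)

    endpoints = [ep for ep in config.endpoints if ep in available]
    for ep in config.endpoints:
        if ep not in available:
            log.info("endpoint %s skipped: columns absent from clinical table", ep)

    endpoint_reports = {}
    for ep in endpoints:
        curves = kaplan_meier(records, ep, "tp53_status")
        lr = log_rank(records, ep, "tp53_status")
        endpoint_reports[ep] = {"log_rank": lr, "curves": {
            g: {"n": c.n, "n_events": c.n_events} for g, c in curves.items()}}

    summary = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_samples": len(calls),
        "calls": {"mutant": n_mut, "wild": len(calls) - n_mut},
        "characteristics": characteristics_table(records),
        "endpoints": endpoint_reports,
        "cox_table3": run_table3(records, "rfs", config.multivariate_entry_p)
            if "rfs" in endpoints else None,
        "subgroups": subgroup_rfs(records) if "rfs" in endpoints else None,
    }
    summary["_calls"] = calls  # in-memory extra, dropped from JSON
    return summary


def run_pipeline(expression_path: str | Path, clinical_path: str | Path,
                 config: PipelineConfig | None = None) -> dict:
    """File-to-file pipeline: read, validate, score, analyse, write reports.

    Writes (when ``config.output_dir`` is set): ``scores.tsv`` and
    ``summary.json``; the JSON is byte-stable for identical inputs and
    configuration (no timestamps).
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    profiles = read_expression_table(expression_path, config.input_scale)
    records, available = read_clinical_table(clinical_path)
    summary = analyze_cohort(profiles, records, panel, config, available)
    calls = summary.pop("_calls")

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_scores(calls, config.cutoff, out / "scores.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(_jsonify(summary), fh, indent=2, sort_keys=True)
        log.info("wrote %s and %s", out / "scores.tsv", out / "summary.json")
    return summary


def calibrate_from_table(path: str | Path) -> dict:
    """Recalibration report from a TSV of sample_id, score, reference_status."""
    df = _read_table(path)
    need = {"sample_id", "score", "reference_status"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(need)}")
    labeled = [LabeledScore(str(r["sample_id"]), float(r["score"]),
                            r["reference_status"]) for _, r in df.iterrows()]
    roc = select_cutoff(labeled)
    calls = [SignatureCall(l.sample_id, l.score,
                           "mutant" if l.score > PAPER_CUTOFF else "wild")
             for l in labeled]
    rate, table = agreement_rate(calls, labeled)
    best = roc.thresholds.index(roc.selected_cutoff)
    return {
        "auc": roc.auc,
        "selected_cutoff": roc.selected_cutoff,
        "youden_j": roc.youden_j,
        "sensitivity_at_cutoff": roc.sensitivity[best],
        "specificity_at_cutoff": roc.specificity[best],
        "published_cutoff": PAPER_CUTOFF,
        "agreement_at_published_cutoff": rate,
        "concordance_table": table,
    }
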