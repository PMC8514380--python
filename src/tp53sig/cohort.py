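"""Clinical cohort records and the covariate codings used by the Cox models.

A ``CohortRecord`` carries the clinicopathological covariates (pathological
stage, nodal status, tumour size, grade, ER/PgR/HER2, Ki-67, adjuvant
therapies), the TP53 signature status, and three right-censored endpoints:

* RFS  - recurrence-free survival: surgery to tumour recurrence,
* OS   - overall survival: surgery to death from any cause,
* BCSS - breast-cancer-specific survival: surgery to death by breast cancer.

Grade and Ki-67 may be missing ("NA"); every analysis is complete-case per
variable, with NA counts surfaced in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import pandas as pd

from .errors import InvalidInputError, VocabularyError

STAGES = ("I", "IIA", "IIB")
POS_NEG = ("positive", "negative")
YES_NO = ("yes", "no")
STATUSES = ("mutant", "wild")
ENDPOINTS = ("rfs", "os", "bcss")

#: Ki-67 dichotomisation threshold (%); >= 10 is the high stratum.
KI67_HIGH_THRESHOLD = 10.0


@dataclass(frozen=True)
class CohortRecord:
    sample_id: str
    age: float
    p_stage: str                    # I / IIA / IIB
    p_ln: str                       # positive / negative
    tumor_size_cm: float
    grade: Optional[int]            # 1 / 2 / 3, None = NA
    er: str                         # positive / negative
    pgr: str
    her2: str
    ki67_pct: Optional[float]       # None = NA
    adj_chemo: str                  # yes / no
    adj_endocrine: str
    tp53_status: str                # mutant / wild
    rfs_time: float
    rfs_event: int
    os_time: float
    os_event: int
    bcss_time: float
    bcss_event: int

    def __post_init__(self):
        def _check_level(name, value, allowed):
            if value not in allowed:
                raise VocabularyError(
                    f"sample {self.sample_id!r}: {name}={value!r} not in {allowed}")

        _check_level("p_stage", self.p_stage, STAGES)
        _check_level("p_ln", self.p_ln, POS_NEG)
        for name in ("er", "pgr", "her2"):
            _check_level(name, getattr(self, name), POS_NEG)
        for name in ("adj_chemo", "adj_endocrine"):
            _check_level(name, getattr(self, name), YES_NO)
        _check_level("tp53_status", self.tp53_status, STATUSES)
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise VocabularyError(
                f"sample {self.sample_id!r}: grade={self.grade!r} not in (1, 2, 3)")
        if self.ki67_pct is not None and self.ki67_pct < 0:
            raise InvalidInputError(f"sample {self.sample_id!r}: negative Ki-67")
        if self.tumor_size_cm <= 0:
            raise InvalidInputError(f"sample {self.sample_id!r}: tumor size must be > 0")
        for ep in ENDPOINTS:
            t, e = getattr(self, f"{ep}_time"), getattr(self, f"{ep}_event")
            if not (math.isfinite(t) and t >= 0):
                raise InvalidInputError(
                    f"sample {self.sample_id!r}: {ep}_time must be finite and >= 0")
            if e not in (0, 1):
                raise InvalidInputError(
                    f"sample {self.sample_id!r}: {ep}_event must be 0 or 1, got {e!r}")
        if self.rfs_time > self.os_time + 1e-9:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: rfs_time exceeds os_time")
        if self.bcss_event == 1 and self.os_event != 1:
            raise InvalidInputError(
                f"sample {self.sample_id!r}: breast-cancer death implies os_event = 1")

    @property
    def ki67_high(self) -> Optional[bool]:
        if self.ki67_pct is None:
            return None
        return self.ki67_pct >= KI67_HIGH_THRESHOLD

    @property
    def subtype(self) -> Optional[str]:
        """Operational molecular subtype (luminal A/B-like need Ki-67)."""
        if self.er == "negative" and self.pgr == "negative" and self.her2 == "negative":
            return "TNBC"
        if self.er == "positive":
            if self.ki67_high is None:
                return None
            return "LuminalA" if not self.ki67_high else "LuminalB"
        return "ER-negative-other"


@dataclass(frozen=True)
class CoxVariable:
    """Binary (0/1) covariate coding for the proportional-hazards models."""

    name: str
    label: str           # e.g. "pStage (vs. Stage I)"
    reference: str       # reference level printed in reports
    encode: Callable[[CohortRecord], Optional[int]]  # None = missing


def _stage_ii(r: CohortRecord) -> int:
    return int(r.p_stage in ("IIA", "IIB"))


#: Covariate codings of the prognostic-factor analysis, in report order.
#: Each is dichotomous; the reference level carries code 0.
COX_VARIABLES: dict[str, CoxVariable] = {
    v.name: v for v in [
        CoxVariable("p_stage", "pStage (vs. Stage I)", "I", _stage_ii),
        CoxVariable("p_ln", "pLN (vs. negative)", "negative",
                    lambda r: int(r.p_ln == "positive")),
        CoxVariable("tumor_size", "Pathological tumor size (vs. T1)", "T1 (<= 2 cm)",
                    lambda r: int(r.tumor_size_cm > 2.0)),
        CoxVariable("grade", "Grade (vs. 1-2)", "1-2",
                    lambda r: None if r.grade is None else int(r.grade == 3)),
        CoxVariable("er", "ER (vs. positive)", "positive",
                    lambda r: int(r.er == "negative")),
        CoxVariable("pgr", "PgR (vs. positive)", "positive",
                    lambda r: int(r.pgr == "negative")),
        CoxVariable("her2", "HER2 (vs. negative)", "negative",
                    lambda r: int(r.her2 == "positive")),
        CoxVariable("ki67", "Ki-67 (vs. < 10%)", "< 10%",
                    lambda r: None if r.ki67_high is None else int(r.ki67_high)),
        CoxVariable("adj_chemo", "Adjuvant chemotherapy (vs. non-therapy)", "no",
                    lambda r: int(r.adj_chemo == "yes")),
        CoxVariable("adj_endocrine", "Adjuvant endocrine therapy (vs. non-therapy)", "no",
                    lambda r: int(r.adj_endocrine == "yes")),
        CoxVariable("tp53_status", "TP53 status by signature (vs. wild-type)", "wild",
                    lambda r: int(r.tp53_status == "mutant")),
    ]
}


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """Flatten cohort records into a DataFrame (one row per patient)."""
    rows = []
    for r in records:
        d = {f: getattr(r, f) for f in (
            "sample_id", "age", "p_stage", "p_ln", "tumor_size_cm", "grade",
            "er", "pgr", "her2", "ki67_pct", "adj_chemo", "adj_endocrine",
            "tp53_status", "rfs_time", "rfs_event", "os_time", "os_event",
            "bcss_time", "bcss_event")}
        rows.append(d)
    return pd.DataFrame(rows)
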