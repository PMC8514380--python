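"""ROC calibration of the signature score against a reference TP53 status.

The mutant class is the positive class; higher scores are more mutant-like.
AUC is the Mann-Whitney concordance probability (ties get half credit).
``select_cutoff`` is a recalibration tool: it scans midpoint thresholds and
maximises Youden's J.  It never silently replaces the published constant
1.11, which classification uses by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import AlignmentError, DegenerateLabelsError, InvalidInputError
from .scoring import MUTANT, WILD, SignatureCall

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledScore:
    """A signature score paired with the external reference TP53 status.

    ``reference_status`` is the ground truth (microarray-derived in the
    development cohort), never the score-derived call.
    """

    sample_id: str
    score: float
    reference_status: str  # MUTANT or WILD

    def __post_init__(self):
        if not (math.isfinite(self.score) and self.score > 0):
            raise InvalidInputError(
                f"sample {self.sample_id!r}: score must be finite and > 0")
        if self.reference_status not in (MUTANT, WILD):
            raise InvalidInputError(
                f"sample {self.sample_id!r}: reference_status must be "
                f"{MUTANT!r} or {WILD!r}, got {self.reference_status!r}")


@dataclass
class RocResult:
    auc: float
    thresholds: list[float]
    sensitivity: list[float]
    specificity: list[float]
    selected_cutoff: float
    youden_j: float
    warnings: list[str] = field(default_factory=list)


def _split(labeled: list[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    mut = np.array([r.score for r in labeled if r.reference_status == MUTANT])
    wild = np.array([r.score for r in labeled if r.reference_status == WILD])
    if len(mut) == 0 or len(wild) == 0:
        raise DegenerateLabelsError(
            "ROC needs at least one mutant and one wild reference label")
    return mut, wild


def roc_auc(labeled: list[LabeledScore]) -> float:
    """Empirical AUC of score vs reference status (mutant = positive class).

    Equals the Mann-Whitney probability
    (#{(w, m): score_m > score_w} + 0.5 * #ties) / (n_wild * n_mutant).
    """
    _split(labeled)  # degenerate-labels check
    y = [1 if r.reference_status == MUTANT else 0 for r in labeled]
    return float(roc_auc_score(y, [r.score for r in labeled]))


def select_cutoff(labeled: list[LabeledScore], strategy: str = "youden") -> RocResult:
    """Scan candidate thresholds and pick the Youden-optimal cutoff.

    Candidates are midpoints between adjacent distinct sorted scores, plus
    -inf/+inf sentinels.  A sample is called mutant when its score is
    strictly greater than the threshold.  Ties in J break toward the lower
    threshold (higher sensitivity).
    """
    if strategy != "youden":
        raise InvalidInputError(f"unknown cutoff strategy {strategy!r}")
    mut, wild = _split(labeled)
    distinct = np.unique([r.score for r in labeled])
    mids = (distinct[:-1] + distinct[1:]) / 2 if len(distinct) > 1 else np.array([])
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    sens = np.array([(mut > t).mean() for t in thresholds])
    spec = np.array([(wild <= t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax takes the first (lowest) threshold on ties

    warnings: list[str] = []
    if j[best] <= 0:
        warnings.append("no threshold separates the classes (Youden J <= 0)")
        log.warning(warnings[-1])
    return RocResult(
        auc=roc_auc(labeled),
        thresholds=list(thresholds),
        sensitivity=list(sens),
        specificity=list(spec),
        selected_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
        warnings=warnings,
    )


def agreement_rate(calls: list[SignatureCall],
                   reference: list[LabeledScore]) -> tuple[float, dict]:
    """Fraction of samples where the score call matches the reference status.

    Returns the agreement fraction and a 2x2 concordance table
    ``table[call_status][reference_status]``.
    """
    call_by_id = {c.sample_id: c for c in calls}
    ref_by_id = {r.sample_id: r for r in reference}
    if len(call_by_id) != len(calls):
        raise AlignmentError([c.sample_id for c in calls
                              if [x.sample_id for x in calls].count(c.sample_id) > 1],
                             "duplicate sample_id in calls")
    unmatched = set(call_by_id) ^ set(ref_by_id)
    if unmatched:
        raise AlignmentError(unmatched)
    table = {c: {r: 0 for r in (MUTANT, WILD)} for c in (MUTANT, WILD)}
    matches = 0
    for sid, call in call_by_id.items():
        ref = ref_by_id[sid]
        table[call.status][ref.reference_status] += 1
        matches += call.status == ref.reference_status
    return matches / len(call_by_id), table
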