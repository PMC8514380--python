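"""TP53 signature score and binary status call.

The signature score of a sample is the ratio

    score = sum(expression of up-regulated panel genes)
          / sum(expression of down-regulated panel genes)

computed on linear-scale, non-negative expression values.  A sample is called
"mutant signature" when its score strictly exceeds the cutoff; the published
cutoff is 1.11 (``PAPER_CUTOFF``), derived once by ROC analysis against
microarray-determined TP53 status and kept fixed thereafter.

The ratio is invariant to any per-sample rescaling of the profile, so
normalisation to internal controls cancels; the three control genes are used
only as a detection-QC gate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import (
    DegenerateProfileError,
    DuplicateSampleError,
    InvalidInputError,
    MissingGeneError,
)
from .panel import GenePanel

log = logging.getLogger(__name__)

#: Published classification cutoff: score > 1.11 => mutant signature.
PAPER_CUTOFF = 1.11

MUTANT = "mutant"
WILD = "wild"


@dataclass(frozen=True)
class ExpressionProfile:
    """One sample's non-negative expression values over panel genes."""

    sample_id: str
    values: Mapping[str, float]

    def __post_init__(self):
        for gene, v in self.values.items():
            if not math.isfinite(v):
                raise InvalidInputError(
                    f"sample {self.sample_id!r}, gene {gene!r}: non-finite value {v!r}")
            if v < 0:
                raise InvalidInputError(
                    f"sample {self.sample_id!r}, gene {gene!r}: negative value {v}")

    def scaled(self, c: float) -> "ExpressionProfile":
        """Profile with every value multiplied by c > 0 (QC/testing helper)."""
        if c <= 0:
            raise InvalidInputError(f"scale factor must be > 0, got {c}")
        return ExpressionProfile(self.sample_id, {g: v * c for g, v in self.values.items()})


@dataclass(frozen=True)
class SignatureCall:
    """Score plus binary TP53 status for one sample."""

    sample_id: str
    score: float
    status: str  # MUTANT or WILD


def compute_score(profile: ExpressionProfile, panel: GenePanel) -> float:
    """Ratio of summed up-gene expression to summed down-gene expression.

    Raises
    ------
    MissingGeneError
        if any scored (up or down) panel gene is absent from the profile.
    DegenerateProfileError
        if the down-gene sum is zero (the ratio is undefined).
    """
    missing = [g for g in panel.scored_genes if g not in profile.values]
    if missing:
        raise MissingGeneError(missing, sample_id=profile.sample_id)
    up_sum = sum(profile.values[g] for g in panel.up_genes)
    down_sum = sum(profile.values[g] for g in panel.down_genes)
    if down_sum == 0:
        raise DegenerateProfileError(
            f"sample {profile.sample_id!r}: down-regulated gene sum is zero")
    return up_sum / down_sum


def classify(score: float, cutoff: float = PAPER_CUTOFF) -> str:
    """Mutant signature iff score > cutoff (strict); wild otherwise.

    Scores exactly at the cutoff are wild: the published rule is "greater
    than", so the boundary goes to the wild-type class.
    """
    if not (math.isfinite(score) and score > 0):
        raise InvalidInputError(f"score must be finite and > 0, got {score!r}")
    if not (math.isfinite(cutoff) and cutoff > 0):
        raise InvalidInputError(f"cutoff must be finite and > 0, got {cutoff!r}")
    return MUTANT if score > cutoff else WILD


def control_qc(profile: ExpressionProfile, panel: GenePanel,
               detection_floor: float = 0.0) -> list[str]:
    """Internal-control genes of this profile below the detection floor.

    Controls never enter the score; a control below the floor indicates a
    failed assay and is surfaced as a warning, not an error.
    """
    low = [g for g in panel.control_genes
           if g in profile.values and profile.values[g] < detection_floor]
    if low:
        log.warning("sample %s: control gene(s) below detection floor %.3g: %s",
                    profile.sample_id, detection_floor, ", ".join(low))
    return low


def score_cohort(profiles: Iterable[ExpressionProfile], panel: GenePanel,
                 cutoff: float = PAPER_CUTOFF) -> list[SignatureCall]:
    """Score and classify every profile, order-preserving.

    Each call depends only on that sample's own profile, so cohort composition
    never changes a sample's call.
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("empty cohort: no profiles to score")
    seen: dict[str, int] = {}
    for p in profiles:
        seen[p.sample_id] = seen.get(p.sample_id, 0) + 1
    dups = [sid for sid, n in seen.items() if n > 1]
    if dups:
        raise DuplicateSampleError(dups)
    return [
        SignatureCall(p.sample_id, s, classify(s, cutoff))
        for p in profiles
        for s in (compute_score(p, panel),)
    ]
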