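"""Published 34-sample development-cohort fixture.

The development cohort pairs each sample's multiplex RT-PCR signature score
with its microarray-determined TP53 status and the status called from the
score at the published cutoff 1.11.  One sample (BR013, score 1.4350) is
called mutant by score but wild by microarray; the other 33 agree, giving the
published 97.1% agreement rate, and the score separates the microarray
classes with AUC 0.993.
"""

from __future__ import annotations

from .calibration import LabeledScore
from .scoring import SignatureCall

# sample_id, signature score, status by score (cutoff 1.11), status by microarray
_TABLE1 = [
    ("BR047", 0.1707, "wild", "wild"),
    ("BR038", 0.3383, "wild", "wild"),
    ("BR019", 0.4267, "wild", "wild"),
    ("BR044", 0.5178, "wild", "wild"),
    ("BR033", 0.5206, "wild", "wild"),
    ("BR050", 0.5406, "wild", "wild"),
    ("BR034", 0.5696, "wild", "wild"),
    ("BR045", 0.5910, "wild", "wild"),
    ("BR063", 0.6151, "wild", "wild"),
    ("BR016", 0.7157, "wild", "wild"),
    ("BR024", 0.7668, "wild", "wild"),
    ("BR052", 0.7820, "wild", "wild"),
    ("BR036", 0.8019, "wild", "wild"),
    ("BR027", 0.8796, "wild", "wild"),
    ("BR048", 0.9536, "wild", "wild"),
    ("BR043", 1.0681, "wild", "wild"),
    ("BR058", 1.1003, "wild", "wild"),
    ("BR064", 1.2907, "mutant", "mutant"),
    ("BR040", 1.4288, "mutant", "mutant"),
    ("BR013", 1.4350, "mutant", "wild"),
    ("BR020", 1.4504, "mutant", "mutant"),
    ("BR035", 1.4809, "mutant", "mutant"),
    ("BR026", 1.6511, "mutant", "mutant"),
    ("BR046", 1.6968, "mutant", "mutant"),
    ("BR017", 1.7842, "mutant", "mutant"),
    ("BR010", 1.9654, "mutant", "mutant"),
    ("BR001", 2.1603, "mutant", "mutant"),
    ("BR005", 2.1959, "mutant", "mutant"),
    ("BR021", 2.3457, "mutant", "mutant"),
    ("BR022", 2.3744, "mutant", "mutant"),
    ("BR053", 2.4841, "mutant", "mutant"),
    ("BR011", 2.5209, "mutant", "mutant"),
    ("BR041", 3.6260, "mutant", "mutant"),
    ("BR009", 4.0595, "mutant", "mutant"),
]


def table1_fixture() -> tuple[list[LabeledScore], list[SignatureCall]]:
    """The 34 published development-cohort rows.

    Returns
    -------
    labeled : list of LabeledScore
        Score plus microarray reference status per sample (the ROC ground
        truth).
    calls : list of SignatureCall
        The published score-based status calls at cutoff 1.11.
    """
    labeled = [LabeledScore(sid, score, ref) for sid, score, _, ref in _TABLE1]
    calls = [SignatureCall(sid, score, by_score) for sid, score, by_score, _ in _TABLE1]
    return labeled, calls
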