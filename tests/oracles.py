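"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive: all-pairs counting for AUC, an explicit
product over risk sets for Kaplan-Meier, and the per-event-time
hypergeometric observed-minus-expected sum for the two-group log-rank
statistic.  They share no code with the library paths they verify.
"""

from __future__ import annotations

import numpy as np


def auc_pairs(wild_scores, mutant_scores) -> float:
    """All-pairs Mann-Whitney concordance: ties get half credit."""
    num = 0.0
    for w in wild_scores:
        for m in mutant_scores:
            if m > w:
                num += 1.0
            elif m == w:
                num += 0.5
    return num / (len(wild_scores) * len(mutant_scores))


def km_step(times, events):
    """Product-limit estimate computed event time by event time.

    Returns (event_times, survival) where survival[i] = S(event_times[i]).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = np.sort(np.unique(times[events == 1]))
    s = 1.0
    surv = []
    for t in event_times:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return event_times, np.array(surv)


def logrank_two_group(times1, events1, times2, events2) -> float:
    """Two-group unweighted log-rank chi-squared via per-event-time 2x2 tables."""
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    event_times = np.sort(np.unique(all_t[all_e == 1]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        n = n1 + n2
        d = int(((all_t == t) & (all_e == 1)).sum())
        d1 = int(((t1 == t) & (e1 == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e ** 2 / var
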