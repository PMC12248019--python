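"""Best-template identification and era-comparison statistics.

The best template for a target is the candidate structure, released
before the target's prediction deadline, with the highest sequence-
independent structural-alignment score (the TM functional normalized by
the target length).  Improvement records hold, per target, the best
predicted score minus the best template score; two eras (or predictor
classes) are compared with a two-sample t-test on these deltas (Welch by
default, pooled variance optionally).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import tm_align
from .structures import Structure

__all__ = [
    "TemplateHit",
    "ImprovementRecord",
    "best_template",
    "improvement_stats",
    "welch_from_summary",
]


@dataclass
class TemplateHit:
    candidate_id: str
    release_date: dt.date
    tm_align_score: float


@dataclass
class ImprovementRecord:
    target_id: str
    best_predicted_tm_align: float
    best_template_tm_align: float
    era: str = "current"  # pre | current
    predictor_class: str = "all"  # all | server
    included: bool = True

    @property
    def delta(self) -> float:
        return self.best_predicted_tm_align - self.best_template_tm_align


def best_template(target: Structure,
                  pool: list[tuple[Structure, dt.date]],
                  deadline: dt.date) -> TemplateHit | None:
    """Highest-scoring candidate released strictly before the deadline.

    Returns None when no candidate predates the deadline.  Ties break
    towards the lexicographically smallest candidate id.
    """
    eligible = [(s, d) for s, d in pool if d < deadline]
    if not eligible:
        return None
    hits = []
    for cand, date in eligible:
        _, score = tm_align(cand, target)
        hits.append(TemplateHit(cand.id, date, score))
    hits.sort(key=lambda h: (-h.tm_align_score, h.candidate_id))
    return hits[0]


def _side(records: list[ImprovementRecord], era: str | None,
          predictor_class: str | None) -> np.ndarray:
    vals = [r.delta for r in records
            if r.included
            and (era is None or r.era == era)
            and (predictor_class is None or r.predictor_class == predictor_class)]
    return np.asarray(vals, dtype=float)


def improvement_stats(records: list[ImprovementRecord],
                      group_a: dict | None = None,
                      group_b: dict | None = None,
                      welch: bool = True) -> dict[str, float]:
    """Means, standard errors, and t-test p-value of delta between two sides.

    ``group_a``/``group_b`` select records by ``era`` and/or
    ``predictor_class`` (e.g. ``{"era": "pre"}`` vs ``{"era": "current"}``).
    """
    group_a = group_a or {"era": "pre"}
    group_b = group_b or {"era": "current"}
    a = _side(records, group_a.get("era"), group_a.get("predictor_class"))
    b = _side(records, group_b.get("era"), group_b.get("predictor_class"))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each side needs at least 2 records")
    sem_a = float(a.std(ddof=1) / np.sqrt(len(a)))
    sem_b = float(b.std(ddof=1) / np.sqrt(len(b)))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: zero variance on both sides
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        t = 0.0 if p == 1.0 else np.inf
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "mean_a": float(a.mean()), "sem_a": sem_a, "n_a": len(a),
        "mean_b": float(b.mean()), "sem_b": sem_b, "n_b": len(b),
        "t": float(t), "p": float(p),
    }


def welch_from_summary(mean1: float, sem1: float, n1: int,
                       mean2: float, sem2: float, n2: int) -> dict[str, float]:
    """Welch t-test reconstructed from printed means and standard errors."""
    sd1 = sem1 * np.sqrt(n1)
    sd2 = sem2 * np.sqrt(n2)
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=False)
    return {"t": float(t), "p": float(p)}
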