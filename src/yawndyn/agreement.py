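"""Agreement and diagnostic-accuracy statistics.

Covers the three reliability/validity computations used when comparing a
candidate classification (timing rule or SVM) or a second human coder
against the reference behavioural coding:

* 2×2 contingency analysis with sensitivity, specificity, percent
  agreement and Cohen's kappa (yawn is the positive class);
* tolerance-window event matching between two coders' annotation sets
  (an event pair matches when both onset and offset agree within the
  tolerance; matching is greedy nearest-onset, one-to-one);
* phase-duration agreement: the percentage of paired duration codings
  within a tolerance, plus the median absolute difference.

Event streams have no natural true-negative count, so event-level
agreement is reported as percent matched; an optional frame-binned kappa
(one bin per video frame, a bin is positive when it falls inside an
event) is provided for comparability with kappa-based reporting
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import NON_YAWN, YAWN, AnnotationSet


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts; reference labels in columns, predictions in rows."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise AgreementError(f"negative count {name}")
        if self.n < 1:
            raise AgreementError("contingency table must contain at least one item")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementStats:
    sensitivity: float  # NaN when no reference positives
    specificity: float  # NaN when no reference negatives
    percent_agreement: float  # 0..100
    kappa: float  # NaN when chance agreement is 1 (degenerate margins)


def contingency(pred: Sequence[str], ref: Sequence[str]) -> ContingencyTable:
    """Tally a 2×2 table from aligned label sequences (yawn = positive)."""
    if len(pred) != len(ref):
        raise AgreementError(
            f"length mismatch: {len(pred)} predictions vs {len(ref)} references"
        )
    tp = fp = fn = tn = 0
    for p, r in zip(pred, ref):
        if p == YAWN and r == YAWN:
            tp += 1
        elif p == YAWN and r == NON_YAWN:
            fp += 1
        elif p == NON_YAWN and r == YAWN:
            fn += 1
        elif p == NON_YAWN and r == NON_YAWN:
            tn += 1
        else:
            raise AgreementError(f"unknown label pair ({p!r}, {r!r})")
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def cohen_kappa(table: ContingencyTable) -> float:
    """Chance-corrected agreement (pₒ − pₑ)/(1 − pₑ) from a 2×2 table.

    pₑ is computed from the table margins. Returns NaN when both raters
    are constant and identical (pₑ == 1, kappa undefined).
    """
    n = table.n
    po = (table.tp + table.tn) / n
    pred_pos = (table.tp + table.fp) / n
    ref_pos = (table.tp + table.fn) / n
    pe = pred_pos * ref_pos + (1 - pred_pos) * (1 - ref_pos)
    if pe == 1.0:
        return math.nan
    return (po - pe) / (1 - pe)


def agreement_stats(table: ContingencyTable) -> AgreementStats:
    """Sensitivity, specificity, percent agreement and kappa from counts.

    A statistic whose margin is empty (no reference positives for
    sensitivity, no reference negatives for specificity) is returned as
    NaN; the others are still computed. Values are unrounded; reports
    round at presentation time.
    """
    ref_pos = table.tp + table.fn
    ref_neg = table.tn + table.fp
    return AgreementStats(
        sensitivity=table.tp / ref_pos if ref_pos else math.nan,
        specificity=table.tn / ref_neg if ref_neg else math.nan,
        percent_agreement=100.0 * (table.tp + table.tn) / table.n,
        kappa=cohen_kappa(table),
    )


@dataclass
class EventMatchResult:
    matched: list[tuple[str, str]]
    unmatched_a: list[str]
    unmatched_b: list[str]
    tolerance: float
    percent_agreement: float = field(init=False)

    def __post_init__(self) -> None:
        denom = max(
            len(self.matched) + len(self.unmatched_a),
            len(self.matched) + len(self.unmatched_b),
        )
        self.percent_agreement = 100.0 * len(self.matched) / denom if denom else math.nan


def match_events(
    set_a: AnnotationSet, set_b: AnnotationSet, tolerance: float = 1.0
) -> EventMatchResult:
    """One-to-one matching of two coders' events within a time tolerance.

    A pair is eligible when |onsetA − onsetB| ≤ tolerance and
    |offsetA − offsetB| ≤ tolerance. Matching is greedy by nearest onset,
    processing A's events in onset order (earlier onset first — the
    deterministic tie-break). Percent agreement is matched pairs over the
    larger coder's event count.
    """
    if tolerance < 0:
        raise AgreementError("tolerance must be non-negative")
    a_events = sorted(set_a, key=lambda e: (e.onset, e.episode_id))
    b_events = sorted(set_b, key=lambda e: (e.onset, e.episode_id))
    used_b: set[int] = set()
    matched: list[tuple[str, str]] = []
    for ea in a_events:
        best_j, best_d = None, None
        for j, eb in enumerate(b_events):
            if j in used_b:
                continue
            if abs(ea.onset - eb.onset) <= tolerance and abs(ea.offset - eb.offset) <= tolerance:
                d = abs(ea.onset - eb.onset)
                if best_d is None or d < best_d:
                    best_j, best_d = j, d
        if best_j is not None:
            used_b.add(best_j)
            matched.append((ea.episode_id, b_events[best_j].episode_id))
    matched_a = {a for a, _ in matched}
    matched_b = {b for _, b in matched}
    return EventMatchResult(
        matched=matched,
        unmatched_a=[e.episode_id for e in a_events if e.episode_id not in matched_a],
        unmatched_b=[e.episode_id for e in b_events if e.episode_id not in matched_b],
        tolerance=tolerance,
    )


def binned_kappa(
    set_a: AnnotationSet,
    set_b: AnnotationSet,
    fps: float = 24.0,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Frame-binned kappa between two coders' event streams.

    The shared timeline is discretized into bins of width 1/fps; a bin is
    positive for a coder when its centre lies inside any of that coder's
    events. Kappa is then the 2×2 kappa over bins.
    """
    events = list(set_a) + list(set_b)
    if not events:
        raise AgreementError("no events to compare")
    if t_start is None:
        t_start = min(e.onset for e in events)
    if t_end is None:
        t_end = max(e.offset for e in events)
    centres = np.arange(t_start + 0.5 / fps, t_end, 1.0 / fps)

    def occupancy(s: AnnotationSet) -> np.ndarray:
        occ = np.zeros(len(centres), dtype=bool)
        for e in s:
            occ |= (centres >= e.onset) & (centres < e.offset)
        return occ

    occ_a, occ_b = occupancy(set_a), occupancy(set_b)
    table = ContingencyTable(
        tp=int(np.sum(occ_a & occ_b)),
        fp=int(np.sum(occ_a & ~occ_b)),
        fn=int(np.sum(~occ_a & occ_b)),
        tn=int(np.sum(~occ_a & ~occ_b)),
    )
    return cohen_kappa(table)


def phase_duration_agreement(
    durations_a: Sequence[float],
    durations_b: Sequence[float],
    tolerance: float = 0.5,
) -> tuple[float, float]:
    """Percent of aligned duration pairs within tolerance, and the median
    absolute difference.

    Returns (percent in 0..100, median |ΔA − ΔB| in seconds).
    """
    if len(durations_a) != len(durations_b):
        raise AgreementError("duration sequences must be aligned (equal length)")
    if len(durations_a) == 0:
        raise AgreementError("empty input")
    diffs = np.abs(np.asarray(durations_a, float) - np.asarray(durations_b, float))
    percent = 100.0 * float(np.mean(diffs <= tolerance))
    return percent, float(np.median(diffs))
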