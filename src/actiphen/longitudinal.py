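"""Longitudinal cluster-transition analysis across consecutive questionnaires.

Within each participant, questionnaires are ordered by date and each
adjacent pair whose gap is compatible with the biannual schedule (90-270
days by default) becomes one transition record carrying the cluster move
and the change in the subtype-matched disease-activity score (SCDAI for
Crohn disease, SCCAI for ulcerative/indeterminate colitis — never mixed).

Transitions are summarised as counts and one-decimal percentages per
movement class and per (from, to) cell, pooled and split by subtype, with
the mean (SD) score change and a two-tailed paired t test per cell. Cells
with fewer than ``min_n`` pairs suppress the test (marker only), matching
small-cell reporting practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import IBDType, QuestionnaireResponse, logger, percent

_TINY_P = 5e-324

LABEL_ORDER = {"low": 0, "moderate": 1, "high": 2}


@dataclass
class TransitionRecord:
    participant_id: str
    date_from: Date
    date_to: Date
    from_label: str
    to_label: str
    ibd_type: IBDType
    disease_score_change: float | None  # score(t+1) - score(t), subtype's own index

    @property
    def movement_class(self) -> str:
        i, j = LABEL_ORDER[self.from_label], LABEL_ORDER[self.to_label]
        if i == j:
            return "same"
        kind = "adjacent" if abs(i - j) == 1 else "extreme"
        return f"{kind}_{'up' if j > i else 'down'}"


@dataclass
class PairedTResult:
    n: int
    t: float | None
    df: int | None
    p: float | None
    suppressed: bool
    degenerate: bool = False


def paired_t_test(differences: Sequence[float], min_n: int = 5) -> PairedTResult:
    """Two-tailed paired-sample t test on a vector of within-pair differences.

    t = mean(d) / (sd(d)/sqrt(n)), df = n-1. With n below ``min_n`` the test
    is suppressed (no statistic). Zero spread is handled explicitly: all
    differences zero gives t = 0, p = 1; zero spread around a nonzero mean
    gives a flagged below-machine-precision p.
    """
    d = np.asarray(differences, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    n = d.size
    if n < min_n:
        return PairedTResult(n=n, t=None, df=None, p=None, suppressed=True)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return PairedTResult(n=n, t=0.0, df=n - 1, p=1.0, suppressed=False)
        return PairedTResult(n=n, t=math.copysign(math.inf, mean), df=n - 1, p=_TINY_P, suppressed=False, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTResult(n=n, t=float(t), df=n - 1, p=p, suppressed=False)


def pair_consecutive(
    questionnaires: Sequence[QuestionnaireResponse],
    assignments: Mapping[tuple[str, Date], str],
    min_gap_days: int = 90,
    max_gap_days: int = 270,
) -> list[TransitionRecord]:
    """Build transition records from adjacent questionnaire pairs.

    Only questionnaires with a cluster assignment participate; adjacent
    pairs whose gap falls outside [min_gap_days, max_gap_days] are dropped
    with a logged count. Participants with fewer than two assigned
    questionnaires contribute nothing.
    """
    by_pid: dict[str, list[QuestionnaireResponse]] = {}
    for q in questionnaires:
        if (q.participant_id, q.completion_date) in assignments:
            by_pid.setdefault(q.participant_id, []).append(q)
    records: list[TransitionRecord] = []
    n_dropped = 0
    for pid in sorted(by_pid):
        qs = sorted(by_pid[pid], key=lambda q: q.completion_date)
        for q0, q1 in zip(qs, qs[1:]):
            gap = (q1.completion_date - q0.completion_date).days
            if not min_gap_days <= gap <= max_gap_days:
                n_dropped += 1
                continue
            s0, s1 = q0.disease_score, q1.disease_score
            change = (s1 - s0) if (s0 is not None and s1 is not None) else None
            records.append(
                TransitionRecord(
                    participant_id=pid,
                    date_from=q0.completion_date,
                    date_to=q1.completion_date,
                    from_label=assignments[(pid, q0.completion_date)],
                    to_label=assignments[(pid, q1.completion_date)],
                    ibd_type=q0.ibd_type,
                    disease_score_change=change,
                )
            )
    if n_dropped:
        logger.info("pair_consecutive dropped %d pairs outside the gap window", n_dropped)
    return records


@dataclass
class CellSummary:
    from_label: str
    to_label: str
    n: int
    percent: float  # of total pairs, one decimal
    mean_change: float | None
    sd_change: float | None
    test: PairedTResult | None


@dataclass
class TransitionSummary:
    total_pairs: int
    class_counts: dict[str, int]
    class_percents: dict[str, float]
    pair_counts: dict[str, int]  # unordered pair classes, e.g. "low<->moderate"
    pair_percents: dict[str, float]
    cells: dict[str, list[CellSummary]]  # "pooled" | "CD" | "UC_IC"

    @property
    def percent_same(self) -> float:
        return self.pair_percents["same"]

    def to_dict(self) -> dict:
        def cell_dict(c: CellSummary) -> dict:
            return {
                "from": c.from_label,
                "to": c.to_label,
                "n": c.n,
                "percent": c.percent,
                "mean_change": c.mean_change,
                "sd_change": c.sd_change,
                "t": c.test.t if c.test else None,
                "df": c.test.df if c.test else None,
                "p": c.test.p if c.test else None,
                "suppressed": c.test.suppressed if c.test else None,
            }

        return {
            "total_pairs": self.total_pairs,
            "class_counts": dict(self.class_counts),
            "class_percents": dict(self.class_percents),
            "pair_counts": dict(self.pair_counts),
            "pair_percents": dict(self.pair_percents),
            "cells": {k: [cell_dict(c) for c in v] for k, v in self.cells.items()},
        }


def _pct(n: int, total: int) -> float:
    return percent(n, total, 1)


def summarize_transitions(records: Sequence[TransitionRecord], min_n: int = 5) -> TransitionSummary:
    """Counts, one-decimal percentages, and per-cell paired t tests.

    ``pair_counts`` pools each unordered move (e.g. low->moderate plus
    moderate->low as "low<->moderate"); denominators are always the total
    number of pairs.
    """
    if not records:
        raise ValueError("no transition records")
    total = len(records)
    class_counts: dict[str, int] = {}
    pair_counts: dict[str, int] = {"same": 0}
    for r in records:
        class_counts[r.movement_class] = class_counts.get(r.movement_class, 0) + 1
        if r.from_label == r.to_label:
            pair_counts["same"] += 1
        else:
            a, b = sorted((r.from_label, r.to_label), key=lambda l: LABEL_ORDER[l])
            key = f"{a}<->{b}"
            pair_counts[key] = pair_counts.get(key, 0) + 1

    cells: dict[str, list[CellSummary]] = {}
    subsets = {
        "pooled": list(records),
        "CD": [r for r in records if r.ibd_type is IBDType.CD],
        "UC_IC": [r for r in records if r.ibd_type is IBDType.UC_IC],
    }
    labels = sorted({r.from_label for r in records} | {r.to_label for r in records}, key=lambda l: LABEL_ORDER[l])
    for name, subset in subsets.items():
        out: list[CellSummary] = []
        for from_label in labels:
            for to_label in labels:
                cell = [r for r in subset if r.from_label == from_label and r.to_label == to_label]
                if not cell:
                    continue
                changes = [r.disease_score_change for r in cell if r.disease_score_change is not None]
                mean_change = float(np.mean(changes)) if changes else None
                sd_change = float(np.std(changes, ddof=1)) if len(changes) > 1 else None
                test = paired_t_test(changes, min_n=min_n) if changes else None
                out.append(
                    CellSummary(
                        from_label=from_label,
                        to_label=to_label,
                        n=len(cell),
                        percent=_pct(len(cell), total),
                        mean_change=mean_change,
                        sd_change=sd_change,
                        test=test,
                    )
                )
        cells[name] = out

    return TransitionSummary(
        total_pairs=total,
        class_counts=class_counts,
        class_percents={k: _pct(v, total) for k, v in class_counts.items()},
        pair_counts=pair_counts,
        pair_percents={k: _pct(v, total) for k, v in pair_counts.items()},
        cells=cells,
    )
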