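"""Selection of the activity-aggregation lag by rank correlation.

Mean daily steps are aggregated over candidate lags (weeks before each
questionnaire) and Spearman-correlated with disease activity — SCDAI in the
Crohn disease subset and SCCAI in the ulcerative/indeterminate colitis
subset. The lag with the strongest combined correlation is selected; both
per-index correlations are always reported because higher activity is
expected to accompany lower disease activity (negative rho) in both groups.

The combined criterion is the subgroup-size-weighted mean of the absolute
correlations, with ties broken toward the shorter lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core import DailyActivityRecord, IBDType, QuestionnaireResponse, logger
from .preprocessing import build_windows

DEFAULT_LAGS_WEEKS = (1, 2, 4, 6, 8, 12, 24)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns (rho, p); p uses the t approximation
    t = rho * sqrt((n-2) / (1-rho^2)). A zero-variance input yields
    (nan, nan), which callers must treat as an undefined, flagged result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    result = stats.spearmanr(x, y)
    return float(result.statistic), float(result.pvalue)


@dataclass
class LagResult:
    lag_weeks: int
    n_pairs: int
    n_cd: int
    n_uc: int
    rho_scdai: float
    p_scdai: float
    rho_sccai: float
    p_sccai: float
    combined_abs_rho: float
    skipped: bool = False


@dataclass
class LagScanResult:
    per_lag: list[LagResult] = field(default_factory=list)
    selected_lag_weeks: int | None = None
    selection_significant: bool = False
    criterion: str = "n-weighted mean of |rho_scdai| and |rho_sccai|; ties to shorter lag"

    def to_dict(self) -> dict:
        return {
            "selected_lag_weeks": self.selected_lag_weeks,
            "selection_significant": self.selection_significant,
            "criterion": self.criterion,
            "per_lag": [dict(r.__dict__) for r in self.per_lag],
        }


def scan_lags(
    daily: Sequence[DailyActivityRecord],
    questionnaires: Sequence[QuestionnaireResponse],
    lags_weeks: Sequence[int] = DEFAULT_LAGS_WEEKS,
    min_coverage: float = 0.5,
    min_pairs: int = 10,
) -> LagScanResult:
    """Scan candidate lags and select the one maximising |rho| combined
    across disease indices.

    For each lag, windows are rebuilt at ``7 * lag`` days with the same
    coverage rule as the main pipeline, and mean steps are correlated with
    the subtype-matched disease score. Lags with fewer than ``min_pairs``
    eligible pairs are skipped with a warning.
    """
    by_key = {(q.participant_id, q.completion_date): q for q in questionnaires}
    result = LagScanResult()
    best: tuple[float, int] | None = None
    for lag in sorted({int(l) for l in lags_weeks}):
        windows = build_windows(daily, questionnaires, window_days=7 * int(lag), min_coverage=min_coverage)
        cd_x, cd_y, uc_x, uc_y = [], [], [], []
        for w in windows:
            q = by_key.get((w.participant_id, w.questionnaire_date))
            if q is None or w.mean_steps is None:
                continue
            if q.ibd_type is IBDType.CD and q.scdai is not None:
                cd_x.append(w.mean_steps)
                cd_y.append(q.scdai)
            elif q.ibd_type is IBDType.UC_IC and q.sccai is not None:
                uc_x.append(w.mean_steps)
                uc_y.append(q.sccai)
        n_cd, n_uc = len(cd_x), len(uc_x)
        n_pairs = n_cd + n_uc
        if n_pairs < min_pairs:
            logger.warning("lag %d weeks skipped: only %d eligible pairs", lag, n_pairs)
            result.per_lag.append(
                LagResult(lag, n_pairs, n_cd, n_uc, float("nan"), float("nan"), float("nan"), float("nan"), float("nan"), skipped=True)
            )
            continue
        rho_cd, p_cd = spearman_rho(cd_x, cd_y) if n_cd >= 3 else (float("nan"), float("nan"))
        rho_uc, p_uc = spearman_rho(uc_x, uc_y) if n_uc >= 3 else (float("nan"), float("nan"))
        parts, weights = [], []
        for rho, n in ((rho_cd, n_cd), (rho_uc, n_uc)):
            if not np.isnan(rho):
                parts.append(abs(rho))
                weights.append(n)
        combined = float(np.average(parts, weights=weights)) if parts else float("nan")
        result.per_lag.append(LagResult(int(lag), n_pairs, n_cd, n_uc, rho_cd, p_cd, rho_uc, p_uc, combined))
        if not np.isnan(combined) and (best is None or combined > best[0]):
            # strict > keeps the earlier (shorter) lag on ties
            best = (combined, int(lag))
    if best is not None:
        result.selected_lag_weeks = best[1]
        chosen = next(r for r in result.per_lag if r.lag_weeks == best[1])
        ps = [p for p in (chosen.p_scdai, chosen.p_sccai) if not np.isnan(p)]
        result.selection_significant = bool(ps and min(ps) < 0.05)
    return result
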