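"""Cross-sectional comparison of PROs and characteristics across clusters.

The unit of analysis is the activity window (period), not the participant:
a participant contributes one observation per questionnaire period, with no
correction for repeated measures — this mirrors the reference analysis and
is a documented caveat, not an oversight. Continuous variables are compared
with one-way ANOVA, categorical variables with Pearson chi-square; disease
indices are profiled only within the matching IBD subtype. Raw p-values are
reported at alpha = .05 with no multiplicity adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    PROMIS_DOMAINS,
    ActivityWindow,
    IBDType,
    QuestionnaireResponse,
)

_TINY_P = 5e-324  # smallest subnormal double; stands in for p < machine-min


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False  # zero within-group variance with unequal means


def oneway_anova(groups: Sequence[Sequence[float]], welch: bool = False) -> AnovaResult:
    """One-way ANOVA from sums of squares.

    Degenerate inputs follow explicit conventions: identical observations
    everywhere give F = 0, p = 1; zero within-group variance with unequal
    means gives a flagged result with p below machine precision. The Welch
    (unequal-variance) form is available behind a flag but off by default.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if any(not np.all(np.isfinite(a)) for a in arrays):
        raise ValueError("observations must be finite")
    if welch:
        means = np.array([a.mean() for a in arrays])
        variances = np.array([a.var(ddof=1) for a in arrays])
        ns = np.array([a.size for a in arrays], dtype=float)
        if np.any(variances == 0):
            raise ValueError("Welch ANOVA requires positive within-group variance")
        w = ns / variances
        grand_w = (w * means).sum() / w.sum()
        k = len(arrays)
        f_num = ((w * (means - grand_w) ** 2).sum()) / (k - 1)
        lam = (3.0 / (k * k - 1)) * (((1 - w / w.sum()) ** 2) / (ns - 1)).sum()
        f = f_num / (1 + 2 * lam * (k - 2) / 3.0)
        df2 = 1.0 / lam
        p = float(stats.f.sf(f, k - 1, df2))
        return AnovaResult(float(f), k - 1, int(df2), p)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between, df_within = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_between, df_within, 1.0)
        return AnovaResult(math.inf, df_between, df_within, _TINY_P, degenerate=True)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    expected: np.ndarray
    low_expected_warning: bool  # any expected cell < 5


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the margins; a zero row/column margin is an
    error, and any expected cell below 5 sets a warning flag.
    """
    observed = np.asarray(table, dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if np.any(observed < 0):
        raise ValueError("counts must be non-negative")
    if np.any(observed.sum(axis=1) == 0) or np.any(observed.sum(axis=0) == 0):
        raise ValueError("zero row or column margin")
    statistic, p, df, expected = stats.chi2_contingency(observed, correction=False)
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p=float(p),
        expected=expected,
        low_expected_warning=bool(np.any(expected < 5)),
    )


#: Continuous variables profiled by default: the six PROMIS T-scores, the two
#: disease indices (within subtype), and numeric covariates.
DEFAULT_CONTINUOUS = (
    ["scdai", "sccai"]
    + [f"promis_{d}" for d in PROMIS_DOMAINS]
    + ["age", "bmi", "disease_duration_years"]
)
DEFAULT_CATEGORICAL = (
    "gender",
    "education",
    "smoking_ever",
    "tx_5asa",
    "tx_biologic",
    "tx_corticosteroid",
    "tx_immunomodulator",
)


@dataclass
class ContinuousProfile:
    variable: str
    per_cluster_n: dict[str, int]
    per_cluster_mean: dict[str, float]
    per_cluster_sd: dict[str, float]
    n_missing: int
    test: AnovaResult | None


@dataclass
class CategoricalProfile:
    variable: str
    counts: dict[str, dict[str, int]]  # cluster -> level -> count
    percents: dict[str, dict[str, float]]
    n_missing: int
    test: ChiSquareResult | None


@dataclass
class ClusterProfile:
    cluster_order: tuple[str, ...]
    n_windows: dict[str, int]
    continuous: dict[str, ContinuousProfile] = field(default_factory=dict)
    categorical: dict[str, CategoricalProfile] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "cluster_order": list(self.cluster_order),
            "n_windows": dict(self.n_windows),
            "continuous": {},
            "categorical": {},
        }
        for name, prof in self.continuous.items():
            out["continuous"][name] = {
                "n": prof.per_cluster_n,
                "mean": prof.per_cluster_mean,
                "sd": prof.per_cluster_sd,
                "n_missing": prof.n_missing,
                "F": prof.test.f if prof.test else None,
                "df": [prof.test.df_between, prof.test.df_within] if prof.test else None,
                "p": prof.test.p if prof.test else None,
                "test": "one-way ANOVA",
            }
        for name, prof in self.categorical.items():
            out["categorical"][name] = {
                "counts": prof.counts,
                "percents": prof.percents,
                "n_missing": prof.n_missing,
                "chi2": prof.test.statistic if prof.test else None,
                "df": prof.test.df if prof.test else None,
                "p": prof.test.p if prof.test else None,
                "low_expected_warning": prof.test.low_expected_warning if prof.test else None,
                "test": "chi-square",
            }
        return out


def _variable_value(q: QuestionnaireResponse, variable: str):
    if variable == "scdai":
        return q.scdai if q.ibd_type is IBDType.CD else None
    if variable == "sccai":
        return q.sccai if q.ibd_type is IBDType.UC_IC else None
    if variable.startswith("promis_"):
        return q.promis.get(variable.removeprefix("promis_"))
    return q.covariates.get(variable)


def profile_clusters(
    windows: Sequence[ActivityWindow],
    assignments: Mapping[tuple[str, object], str],
    questionnaires: Sequence[QuestionnaireResponse],
    continuous: Sequence[str] = tuple(DEFAULT_CONTINUOUS),
    categorical: Sequence[str] = tuple(DEFAULT_CATEGORICAL),
) -> ClusterProfile:
    """Per-cluster profile of continuous and categorical variables.

    ``assignments`` maps (participant_id, questionnaire_date) to a cluster
    label. Continuous variables get per-cluster mean/SD plus ANOVA;
    categorical variables get counts/percents plus chi-square. Missing
    values are excluded pairwise with counts reported. Disease indices are
    restricted to the matching subtype by construction.
    """
    by_key = {(q.participant_id, q.completion_date): q for q in questionnaires}
    rows: list[tuple[str, QuestionnaireResponse]] = []
    for w in windows:
        key = (w.participant_id, w.questionnaire_date)
        if key not in assignments:
            raise ValueError(f"window {key} has no cluster assignment")
        if key not in by_key:
            raise ValueError(f"window {key} has no linked questionnaire")
        rows.append((assignments[key], by_key[key]))

    clusters = sorted({label for label, _ in rows}, key=_cluster_sort_key)
    profile = ClusterProfile(
        cluster_order=tuple(clusters),
        n_windows={c: sum(1 for label, _ in rows if label == c) for c in clusters},
    )

    known = set(DEFAULT_CONTINUOUS) | set(DEFAULT_CATEGORICAL)
    for variable in list(continuous) + list(categorical):
        present = any(_variable_value(q, variable) is not None for _, q in rows)
        if not present and variable not in known:
            raise ValueError(f"variable {variable!r} absent from data")

    for variable in continuous:
        groups: dict[str, list[float]] = {c: [] for c in clusters}
        n_missing = 0
        for label, q in rows:
            value = _variable_value(q, variable)
            if value is None:
                n_missing += 1
            else:
                groups[label].append(float(value))
        usable = {c: g for c, g in groups.items() if len(g) >= 2}
        test = oneway_anova(list(usable.values())) if len(usable) >= 2 else None
        profile.continuous[variable] = ContinuousProfile(
            variable=variable,
            per_cluster_n={c: len(g) for c, g in groups.items()},
            per_cluster_mean={c: float(np.mean(g)) for c, g in groups.items() if g},
            per_cluster_sd={c: float(np.std(g, ddof=1)) if len(g) > 1 else 0.0 for c, g in groups.items() if g},
            n_missing=n_missing,
            test=test,
        )

    for variable in categorical:
        counts: dict[str, dict[str, int]] = {c: {} for c in clusters}
        n_missing = 0
        levels: list[str] = []
        for label, q in rows:
            value = _variable_value(q, variable)
            if value is None or value == "":
                n_missing += 1
                continue
            value = str(value)
            if value not in levels:
                levels.append(value)
            counts[label][value] = counts[label].get(value, 0) + 1
        table = np.array([[counts[c].get(level, 0) for level in levels] for c in clusters], dtype=float)
        test = None
        if len(levels) >= 2 and table.size and not (
            np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0)
        ):
            test = chi_square_independence(table)
        percents = {
            c: {
                level: 100.0 * counts[c].get(level, 0) / max(sum(counts[c].values()), 1)
                for level in levels
            }
            for c in clusters
        }
        profile.categorical[variable] = CategoricalProfile(
            variable=variable, counts=counts, percents=percents, n_missing=n_missing, test=test
        )
    return profile


_ACTIVITY_ORDER = {"low": 0, "moderate": 1, "high": 2}


def _cluster_sort_key(label: str):
    return (_ACTIVITY_ORDER.get(label, 99), label)
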