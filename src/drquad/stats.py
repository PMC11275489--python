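"""Cohort statistics for quadrant lesion counts.

Summaries (n, mean, SD, SEM), two-sample t-tests computed either from raw
values or directly from printed summary statistics (the form needed to audit
published tables), one-way ANOVA, and the assembly of a full cohort report:
per-grade x per-quadrant summaries, ANOVA margins, and pairwise t-tests of a
reference quadrant against the others.

Quadrant comparisons treat the four quadrant count groups as independent
samples (not paired within eyes): with k groups of equal size n the Welch
and pooled t statistics coincide, and published quadrant t-values for these
cohorts are reproducible only under the independent two-sample formula.  A
paired analysis is deliberately not the default.  No multiple-testing
correction is applied; p-values are reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import QUADRANTS, QuadrantCounts, Region
from .grading import GRADE_LABELS
from .lesions import LesionType

LESION_COLUMNS = {LesionType.MA: "n_MA", LesionType.HEM: "n_HEM"}


class ZeroVarianceError(ValueError):
    """Both groups constant with equal means: the t statistic is undefined."""


@dataclass(frozen=True)
class SummaryStats:
    """Sample size, mean, standard deviation (n-1) and standard error."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"summary statistics require n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def sem(self) -> float:
        return self.sd / math.sqrt(self.n)


def summarize(values: Sequence[float] | np.ndarray) -> SummaryStats:
    """Mean, sample SD (n-1 denominator) and SEM of a sample (n >= 2)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise ValueError(f"need at least two values, got {arr.size}")
    return SummaryStats(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: str  # "pooled" | "welch"


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def t_from_summary(
    a: SummaryStats, b: SummaryStats, method: str = "welch"
) -> TTestResult:
    """Two-sample t-test computed from summary statistics alone.

    ``welch`` uses unpooled variances with Welch-Satterthwaite degrees of
    freedom; ``pooled`` is the classic equal-variance Student t.  With equal
    group sizes the two t statistics are numerically identical (only the df,
    hence p, can differ).  Two-sided p.
    """
    if method not in ("welch", "pooled"):
        raise ValueError(f"method must be 'welch' or 'pooled', got {method!r}")
    va, vb = a.sd**2, b.sd**2
    diff = a.mean - b.mean
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            raise ZeroVarianceError("both groups constant with equal means: t undefined")
        t = math.inf if diff > 0 else -math.inf
        df = float(a.n + b.n - 2)
        return TTestResult(t=t, df=df, p=0.0, method=method)
    if method == "pooled":
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        qa, qb = va / a.n, vb / b.n
        se = math.sqrt(qa + qb)
        df = (qa + qb) ** 2 / (qa**2 / (a.n - 1) + qb**2 / (b.n - 1))
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, method=method)


def t_independent(
    x: Sequence[float], y: Sequence[float], method: str = "welch"
) -> TTestResult:
    """Two-sample t-test on raw values; identical to summarizing then testing."""
    return t_from_summary(summarize(x), summarize(y), method=method)


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA, F = MS_between / MS_within.

    Degenerate inputs follow the conventions: all values identical overall
    gives F = 0, p = 1; zero within-group variance with distinct group means
    gives an infinite F with p = 0.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between, df_within = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(f=0.0, df_between=df_between, df_within=df_within, p=1.0)
        return AnovaResult(f=math.inf, df_between=df_between, df_within=df_within, p=0.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(f=float(f), df_between=df_between, df_within=df_within, p=p)


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------


@dataclass
class CohortReport:
    """Per-grade per-quadrant summaries with ANOVA margins and pairwise t's.

    ``summaries`` is long-format (database, lesion, grade, quadrant, n, mean,
    sd, sem).  ``anova_across_quadrants`` has one row per (lesion, grade);
    ``anova_across_grades`` one per (lesion, quadrant); ``pairwise_t`` one
    per (lesion, grade, other quadrant) comparing the reference quadrant
    against the other.  Cells that could not be computed are listed in
    ``missing`` rather than silently dropped or zero-filled.
    """

    database: str
    reference_quadrant: Region
    summaries: pd.DataFrame
    anova_across_quadrants: pd.DataFrame
    anova_across_grades: pd.DataFrame
    pairwise_t: pd.DataFrame
    missing: list[str] = field(default_factory=list)

    def summary(self, lesion: LesionType | str, grade: str, quadrant: Region | str) -> SummaryStats:
        df = self.summaries
        row = df[
            (df.lesion == LesionType(lesion).value)
            & (df.grade == grade)
            & (df.quadrant == Region(quadrant).value)
        ]
        if row.empty:
            raise KeyError(f"no summary for ({lesion}, {grade}, {quadrant})")
        r = row.iloc[0]
        return SummaryStats(n=int(r.n), mean=float(r["mean"]), sd=float(r.sd))

    def stats_dict(self) -> dict:
        """JSON-serializable block with the ANOVA and pairwise-t results."""
        return {
            "database": self.database,
            "reference_quadrant": self.reference_quadrant.value,
            "anova_across_quadrants": self.anova_across_quadrants.to_dict("records"),
            "anova_across_grades": self.anova_across_grades.to_dict("records"),
            "pairwise_t": self.pairwise_t.to_dict("records"),
            "missing": list(self.missing),
        }


def _counts_long(counts: Iterable[QuadrantCounts]) -> pd.DataFrame:
    rows: list[dict] = []
    for qc in counts:
        rows.extend(qc.to_rows())
    return pd.DataFrame(rows)


def build_report(
    counts: Iterable[QuadrantCounts] | pd.DataFrame,
    grades: Mapping[str, int] | pd.DataFrame,
    reference_quadrant: Region | str = Region.TEMPORAL,
    database: str = "cohort",
    method: str = "welch",
    include_levels: Sequence[int] = (1, 2, 3),
) -> CohortReport:
    """Assemble the full quadrant-statistics report for a graded cohort.

    Parameters
    ----------
    counts:
        Per-image :class:`~drquad.geometry.QuadrantCounts`, or an equivalent
        long DataFrame with columns (image_id, region, n_MA, n_HEM).
    grades:
        ``image_id -> level`` mapping, or a DataFrame with columns
        (image_id, level).
    reference_quadrant:
        Quadrant compared pairwise against the other three (default
        temporal, the quadrant with the highest lesion load).
    include_levels:
        DR levels entering the report; level-0 (lesion-free) images are
        excluded by default, as published per-grade tables list only the
        graded strata.
    """
    reference_quadrant = Region(reference_quadrant)
    if reference_quadrant not in QUADRANTS:
        raise ValueError(f"reference quadrant must be one of the four quadrants, got {reference_quadrant}")
    df = counts if isinstance(counts, pd.DataFrame) else _counts_long(counts)
    if isinstance(grades, pd.DataFrame):
        grade_map = dict(zip(grades["image_id"].astype(str), grades["level"].astype(int)))
    else:
        grade_map = {str(k): int(v) for k, v in grades.items()}
    df = df.copy()
    df["image_id"] = df["image_id"].astype(str)
    unknown = set(df.image_id) - set(grade_map)
    if unknown:
        raise ValueError(f"{len(unknown)} image(s) have counts but no grade, e.g. {sorted(unknown)[:3]}")
    df["level"] = df.image_id.map(grade_map)
    df = df[df.level.isin(include_levels) & df.region.isin([q.value for q in QUADRANTS])]

    levels_present = sorted(df.level.unique())
    summaries: list[dict] = []
    missing: list[str] = []
    # values[(lesion, level, quadrant)] -> per-image count vector
    values: dict[tuple[str, int, str], np.ndarray] = {}
    for lesion, col in ((lt.value, c) for lt, c in LESION_COLUMNS.items()):
        for level in levels_present:
            for q in QUADRANTS:
                v = df[(df.level == level) & (df.region == q.value)][col].to_numpy(float)
                key = (lesion, level, q.value)
                if v.size < 2:
                    missing.append(f"summary:{lesion}:{GRADE_LABELS[level]}:{q.value}")
                    continue
                values[key] = v
                s = summarize(v)
                summaries.append(
                    {
                        "database": database,
                        "lesion": lesion,
                        "grade": GRADE_LABELS[level],
                        "quadrant": q.value,
                        "n": s.n,
                        "mean": s.mean,
                        "sd": s.sd,
                        "sem": s.sem,
                    }
                )

    anova_q_rows, anova_g_rows, pairwise_rows = [], [], []
    for lesion in (lt.value for lt in LESION_COLUMNS):
        for level in levels_present:
            groups = [values.get((lesion, level, q.value)) for q in QUADRANTS]
            if any(g is None for g in groups):
                missing.append(f"anova_quadrants:{lesion}:{GRADE_LABELS[level]}")
            else:
                a = anova_oneway(groups)
                anova_q_rows.append(
                    {"lesion": lesion, "grade": GRADE_LABELS[level], "f": a.f,
                     "df_between": a.df_between, "df_within": a.df_within, "p": a.p}
                )
            ref = values.get((lesion, level, reference_quadrant.value))
            for q in QUADRANTS:
                if q is reference_quadrant:
                    continue
                other = values.get((lesion, level, q.value))
                if ref is None or other is None:
                    missing.append(f"t:{lesion}:{GRADE_LABELS[level]}:{reference_quadrant.value}_vs_{q.value}")
                    continue
                try:
                    t = t_independent(ref, other, method=method)
                except ZeroVarianceError:
                    # constant identical groups: no evidence of a difference
                    t = TTestResult(t=0.0, df=float(len(ref) + len(other) - 2), p=1.0, method=method)
                pairwise_rows.append(
                    {"lesion": lesion, "grade": GRADE_LABELS[level],
                     "reference": reference_quadrant.value, "other": q.value,
                     "t": t.t, "df": t.df, "p": t.p, "method": t.method}
                )
        for q in QUADRANTS:
            groups = [values.get((lesion, lvl, q.value)) for lvl in levels_present]
            groups = [g for g in groups if g is not None]
            if len(groups) < 2:
                missing.append(f"anova_grades:{lesion}:{q.value}")
                continue
            a = anova_oneway(groups)
            anova_g_rows.append(
                {"lesion": lesion, "quadrant": q.value, "f": a.f,
                 "df_between": a.df_between, "df_within": a.df_within, "p": a.p}
            )

    sum_cols = ["database", "lesion", "grade", "quadrant", "n", "mean", "sd", "sem"]
    return CohortReport(
        database=database,
        reference_quadrant=reference_quadrant,
        summaries=pd.DataFrame(summaries, columns=sum_cols),
        anova_across_quadrants=pd.DataFrame(
            anova_q_rows, columns=["lesion", "grade", "f", "df_between", "df_within", "p"]
        ),
        anova_across_grades=pd.DataFrame(
            anova_g_rows, columns=["lesion", "quadrant", "f", "df_between", "df_within", "p"]
        ),
        pairwise_t=pd.DataFrame(
            pairwise_rows,
            columns=["lesion", "grade", "reference", "other", "t", "df", "p", "method"],
        ),
        missing=missing,
    )
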