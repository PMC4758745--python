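"""Cohort statistics: descriptive tables, normality screen, rank correlation.

Metrics are summarized per LOCS III grade as median [min-max] (the metric
distributions are screened for normality with a one-sample Kolmogorov-
Smirnov test and are generally non-normal, hence medians).  Agreement of a
metric with the ordinal LOCS grade is quantified by the Spearman rank
correlation with average-rank tie handling, plus an ordinary least-squares
tendency line reported descriptively.  Eyes (not patients) are the
statistical unit; significance is two-sided at P < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GradeRecord",
    "CorrelationResult",
    "descriptive_table",
    "ks_normality",
    "spearman_with_grade",
]

#: Sample size at or below which the Spearman p-value is computed by exact
#: permutation enumeration rather than the t approximation.
EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class GradeRecord:
    """One eye's subjective LOCS III grade.

    ``locs_grade`` is 0.0 for clear-lens controls (the LOCS III scale itself
    starts at 0.1), otherwise in [0.1, 5.9]; non-integer grades occur only at
    .5 midpoints between standards.
    """

    eye_id: str
    locs_grade: float
    opacity_type: str

    def __post_init__(self) -> None:
        g = float(self.locs_grade)
        if g != 0.0:
            if not (0.1 <= g <= 5.9):
                raise ValueError(f"LOCS grade {g} outside [0.1, 5.9]")
            if abs(g * 2 - round(g * 2)) > 1e-9:
                raise ValueError(
                    f"LOCS grade {g}: decimals only at .5 midpoints between standards"
                )
        if self.opacity_type not in ("nuclear", "cortical"):
            raise ValueError("opacity_type must be 'nuclear' or 'cortical'")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman agreement of a metric with the LOCS grade, plus tendency line."""

    rho: float
    p_value: float
    n: int
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValueError("|rho| must not exceed 1")
        if self.n < 3:
            raise ValueError("a p-value needs at least 3 pairs")


def descriptive_table(
    grades: Sequence[float], values: Sequence[float]
) -> pd.DataFrame:
    """Median [min-max] of a metric per LOCS grade bin.

    Grades are binned exactly as given (no interpolation between standards).
    Returns a DataFrame indexed by grade with columns ``n``, ``median``,
    ``min``, ``max``.
    """
    grades = np.asarray(grades, dtype=float)
    values = np.asarray(values, dtype=float)
    if grades.size == 0 or grades.size != values.size:
        raise ValueError("need one (grade, value) pair per eye, at least one pair")
    df = pd.DataFrame({"grade": grades, "value": values})
    out = (
        df.groupby("grade")["value"]
        .agg(n="size", median="median", min="min", max="max")
        .sort_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def ks_normality(values: Sequence[float]) -> Tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    Tests the sample against a normal distribution with the sample's own
    mean and standard deviation; used as a reporting gate (medians vs means),
    with no downstream branching.  Requires n >= 5 and a non-constant sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"normality screen needs n >= 5, got n = {x.size}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("normality screen undefined for a constant sample")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (tie-aware).

    Enumerates all n! pairings of the (average) ranks; the p-value is the
    fraction of permutations whose |rho| is at least |rho_obs|.
    """
    n = rx.size
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(np.dot(rxc, rxc)) * float(np.dot(ryc, ryc)))
    obs = abs(rho_obs) * denom - 1e-9
    count = 0
    total = 0
    chunk = []
    chunk_size = 200_000
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            dots = np.abs(ryc[np.array(chunk)] @ rxc)
            count += int((dots >= obs).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        dots = np.abs(ryc[np.array(chunk)] @ rxc)
        count += int((dots >= obs).sum())
        total += len(chunk)
    return count / total


def spearman_with_grade(
    grades: Sequence[float], values: Sequence[float]
) -> CorrelationResult:
    """Spearman rank correlation of a metric with the LOCS grade.

    Ties receive average ranks; rho is the Pearson correlation of the rank
    vectors.  The two-sided p-value uses the t approximation for n > 10 and
    exact permutation enumeration for n <= 10.  An OLS tendency line of
    metric on grade is fitted and reported descriptively (slope, intercept).
    """
    x = np.asarray(grades, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (grade, value) pairs")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Spearman rho undefined when either variable is constant")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(
        rho=rho, p_value=float(p), n=int(n), slope=float(slope), intercept=float(intercept)
    )
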