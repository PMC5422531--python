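"""Group formation and nonparametric inference.

Median splits define the groups (age -> younger/older; naming latency
within the older group -> faster/slower), Mann-Whitney U compares them on
each asymmetry index, and an ANCOVA checks whether a group difference
survives adjustment for naming latency.

The Mann-Whitney statistic is computed from first principles: U counts
favorable cross-pairs (with 1/2 per tie), the exact two-sided p comes from
full enumeration of the null U distribution for small untied samples, and
otherwise from the tie-corrected normal approximation without continuity
correction.  The signed Z is negative when the first sample tends lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import (
    ArgumentError,
    AssignmentError,
    CollinearityError,
    DegenerateSplitError,
)
from .indices import INDEX_NAMES

__all__ = [
    "GroupAssignment",
    "MWResult",
    "AncovaResult",
    "Descriptives",
    "median_split",
    "mann_whitney",
    "ancova_group_effect",
    "compare_groups",
    "describe",
]


@dataclass(frozen=True)
class GroupAssignment:
    """A two-group labelling of subjects, with a fixed label order."""

    labels: tuple[str, str]
    assignment: dict[str, str]

    def members(self, label: str) -> list[str]:
        return [sid for sid, lab in self.assignment.items() if lab == label]

    def __post_init__(self) -> None:
        extra = set(self.assignment.values()) - set(self.labels)
        if extra:
            raise ArgumentError(f"assignment uses labels {extra} outside {self.labels}")


@dataclass(frozen=True)
class MWResult:
    """A Mann-Whitney U comparison of two samples."""

    U1: float
    Z: float
    p_two_sided: float
    method: str  # "exact" or "normal"
    n1: int
    n2: int


@dataclass(frozen=True)
class AncovaResult:
    """Group effect adjusted for a continuous covariate (extra sum of squares F)."""

    F: float
    df_effect: int
    df_residual: int
    p: float
    intercept: float
    group_effect: float
    covariate_slope: float


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float


def describe(values) -> Descriptives:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return Descriptives(n=int(arr.size), mean=float(arr.mean()), sd=sd)


def median_split(values: dict[str, float], labels: tuple[str, str]) -> GroupAssignment:
    """Partition subjects at the median of ``values``.

    Subjects strictly below the (midpoint-interpolated) median go to the
    first label, subjects at or above it to the second.  For an even number
    of distinct values this is an exact half split.  Constant values cannot
    be split.
    """
    if len(values) < 4:
        raise ArgumentError("median split needs at least 4 subjects")
    arr = np.array(list(values.values()), dtype=float)
    if np.all(arr == arr[0]):
        raise DegenerateSplitError("all values identical; cannot median-split")
    med = float(np.median(arr))
    assignment = {sid: (labels[0] if v < med else labels[1]) for sid, v in values.items()}
    return GroupAssignment(labels=labels, assignment=assignment)


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value, U = 0 .. n1*n2.

    Classic recurrence: c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u),
    i.e. the Gaussian binomial coefficient expansion.
    """
    if n1 == 0 or n2 == 0:
        return tuple([1] + [0] * (n1 * n2))
    counts = np.zeros(n1 * n2 + 1, dtype=object)
    a = np.array(_u_counts(n1 - 1, n2), dtype=object)
    counts[n2 : n2 + a.size] += a
    b = np.array(_u_counts(n1, n2 - 1), dtype=object)
    counts[: b.size] += b
    return tuple(int(c) for c in counts)


def exact_u_pvalue(u1: float, n1: int, n2: int) -> float:
    """Exact two-sided p for untied samples by enumerating the U distribution."""
    counts = _u_counts(n1, n2)
    total = sum(counts)
    u_small = min(u1, n1 * n2 - u1)
    tail = sum(c for u, c in enumerate(counts) if u <= u_small + 1e-9)
    return min(1.0, 2.0 * tail / total)


def mann_whitney(x, y, exact_max_n: int = 10) -> MWResult:
    """Mann-Whitney U test of two independent samples.

    U1 is the first sample's statistic (favorable (x_i, y_j) pairs, ties
    counting 1/2).  Z uses the tie-corrected null variance without
    continuity correction; its sign is negative when the first sample tends
    lower.  The two-sided p is exact (full enumeration) when
    ``max(n1, n2) <= exact_max_n`` and there are no ties, otherwise from
    the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ArgumentError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks for ties
    r1 = ranks[:n1].sum()
    u1 = float(r1 - n1 * (n1 + 1) / 2.0)

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mean_u = n1 * n2 / 2.0
    if var > 0:
        z = (u1 - mean_u) / np.sqrt(var)
    else:
        z = 0.0

    if not has_ties and (max(n1, n2) <= exact_max_n or n <= 12):
        p = exact_u_pvalue(u1, n1, n2)
        method = "exact"
    else:
        p = float(2.0 * sps.norm.sf(abs(z))) if var > 0 else 1.0
        method = "normal"
    return MWResult(U1=u1, Z=float(z), p_two_sided=min(1.0, p), method=method, n1=n1, n2=n2)


def ancova_group_effect(y, group, covariate) -> AncovaResult:
    """F test of a two-level group effect adjusted for a covariate.

    Fits ``y ~ 1 + group + covariate`` by least squares and tests the group
    term by the extra sum of squares against ``y ~ 1 + covariate`` with
    df (1, n - 3).  A residual sum of squares of (numerically) zero in the
    full model with a nonzero group effect is flagged as exact separation
    (F = inf, p = 0).
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    covariate = np.asarray(covariate, dtype=float)
    n = y.size
    if n < 4:
        raise ArgumentError("ANCOVA needs at least 4 subjects")
    levels = np.unique(group)
    if levels.size != 2:
        raise ArgumentError(f"group must have exactly 2 levels, got {levels.size}")
    if np.ptp(covariate) == 0:
        raise ArgumentError("covariate is constant")
    g = (group == levels[1]).astype(float)

    X_full = np.column_stack([np.ones(n), g, covariate])
    if np.linalg.matrix_rank(X_full) < 3:
        raise CollinearityError("group indicator is collinear with the covariate")
    full = sm.OLS(y, X_full).fit()
    X_red = np.column_stack([np.ones(n), covariate])
    reduced = sm.OLS(y, X_red).fit()

    df_resid = n - 3
    ssr_full = float(full.ssr)
    ssr_red = float(reduced.ssr)
    scale = float(np.sum(y**2)) + 1.0
    if ssr_full <= 1e-12 * scale:
        if ssr_red - ssr_full <= 1e-12 * scale:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssr_red - ssr_full) / (ssr_full / df_resid)
        p = float(sps.f.sf(f_stat, 1, df_resid))
    b0, b1, b2 = full.params
    return AncovaResult(
        F=float(f_stat),
        df_effect=1,
        df_residual=df_resid,
        p=p,
        intercept=float(b0),
        group_effect=float(b1),
        covariate_slope=float(b2),
    )


def compare_groups(indices: pd.DataFrame, assignment: GroupAssignment) -> dict:
    """Descriptives and Mann-Whitney result for each of the four indices.

    ``indices`` is the per-subject index table; every subject in it must be
    covered by the assignment.  Output is keyed by index name in the fixed
    reporting order L_AP, R_AP, A_LR, P_LR; within each comparison the
    first label's sample enters the test first (so Z < 0 means the first
    group tends lower).
    """
    subjects = list(indices["subject_id"])
    missing = [s for s in subjects if s not in assignment.assignment]
    if missing:
        raise AssignmentError(f"subjects not covered by assignment: {missing}")
    lab1, lab2 = assignment.labels
    out: dict[str, dict] = {}
    for name in INDEX_NAMES:
        by_sid = dict(zip(indices["subject_id"], indices[name]))
        x = [by_sid[s] for s in subjects if assignment.assignment[s] == lab1]
        y = [by_sid[s] for s in subjects if assignment.assignment[s] == lab2]
        out[name] = {
            "groups": {lab1: describe(x), lab2: describe(y)},
            "test": mann_whitney(x, y),
        }
    return out
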