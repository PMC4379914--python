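"""Group-comparison statistics for the behavioral assay.

The assay's analysis plan compares treatment arms with the
Mann–Whitney U test (P-sol and attraction index, which are far from
normal), the pooled two-sample Student t test (distance and movement
frequency between two arms), and one-way ANOVA followed by Tukey's HSD
(time-course designs).  The test statistics are computed from first
principles here; only the reference distributions (t, F, normal,
studentized range) come from :mod:`scipy.stats`.

Conventions: all p-values are two-sided.  The reported U is the smaller
of the pair (U, n1*n2 - U); both orientations are carried in
``TestResult.details``.  The U p-value is exact (full enumeration of
the null rank distribution) when ``n1*n2 <= 400`` and the data are
tie-free, otherwise a tie-corrected normal approximation with
continuity correction is used; the mode actually applied is recorded in
``method_detail``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "student_t",
    "one_way_anova",
    "tukey_hsd",
]


@dataclass(frozen=True)
class TestResult:
    """One group comparison: statistic, p-value and how they were obtained."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method_detail: str
    groups: tuple[str, ...] = ()
    details: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "method_detail": self.method_detail,
            "groups": list(self.groups),
            **{k: v for k, v in self.details.items()},
        }


@lru_cache(maxsize=256)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Exact null distribution of U: counts over u = 0..n1*n2.

    Classical recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u),
    i.e. enumeration of all C(n1+n2, n1) label assignments by rank.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_null_counts(n1 - 1, n2)  # largest a-value beats all of nothing extra
    b = _u_null_counts(n1, n2 - 1)
    size = n1 * n2 + 1
    out = [0] * size
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _u_exact_p(u: float, n1: int, n2: int) -> float:
    """Two-sided exact p: P(U at least as extreme as u) under the null."""
    counts = _u_null_counts(n1, n2)
    m = n1 * n2
    u_small = min(u, m - u)
    total = sum(counts)
    extreme = sum(c for v, c in enumerate(counts) if min(v, m - v) <= u_small + 1e-9)
    return extreme / total


def mann_whitney_u(a, b, mode: str = "auto") -> TestResult:
    """Mann–Whitney U test for two independent samples.

    U counts the pairs ``(a_i, b_j)`` with ``a_i < b_j`` plus half the
    tied pairs; the reported statistic is ``min(U, n1*n2 - U)``.
    ``mode`` is ``"auto"`` (exact when small and tie-free), ``"exact"``
    or ``"approx"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    less = np.sum(a[:, None] < b[None, :])
    ties = np.sum(a[:, None] == b[None, :])
    u = float(less) + 0.5 * float(ties)
    m = n1 * n2
    u_small, u_large = min(u, m - u), max(u, m - u)

    has_ties = ties > 0 or len(np.unique(np.concatenate([a, b]))) < n1 + n2
    if mode == "exact" or (mode == "auto" and m <= 400 and not has_ties):
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        p = _u_exact_p(u, n1, n2)
        detail = "exact enumeration"
    elif mode in ("auto", "approx"):
        pooled = np.concatenate([a, b])
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var = m / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = max(abs(u - m / 2.0) - 0.5, 0.0) / math.sqrt(var)
            p = min(2.0 * sps.norm.sf(z), 1.0)
        detail = "normal approximation, tie and continuity corrected"
    else:
        raise ValueError("mode must be 'auto', 'exact' or 'approx'")
    return TestResult(
        test_name="mann_whitney_u",
        statistic=u_small,
        p_value=float(p),
        n_per_group=(n1, n2),
        method_detail=detail,
        details={"U_small": u_small, "U_large": u_large, "n_tied_pairs": float(ties)},
    )


def student_t(a, b, equal_var: bool = True) -> TestResult:
    """Two-sample Student t test (pooled variance by default).

    With equal variances assumed the statistic uses the pooled standard
    deviation with ``n1 + n2 - 2`` degrees of freedom; ``equal_var=False``
    gives the Welch form.  Zero pooled variance is degenerate: equal
    means give t = 0, p = 1; unequal means give p = 0, both flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    m1, m2 = float(np.mean(a)), float(np.mean(b))
    v1, v2 = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        detail = f"pooled variance, df={df}"
    else:
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = math.sqrt(se2_1 + se2_2)
        df = (
            (se2_1 + se2_2) ** 2
            / (se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1))
            if se > 0
            else n1 + n2 - 2
        )
        detail = f"Welch, df={df:.2f}"
    if se == 0.0:
        if m1 == m2:
            return TestResult(
                "student_t", 0.0, 1.0, (n1, n2),
                detail + "; degenerate: zero variance, equal means",
                details={"df": df},
            )
        return TestResult(
            "student_t", math.copysign(math.inf, m1 - m2), 0.0, (n1, n2),
            detail + "; degenerate: zero variance, unequal means",
            details={"df": df},
        )
    t = (m1 - m2) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult("student_t", t, p, (n1, n2), detail, details={"df": df})


def _anova_tables(groups: Sequence[Sequence[float]]):
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in gs):
        raise ValueError("need n >= 2 per group")
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    N = int(ns.sum())
    grand = float(np.concatenate(gs).mean())
    means = np.array([g.mean() for g in gs])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in gs))
    return gs, k, ns, N, means, ss_between, ss_within


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    gs, k, ns, N, means, ssb, ssw = _anova_tables(groups)
    df_b, df_w = k - 1, N - k
    msb = ssb / df_b
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult(
                "one_way_anova", 0.0, 1.0, tuple(int(n) for n in ns),
                f"df=({df_b}, {df_w}); degenerate: all observations identical",
            )
        return TestResult(
            "one_way_anova", math.inf, 0.0, tuple(int(n) for n in ns),
            f"df=({df_b}, {df_w}); degenerate: zero within-group variance",
        )
    msw = ssw / df_w
    f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(
        "one_way_anova",
        f,
        p,
        tuple(int(n) for n in ns),
        f"df=({df_b}, {df_w})",
        details={"ss_between": ssb, "ss_within": ssw},
    )


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[TestResult]:
    """Tukey's HSD over all group pairs.

    Each pair's studentized-range statistic uses the common within-group
    mean square (Tukey–Kramer standard error for unbalanced pairs); the
    family-wise adjusted p comes from the studentized range distribution
    with k groups and the ANOVA residual degrees of freedom.
    """
    gs, k, ns, N, means, ssb, ssw = _anova_tables(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels must match the number of groups")
    df_w = N - k
    msw = ssw / df_w
    out: list[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(means[i] - means[j])
            se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j])) if msw > 0 else 0.0
            if se == 0.0:
                q = 0.0 if diff == 0.0 else math.inf
                p = 1.0 if diff == 0.0 else 0.0
                detail = f"k={k}, df={df_w}; degenerate: zero within-group variance"
            else:
                q = diff / se
                p = float(sps.studentized_range.sf(q, k, df_w))
                p = min(max(p, 0.0), 1.0)
                detail = f"k={k}, df={df_w}; studentized range"
            out.append(
                TestResult(
                    "tukey_hsd",
                    q,
                    p,
                    (int(ns[i]), int(ns[j])),
                    detail,
                    groups=(str(labels[i]), str(labels[j])),
                    details={"mean_difference": float(means[i] - means[j])},
                )
            )
    return out
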