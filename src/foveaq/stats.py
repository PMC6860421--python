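"""Descriptive statistics and the Bonferroni-corrected group comparisons.

The confirmatory analysis consists of four Mann-Whitney U tests — healthy
vs albinism FH and non-albinism FH vs albinism FH, for each of the two
quotients — carried out at the Bonferroni local level 5%/4 = 1.25%.  The
healthy vs non-albinism comparisons are exploratory and reported without a
significance gate.

Quantiles use linear interpolation between order statistics at positions
(n-1)p + 1; this is pinned because group medians are study endpoints and
the quantile definition would otherwise be a silent degree of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupDescription",
    "TestResult",
    "describe",
    "mann_whitney_u",
    "bonferroni_local_alpha",
    "run_hypotheses",
]


@dataclass(frozen=True)
class GroupDescription:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    single_value: bool = False


@dataclass(frozen=True)
class TestResult:
    hypothesis: str
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    local_alpha: float
    significant: bool
    confirmatory: bool
    n_a: int
    n_b: int
    mode: str
    degenerate: bool = False


def describe(values) -> GroupDescription:
    """Sample mean/SD (n-1 denominator) and median/quartiles."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot describe an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    single = x.size == 1
    sd = 0.0 if single else float(np.std(x, ddof=1))
    return GroupDescription(
        n=int(x.size),
        mean=float(x.mean()),
        sd=sd,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        single_value=single,
    )


def bonferroni_local_alpha(global_alpha: float, k: int) -> float:
    """Local significance level for k Bonferroni-corrected tests."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not (0.0 < global_alpha < 1.0):
        raise ValueError(f"global alpha must be in (0, 1), got {global_alpha}")
    return global_alpha / k


def mann_whitney_u(
    a,
    b,
    mode: str = "auto",
    local_alpha: float = 0.05,
    hypothesis: str = "",
    group_a: str = "A",
    group_b: str = "B",
    confirmatory: bool = True,
    exact_limit: int = 25,
) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``mode``: "exact" (full enumeration of the null distribution; requires
    no ties), "asymptotic" (tie-corrected normal approximation without
    continuity correction), or "auto" (exact when n_a + n_b <= ``exact_limit``
    and the data are tie-free, otherwise asymptotic).  U is the statistic of
    sample ``a`` computed from rank sums with midranks for ties.  If all
    values in both samples are identical the test is degenerate and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    if np.unique(pooled).size == 1:
        return TestResult(
            hypothesis, group_a, group_b,
            u_statistic=a.size * b.size / 2.0, p_value=1.0,
            local_alpha=local_alpha, significant=False, confirmatory=confirmatory,
            n_a=int(a.size), n_b=int(b.size), mode="degenerate", degenerate=True,
        )

    if mode == "auto":
        use = "exact" if (a.size + b.size <= exact_limit and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        use = mode
        if use == "exact" and has_ties:
            warnings.warn(
                "exact Mann-Whitney enumeration is not defined with ties; "
                "falling back to the tie-corrected normal approximation",
                stacklevel=2,
            )
            use = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if use == "exact" else "asymptotic",
        use_continuity=False,
    )
    p = float(min(res.pvalue, 1.0))
    return TestResult(
        hypothesis, group_a, group_b,
        u_statistic=float(res.statistic), p_value=p,
        local_alpha=local_alpha, significant=bool(p < local_alpha),
        confirmatory=confirmatory, n_a=int(a.size), n_b=int(b.size), mode=use,
    )


#: (hypothesis label, group A, group B, quotient kind, confirmatory)
_HYPOTHESES = [
    ("H1: healthy vs albinism FH, quotient I", "healthy", "albinism_fh", "I", True),
    ("H2: healthy vs albinism FH, quotient II", "healthy", "albinism_fh", "II", True),
    ("H3: non-albinism FH vs albinism FH, quotient I", "non_albinism_fh", "albinism_fh", "I", True),
    ("H4: non-albinism FH vs albinism FH, quotient II", "non_albinism_fh", "albinism_fh", "II", True),
    ("E1: healthy vs non-albinism FH, quotient I", "healthy", "non_albinism_fh", "I", False),
    ("E2: healthy vs non-albinism FH, quotient II", "healthy", "non_albinism_fh", "II", False),
]


def run_hypotheses(
    quotients: pd.DataFrame,
    layer: str = "gcl",
    global_alpha: float = 0.05,
    k: int = 4,
    mode: str = "auto",
) -> list[TestResult]:
    """The four confirmatory comparisons plus two exploratory ones.

    Confirmatory tests run at the Bonferroni local level ``global_alpha/k``;
    exploratory results carry local_alpha but are flagged non-confirmatory.
    """
    local = bonferroni_local_alpha(global_alpha, k)
    groups = set(quotients["group"].unique())
    required = {"healthy", "non_albinism_fh", "albinism_fh"}
    if not required <= groups:
        raise ValueError(f"missing groups: {sorted(required - groups)}")
    results = []
    for label, ga, gb, kind, confirmatory in _HYPOTHESES:
        col = f"{layer}_quotient_{kind}"
        va = quotients.loc[quotients["group"] == ga, col].to_numpy()
        vb = quotients.loc[quotients["group"] == gb, col].to_numpy()
        results.append(
            mann_whitney_u(
                va, vb, mode=mode, local_alpha=local, hypothesis=label,
                group_a=ga, group_b=gb, confirmatory=confirmatory,
            )
        )
    return results
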