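"""Two-group statistics: normality-routed comparison, mean +/- SEM
summaries, and immunoblot normalization arithmetic.

The comparison rule: assess normality per group (Shapiro-Wilk at
alpha = 0.05, both groups must pass); normally distributed groups are
compared with a two-tailed unpaired Student's t-test, otherwise with a
two-sided Mann-Whitney U test.  Every result records the route taken.

The Mann-Whitney p-value is exact — computed by exhaustive enumeration
of all rank assignments, ties included — whenever
``n_a + n_b <= EXACT_CUTOFF`` (12); above the cutoff the tie-corrected
normal approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "summarize",
    "mann_whitney_exact",
    "route_and_compare",
    "normalize_densitometry",
]

EXACT_CUTOFF = 12
NORMALITY_ALPHA = 0.05


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.values = self.values[np.isfinite(self.values)]
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} has no finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class SummaryStats:
    mean: float
    sem: float
    n: int
    sem_defined: bool


@dataclass
class ComparisonResult:
    test: str                    # "t-test" | "mann-whitney" | "degenerate"
    statistic: float
    p_value: float
    summary_a: SummaryStats
    summary_b: SummaryStats
    label_a: str
    label_b: str
    normal_a: bool | None = None
    normal_b: bool | None = None
    exact: bool | None = None


def summarize(values) -> SummaryStats:
    """Mean, SEM (sd / sqrt(n), n-1 denominator) and n.

    For n = 1 the SEM is undefined and flagged.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 1:
        raise ValueError("summarize needs >= 1 finite value")
    if v.size == 1:
        return SummaryStats(float(v[0]), np.nan, 1, False)
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
    return SummaryStats(float(np.mean(v)), sem, int(v.size), True)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of sample x vs y with midrank tie handling."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by exhaustive enumeration.

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled values to
    the two groups (valid under the null for ties as well) and returns
    (U of x, two-sided p) where p is the null probability of a U at
    least as extreme — as far from the null center n_a*n_b/2 — as
    observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, na = pooled.size, x.size
    u_obs = _u_statistic(x, y)
    center = na * y.size / 2.0
    dev = abs(u_obs - center)
    extreme = 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - center) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / comb(n, na)


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if values.size < 3 or np.ptp(values) == 0:
        # Shapiro-Wilk is undefined; treat as non-normal so the
        # comparison routes to the rank test
        return False
    return bool(sps.shapiro(values).pvalue > alpha)


def route_and_compare(
    a: GroupSample, b: GroupSample, alpha: float = NORMALITY_ALPHA
) -> ComparisonResult:
    """Compare two groups, routing on per-group normality.

    Both groups Shapiro-Wilk-normal at ``alpha`` -> two-tailed unpaired
    t-test; otherwise two-sided Mann-Whitney U (exact below the
    enumeration cutoff).  Identical constant groups short-circuit to a
    degenerate result with p = 1.
    """
    sa, sb = summarize(a.values), summarize(b.values)
    pooled = np.concatenate([a.values, b.values])
    if np.ptp(pooled) == 0:
        return ComparisonResult("degenerate", 0.0, 1.0, sa, sb,
                                a.label, b.label)
    norm_a = _is_normal(a.values, alpha)
    norm_b = _is_normal(b.values, alpha)
    if norm_a and norm_b and a.n >= 2 and b.n >= 2:
        t, p = sps.ttest_ind(a.values, b.values, equal_var=True)
        return ComparisonResult("t-test", float(t), float(p), sa, sb,
                                a.label, b.label, norm_a, norm_b)
    if a.n + b.n <= EXACT_CUTOFF:
        u, p = mann_whitney_exact(a.values, b.values)
        exact = True
    else:
        u, p = sps.mannwhitneyu(a.values, b.values, alternative="two-sided",
                                method="asymptotic")
        u, p = float(u), float(p)
        exact = False
    return ComparisonResult("mann-whitney", u, p, sa, sb,
                            a.label, b.label, norm_a, norm_b, exact)


def normalize_densitometry(
    samples, loading_control, control_mask
) -> np.ndarray:
    """Immunoblot normalization: each lane's integrated density is
    divided by its loading-control (tubulin) density, and the ratios are
    then divided by the mean ratio of the control lanes.

    Lanes with zero loading-control density are excluded (NaN in the
    output) with a warning.  The control-group mean of the output is
    exactly 1.
    """
    import warnings

    d = np.asarray(samples, dtype=float)
    t = np.asarray(loading_control, dtype=float)
    mask = np.asarray(control_mask, dtype=bool)
    if d.shape != t.shape or d.shape != mask.shape:
        raise ValueError("samples, loading_control and control_mask must "
                         "have equal length")
    if not mask.any():
        raise ValueError("control group is empty")
    bad = t == 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} lane(s) with zero loading-control "
            "density", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(bad, np.nan, d / t)
    ctrl_mean = np.nanmean(r[mask])
    return r / ctrl_mean
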