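"""Group and nested-model statistics for gating-parameter comparisons.

Values are summarized as mean +/- SEM with n; group comparisons use
unpaired t-tests or one-way ANOVA with Bonferroni-adjusted pairwise
post-hoc tests (adjusted p = raw p x number of pairs, capped at 1); nested
curve-fit models are compared with the extra sum-of-squares F-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sstats


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class FTestResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class Summary:
    mean: float
    sem: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sem:.2f} (n={self.n})"


@dataclass(frozen=True)
class PairComparison:
    group_a: str
    group_b: str
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparison:
    method: str
    omnibus_F: float | None
    omnibus_p: float | None
    pairs: tuple[PairComparison, ...]


def ess_f_test(ss_reduced: float, df_reduced: int, ss_full: float, df_full: int) -> FTestResult:
    """Extra sum-of-squares F-test between nested least-squares fits.

    F = ((SS_r - SS_f) / (df_r - df_f)) / (SS_f / df_f), with the p-value
    from the F distribution (incomplete-beta tail).
    """
    if df_reduced <= df_full:
        raise StatsError("reduced model must have more residual degrees of freedom")
    if df_full <= 0:
        raise StatsError("full model needs positive residual degrees of freedom")
    if ss_reduced < ss_full - 1e-12 * max(ss_full, 1.0):
        raise StatsError("reduced-model SS cannot be below full-model SS")
    df_num = df_reduced - df_full
    extra = max(ss_reduced - ss_full, 0.0)
    if ss_full == 0.0:
        f = 0.0 if extra == 0.0 else float("inf")
    else:
        f = (extra / df_num) / (ss_full / df_full)
    p = float(sstats.f.sf(f, df_num, df_full)) if np.isfinite(f) else 0.0
    return FTestResult(F=float(f), df_num=df_num, df_den=df_full, p=p)


def summarize(values) -> Summary:
    """Mean +/- SEM (sd/sqrt(n), sample sd) with the number of experiments."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise StatsError("need at least one value")
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return Summary(mean=float(x.mean()), sem=sem, n=int(x.size))


def t_test(a, b) -> float:
    """Two-sided unpaired Student's t-test p-value."""
    return float(sstats.ttest_ind(np.asarray(a, float), np.asarray(b, float)).pvalue)


def anova_bonferroni(groups: dict[str, "np.ndarray"]) -> GroupComparison:
    """One-way ANOVA followed by Bonferroni-adjusted pairwise t-tests."""
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise StatsError(f"group {k!r} needs n >= 2")
    if all(v.std(ddof=1) == 0 for v in arrays.values()):
        raise StatsError("zero within-group variance in every group")

    names = list(arrays)
    f, p = sstats.f_oneway(*arrays.values())
    m = len(names) * (len(names) - 1) // 2
    pairs = []
    for a, b in combinations(names, 2):
        praw = t_test(arrays[a], arrays[b])
        pairs.append(
            PairComparison(a, b, p_raw=praw, p_adjusted=min(praw * m, 1.0))
        )
    return GroupComparison(
        method="anova_bonferroni",
        omnibus_F=float(f),
        omnibus_p=float(p),
        pairs=tuple(pairs),
    )
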