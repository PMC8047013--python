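"""Group summaries and the non-delegated statistics: Welch/pooled t tests,
Spearman rank correlation, and mean +/- SEM reporting tables.

Repeated-measures ANOVA and post-hoc comparisons are deliberately not
reimplemented here; :func:`summarize_groups` and the CLI export tidy
long-format tables ready for standard statistics environments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "two_sample_t", "spearman_rank", "summarize_groups"]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float          # sd / sqrt(n); NaN for n = 1
    median: float


def two_sample_t(a, b, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t test; Welch (unequal variance) by default.

    Returns (t, df, p). Set ``equal_var=True`` for the pooled-variance test.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both samples are constant with different means; t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Exact two-sided permutation p for Spearman r (midrank ties respected)."""
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    rs = (ry_c[perms] * rx_c).sum(axis=1) / denom
    return float(np.mean(np.abs(rs) >= abs(r_obs) - 1e-12))


def spearman_rank(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    The p value is an exact permutation p for n < 10 and the asymptotic
    t-approximation otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input; rank correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if len(x) < 10:
        p = _spearman_exact_p(rx, ry, r)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return r, p


def summarize_groups(values_by_group: dict[str, "np.ndarray | list"]) -> pd.DataFrame:
    """Mean +/- SEM and median per group, mirroring the reporting convention.

    Single-value groups get SEM = NaN (reported as NA, not zero).
    """
    rows = []
    for label, vals in values_by_group.items():
        v = np.asarray(vals, dtype=np.float64)
        if v.size < 1:
            raise ValueError(f"group {label!r} is empty")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append(GroupSummary(label=str(label), n=int(v.size), mean=float(v.mean()),
                                 sem=sem, median=float(np.median(v))))
    return pd.DataFrame([r.__dict__ for r in rows])
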