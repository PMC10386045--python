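"""Statistical battery for ROI tables.

Covers the analysis applied to region-mean AACID values: Shapiro-Wilk
normality screening, two-way fully-within repeated-measures ANOVA with the
Greenhouse-Geisser sphericity correction, Tukey post-hoc comparisons on the
studentized-range distribution with multiplicity-adjusted p-values, a
paired t-test for tumor volumes, and the conventional star annotation.

The RM ANOVA uses the univariate within-subject decomposition: every fixed
effect (side, time, side×time) is tested against its own subject-interaction
error term.  Greenhouse-Geisser epsilon is the standard sample estimator
computed from orthonormal contrasts C of the effect: with S the subject-level
covariance of the effect's cell vectors and M = C S Cᵀ,

    ε̂ = tr(M)² / (d · tr(M²)),   d = rank(C),

clipped to [1/d, 1]; ε̂ = 1 exactly for two-level factors.  Sphericity is
never assumed: the correction is always applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "shapiro_wilk",
    "rm_anova_gg",
    "tukey_posthoc",
    "paired_t",
    "significance_stars",
]


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p-value."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    p_adjusted: float | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adjusted if self.p_adjusted is not None else self.p)


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk normality test (3 ≤ n ≤ 5000, non-constant input)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = sps.shapiro(x)
    return TestResult(name="shapiro_wilk", statistic=float(w), df=(float(x.size),), p=float(p))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1)×k orthonormal rows spanning the complement of the unit vector."""
    h, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))
    return h[:, 1:].T


def _gg_epsilon(subject_vectors: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser ε̂ from per-subject cell vectors and effect contrasts."""
    d = contrasts.shape[0]
    if d == 1:
        return 1.0
    s_cov = np.cov(subject_vectors, rowvar=False, ddof=1)
    m = contrasts @ s_cov @ contrasts.T
    eps = np.trace(m) ** 2 / (d * np.trace(m @ m))
    return float(np.clip(eps, 1.0 / d, 1.0))


def _pivot(table: pd.DataFrame, dv: str, subject: str, within: tuple[str, str]) -> np.ndarray:
    """Cell array Y[subject, A level, B level]; errors on missing/dup cells."""
    a, b = within
    counts = table.groupby([subject, a, b], observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("design must be balanced and complete with one value per cell")
    subs = sorted(table[subject].unique())
    if len(subs) < 2:
        raise ValueError("repeated-measures ANOVA needs at least two subjects")
    la, lb = sorted(table[a].unique()), sorted(table[b].unique())
    wide = table.pivot_table(index=subject, columns=[a, b], values=dv, observed=True)
    cols = pd.MultiIndex.from_product([la, lb])
    if set(cols) != set(wide.columns):
        raise ValueError("missing cells in the design")
    return wide.reindex(index=subs, columns=cols).to_numpy().reshape(len(subs), len(la), len(lb))


def rm_anova_gg(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: tuple[str, str] = ("side", "time"),
) -> dict[str, TestResult]:
    """Two-way fully repeated-measures ANOVA with GG-corrected p-values.

    Returns results keyed by effect: the two within factors and their
    interaction, each tested against its own subject-interaction error term
    with Greenhouse-Geisser-scaled degrees of freedom.
    """
    y = _pivot(table, dv, subject, within)
    n, p, q = y.shape

    grand = y.mean()
    mean_s = y.mean(axis=(1, 2))
    mean_a = y.mean(axis=(0, 2))
    mean_b = y.mean(axis=(0, 1))
    mean_ab = y.mean(axis=0)
    mean_sa = y.mean(axis=2)
    mean_sb = y.mean(axis=1)

    ss_a = n * q * np.sum((mean_a - grand) ** 2)
    ss_b = n * p * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_as = q * np.sum((mean_sa - mean_s[:, None] - mean_a[None, :] + grand) ** 2)
    ss_bs = p * np.sum((mean_sb - mean_s[:, None] - mean_b[None, :] + grand) ** 2)
    resid = (
        y
        - mean_sa[:, :, None]
        - mean_sb[:, None, :]
        - mean_ab[None, :, :]
        + mean_s[:, None, None]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        - grand
    )
    ss_abs = np.sum(resid**2)

    ca, cb = _orthonormal_contrasts(p), _orthonormal_contrasts(q)
    eff = {
        within[0]: (ss_a, p - 1, ss_as, (p - 1) * (n - 1), y.mean(axis=2), ca),
        within[1]: (ss_b, q - 1, ss_bs, (q - 1) * (n - 1), y.mean(axis=1), cb),
        f"{within[0]}*{within[1]}": (
            ss_ab,
            (p - 1) * (q - 1),
            ss_abs,
            (p - 1) * (q - 1) * (n - 1),
            y.reshape(n, p * q),
            np.kron(ca, cb),
        ),
    }
    out: dict[str, TestResult] = {}
    for name, (ss, df1, ss_err, df2, vecs, contrasts) in eff.items():
        if df2 <= 0:
            raise ValueError("not enough subjects for this design")
        f_stat = (ss / df1) / (ss_err / df2)
        eps = _gg_epsilon(vecs, contrasts)
        p_gg = float(sps.f.sf(f_stat, eps * df1, eps * df2))
        out[name] = TestResult(
            name=f"rm_anova[{name}]",
            statistic=float(f_stat),
            df=(float(df1), float(df2)),
            p=p_gg,
            epsilon=eps,
        )
    return out


def tukey_posthoc(
    table: pd.DataFrame,
    factor: str = "time",
    dv: str = "value",
    subject: str = "subject",
) -> list[TestResult]:
    """All pairwise level comparisons of a within-subject factor.

    Other columns are averaged per subject first.  Each pair is tested with
    the studentized-range statistic q = |m̄ᵢ − m̄ⱼ| / √(MS_err/n), where
    MS_err is the factor×subject interaction mean square, giving the
    multiplicity-adjusted p directly from the range distribution with k
    levels.  With k = 2 this reduces to the paired comparison (q = √2·|t|).
    """
    levels = sorted(table[factor].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("post-hoc comparisons need at least 2 levels")
    wide = table.pivot_table(index=subject, columns=factor, values=dv, observed=True)
    if wide.isna().any().any():
        raise ValueError("design must be complete")
    x = wide.reindex(columns=levels).to_numpy()
    n = x.shape[0]
    grand = x.mean()
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    df_err = (k - 1) * (n - 1)
    ms_err = np.sum(resid**2) / df_err
    means = x.mean(axis=0)
    out = []
    for i, j in combinations(range(k), 2):
        q = abs(means[i] - means[j]) / np.sqrt(ms_err / n)
        p_adj = float(sps.studentized_range.sf(q, k, df_err))
        p_adj = min(max(p_adj, 0.0), 1.0)
        out.append(
            TestResult(
                name=f"tukey[{levels[i]} vs {levels[j]}]",
                statistic=float(q),
                df=(float(k), float(df_err)),
                p=p_adj,
                p_adjusted=p_adj,
            )
        )
    return out


def paired_t(values_a, values_b) -> TestResult:
    """Two-sided paired t-test (textbook formula on the differences)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired t-test undefined for zero-variance differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return TestResult(name="paired_t", statistic=float(t), df=(float(n - 1),), p=p)


def significance_stars(p: float) -> str:
    """Conventional annotation: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
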