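"""Behavioral and brain-behavior statistics.

Repeated-measures ANOVA with Greenhouse-Geisser correction, planned
paired contrasts with Cohen's dz, high/low-suppression subgrouping,
Spearman brain-behavior correlations, the Meng-Rosenthal-Rubin test for
dependent correlations, and exact noncentral-t power for paired designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from sklearn.cluster import KMeans


@dataclass
class StatResult:
    """One statistical test: statistic, (possibly fractional) df, p, effect size."""

    name: str
    value: float
    df: float
    p: float
    effect_size: float | None = None
    df2: float | None = None
    tails: int = 2

    def __str__(self) -> str:  # compact report line
        dfs = f"{self.df:g}" if self.df2 is None else f"{self.df:g}, {self.df2:g}"
        es = "" if self.effect_size is None else f", es = {self.effect_size:.3f}"
        return f"{self.name}({dfs}) = {self.value:.3f}, p = {self.p:.4f}{es}"


def rm_anova_gg(scores) -> StatResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``scores`` is participants x conditions (array or wide DataFrame).
    Returns the F statistic with GG-corrected degrees of freedom and
    p-value, and partial eta squared as effect size.
    """
    x = np.asarray(scores, dtype=float)
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 participants")
    if np.allclose(x - x.mean(axis=1, keepdims=True), (x - x.mean(axis=1, keepdims=True))[0]):
        raise ValueError("zero error variance: ANOVA undefined")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.arange(k), n),
            "score": x.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="score", within="condition", subject="subject",
        correction=True, detailed=True, effsize="np2",
    )
    aov = aov.rename(columns=lambda c: c.replace("-", "_"))
    row = aov.iloc[0]
    eps = float(row["eps"])
    p_gg = row["p_GG_corr"] if "p_GG_corr" in aov.columns else np.nan
    p = float(p_gg) if np.isfinite(p_gg) else float(row["p_unc"])
    return StatResult(
        name="F",
        value=float(row["F"]),
        df=eps * (k - 1),
        df2=eps * (k - 1) * (n - 1),
        p=p,
        effect_size=float(row["np2"]),
    )


def paired_t_dz(a, b, tails: int = 2) -> StatResult:
    """Paired t-test with Cohen's dz (= mean diff / SD of diffs = t / sqrt(n)).

    ``tails=1`` tests the positive direction of ``a - b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return StatResult("t", 0.0, len(a) - 1, 1.0, 0.0, tails=tails)
        raise ValueError("zero-variance nonzero differences: dz unbounded")
    n = len(a)
    t = diff.mean() / (sd / np.sqrt(n))
    if tails == 2:
        p = 2 * stats.t.sf(abs(t), n - 1)
    else:
        p = stats.t.sf(t, n - 1)
    return StatResult("t", float(t), n - 1, float(p), float(diff.mean() / sd), tails=tails)


def split_groups(forgetting_scores, method: str = "median", ids=None) -> np.ndarray:
    """High/low-suppression grouping (1 = high suppression, 0 = low).

    ``median``: rank by score (ties and odd n broken by participant id,
    first half = low).  ``kmeans2``: 1-D k-means with k = 2, deterministic
    multi-start; the cluster with the larger mean is "high".
    """
    scores = np.asarray(forgetting_scores, dtype=float)
    n = len(scores)
    if n < 4:
        raise ValueError("need at least 4 participants")
    if np.ptp(scores) == 0:
        raise ValueError("all scores identical: no split possible")
    ids = np.arange(n) if ids is None else np.asarray(ids)
    if method == "median":
        order = np.lexsort((ids, scores))  # score first, id breaks ties
        labels = np.zeros(n, dtype=int)
        labels[order[n // 2:]] = 1
        return labels
    if method == "kmeans2":
        km = KMeans(n_clusters=2, n_init=10, random_state=0)
        lab = km.fit_predict(scores[:, None])
        high = int(np.argmax(km.cluster_centers_.ravel()))
        return (lab == high).astype(int)
    raise ValueError("method must be 'median' or 'kmeans2'")


def normalize_memory(score, baseline):
    """Baseline-proportional memory: (score - baseline) / baseline.

    A zero baseline yields NaN (flagged missing) rather than an error.
    """
    score = np.asarray(score, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    out = np.where(baseline == 0, np.nan, (score - baseline) / np.where(baseline == 0, 1, baseline))
    return out


def spearman_brainbehavior(
    decoding_metric, behavior, baseline=None, tails: int = 2
) -> StatResult:
    """Spearman correlation between a decoding summary and behavior.

    If ``baseline`` is given, behavior is first normalized to
    ``(behavior - baseline) / baseline``.  NaNs (e.g. from a zero
    baseline) are dropped pairwise.
    """
    x = np.asarray(decoding_metric, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if baseline is not None:
        y = normalize_memory(y, baseline)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    alt = "two-sided" if tails == 2 else "greater"
    res = stats.spearmanr(x, y, alternative=alt)
    return StatResult(
        "rho", float(res.statistic), len(x) - 2, float(res.pvalue), tails=tails
    )


def compare_dependent_correlations(r1: float, r2: float, r_between: float, n: int) -> StatResult:
    """Meng-Rosenthal-Rubin z-test for two correlations sharing a variable.

    Tests r(x, y1) against r(x, y2) given r(y1, y2) = ``r_between``,
    two-sided.  Antisymmetric in (r1, r2).
    """
    for r in (r1, r2, r_between):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    r2bar = (r1**2 + r2**2) / 2.0
    f = min((1.0 - r_between) / (2.0 * (1.0 - r2bar)), 1.0)
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r_between) * h))
    p = 2 * stats.norm.sf(abs(z))
    return StatResult("z", float(z), np.inf, float(p))


def power_paired_t(n: int, dz: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of a one-sample/paired t-test via the noncentral t.

    ``dz`` is the within-subject effect size; noncentrality is
    ``dz * sqrt(n)``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 1
    ncp = dz * np.sqrt(n)
    if tails == 2:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def forgetting_scores(behavior: pd.DataFrame, measure: str = "detail") -> pd.Series:
    """Baseline-minus-No-Think score per participant (higher = more forgetting)."""
    wide = behavior.pivot(index="participant", columns="condition", values=measure)
    return wide["Baseline"] - wide["NoThink"]
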