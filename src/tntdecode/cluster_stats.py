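"""Nonparametric cluster-based Monte-Carlo inference.

Pointwise t-statistics are thresholded at the cluster-forming alpha,
contiguous exceedances (in time, on the time-frequency grid, or over the
channel neighbor graph) are grouped into clusters, and each observed
cluster's summed-t mass is compared against the distribution of the
maximum null cluster mass over label permutations.  Three null
constructions are provided, matching how the decoding results were
obtained:

* *vs chance*: each participant's trial-level classification records are
  re-assigned to random classes (the classifier "knows nothing"), and the
  accuracies recomputed — a one-tailed test against the chance level;
* *condition difference*: condition labels are shuffled across the pooled
  trial records of the two conditions within participant — two-tailed,
  with separate positive/negative cluster nulls (critical values at the
  2.5% / 97.5% points);
* *group difference*: group membership is shuffled across participants —
  two-tailed independent t.

A fourth scheme handles correlation timecourses: Spearman's rho is
transformed to t and the pairing between the two variables is permuted.
Permutation p-values use the (b + 1) / (m + 1) convention so p is never
exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_WINDOW = (0.0, 3000.0)  # statistics restricted to the task period


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def form_clusters(stat_values: np.ndarray, threshold: float, adjacency="1d"):
    """Group supra-threshold elements into contiguous clusters.

    ``adjacency`` is ``"1d"`` (a time axis), ``"grid"`` (a 2-D
    time-frequency matrix, 4-connectivity) or an (n, n) boolean adjacency
    matrix (channel graph).  Returns a list of ``(indices, mass)`` with
    mass the sum of member statistic values; only positive exceedances
    (``stat > threshold``) are grouped — pass ``-stat`` for the negative
    tail.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    stat_values = np.asarray(stat_values, dtype=float)
    mask = stat_values > threshold
    if not mask.any():
        return []
    clusters = []
    if isinstance(adjacency, str) and adjacency == "1d":
        lab, n = ndimage.label(mask)
        for k in range(1, n + 1):
            idx = np.flatnonzero(lab == k)
            clusters.append((idx, float(stat_values[idx].sum())))
    elif isinstance(adjacency, str) and adjacency == "grid":
        lab, n = ndimage.label(mask)  # cross-shaped structuring element
        for k in range(1, n + 1):
            idx = np.argwhere(lab == k)
            clusters.append((idx, float(stat_values[lab == k].sum())))
    else:
        adj = np.asarray(adjacency, dtype=bool)
        nodes = np.flatnonzero(mask)
        sub = adj[np.ix_(nodes, nodes)]
        n_comp, lab = connected_components(csr_matrix(sub), directed=False)
        for k in range(n_comp):
            idx = nodes[lab == k]
            clusters.append((idx, float(stat_values[idx].sum())))
    return clusters


@dataclass
class Cluster:
    indices: np.ndarray
    mass: float
    p: float
    sign: int  # +1 / -1 tail


@dataclass
class ClusterTestResult:
    """Observed clusters, their corrected p-values, and the permutation null."""

    clusters: list[Cluster]
    null_pos: np.ndarray
    null_neg: np.ndarray | None
    tails: int
    n_permutations: int
    cluster_alpha: float
    threshold: float
    times: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]

    def any_significant(self, alpha: float = 0.05) -> bool:
        return len(self.significant(alpha)) > 0

    def significant_mask(self, n: int | None = None, alpha: float = 0.05) -> np.ndarray:
        """Boolean mask (over the tested axis) of significant cluster members."""
        if n is None:
            n = len(self.times)
        mask = np.zeros(n, dtype=bool)
        for c in self.significant(alpha):
            mask[np.asarray(c.indices).ravel()] = True
        return mask


# ---------------------------------------------------------------------------
# generic permutation machinery
# ---------------------------------------------------------------------------

def _perm_p(null: np.ndarray, observed: float) -> float:
    return float((np.sum(null >= observed) + 1.0) / (len(null) + 1.0))


def _run_cluster_test(
    observed_stat,
    null_iter,
    threshold,
    adjacency,
    tails,
    n_perm,
    cluster_alpha,
    times=None,
    rank_matched=False,
):
    """Shared core: form observed clusters, collect null masses, assign p.

    ``null_iter`` yields one permuted statistic map per draw.  For
    ``rank_matched`` (2-D maps) the k-th largest observed mass is compared
    with the null distribution of k-th largest masses; otherwise the
    classical max-mass null is used.
    """
    pos = form_clusters(observed_stat, threshold, adjacency)
    neg = form_clusters(-np.asarray(observed_stat), threshold, adjacency) if tails == 2 else []
    k_pos, k_neg = max(len(pos), 1), max(len(neg), 1)
    null_pos = np.zeros((n_perm, k_pos))
    null_neg = np.zeros((n_perm, k_neg)) if tails == 2 else None

    def _top(masses, k):
        m = sorted(masses, reverse=True)[:k]
        return np.pad(m, (0, k - len(m)))

    for b, stat_b in enumerate(null_iter):
        if b >= n_perm:
            break
        masses = [m for _, m in form_clusters(stat_b, threshold, adjacency)]
        null_pos[b] = _top(masses, k_pos)
        if tails == 2:
            masses_n = [m for _, m in form_clusters(-np.asarray(stat_b), threshold, adjacency)]
            null_neg[b] = _top(masses_n, k_neg)

    # For two-tailed tests each tail's null is evaluated at alpha/2
    # (critical values at the 2.5% / 97.5% points), reported as a
    # two-sided p = 2 x tail p so that p <= alpha means significance.
    side = 2.0 if tails == 2 else 1.0
    clusters = []
    for rank, (idx, mass) in enumerate(
        sorted(pos, key=lambda c: -c[1])
    ):
        col = rank if rank_matched else 0
        p = min(1.0, side * _perm_p(null_pos[:, col], mass))
        clusters.append(Cluster(idx, mass, p, +1))
    for rank, (idx, mass) in enumerate(sorted(neg, key=lambda c: -c[1])):
        col = rank if rank_matched else 0
        p = min(1.0, side * _perm_p(null_neg[:, col], mass))
        clusters.append(Cluster(idx, -mass, p, -1))
    return ClusterTestResult(
        clusters=clusters,
        null_pos=null_pos[:, 0] if not rank_matched else null_pos,
        null_neg=(None if tails == 1 else (null_neg[:, 0] if not rank_matched else null_neg)),
        tails=tails,
        n_permutations=n_perm,
        cluster_alpha=cluster_alpha,
        threshold=threshold,
        times=times,
    )


def one_sample_t(x: np.ndarray, popmean: float = 0.0) -> np.ndarray:
    """Vectorized one-sample t over axis 0."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return (x.mean(axis=0) - popmean) / (sd / np.sqrt(n))


def independent_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance two-sample t over axis 0."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    sp = np.where(sp == 0, np.inf, sp)
    return (a.mean(axis=0) - b.mean(axis=0)) / (sp * np.sqrt(1.0 / na + 1.0 / nb))


# ---------------------------------------------------------------------------
# accuracy extraction from decoding records
# ---------------------------------------------------------------------------

def _window_mask(times, window):
    return (times >= window[0]) & (times < window[1])


def _correct_matrices(results, window):
    """Per participant: boolean (n_timepoints_in_window, n_units) correctness."""
    times = results[0].times
    mask = _window_mask(times, window) if window is not None else np.ones(len(times), bool)
    if not mask.any():
        raise ValueError(f"no decoding timepoints inside window {window}")
    mats = []
    for r in results:
        if not np.array_equal(r.times, times):
            raise ValueError("decoding results have mismatched time axes")
        if r.pred is None:
            raise ValueError("trial-level records missing from DecodingResult")
        mats.append((r.pred[mask] == r.true[None, :], r.true, r.pred[mask]))
    return times[mask], mats


# ---------------------------------------------------------------------------
# the three decoding nulls + correlation clustering
# ---------------------------------------------------------------------------

def perm_test_vs_chance(
    results,
    chance: float | None = None,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    window=DEFAULT_WINDOW,
    seed=None,
) -> ClusterTestResult:
    """One-tailed cluster test of decoding accuracy against chance.

    ``results`` is one :class:`~tntdecode.decoding.DecodingResult` per
    participant.  The null re-assigns each participant's trial-level
    classification records to random classes (permuting the true labels
    against the fixed predictions) and recomputes the accuracies.
    """
    rng = np.random.default_rng(seed)
    chance = results[0].chance if chance is None else chance
    times, mats = _correct_matrices(results, window)
    n_sub = len(results)
    acc = np.stack([c.mean(axis=1) for c, _, _ in mats])
    threshold = stats.t.ppf(1 - cluster_alpha, df=n_sub - 1)
    observed = one_sample_t(acc, popmean=chance)

    def nulls():
        for _ in range(n_perm):
            acc_b = np.empty_like(acc)
            for p, (_, true, pred) in enumerate(mats):
                perm_true = rng.permutation(true)
                acc_b[p] = (pred == perm_true[None, :]).mean(axis=1)
            yield one_sample_t(acc_b, popmean=chance)

    return _run_cluster_test(
        observed, nulls(), threshold, "1d", 1, n_perm, cluster_alpha, times
    )


def perm_test_condition_diff(
    results_a,
    results_b,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    window=DEFAULT_WINDOW,
    seed=None,
) -> ClusterTestResult:
    """Two-tailed paired cluster test between two decoding conditions.

    The null randomly re-assigns condition labels to the pooled trial
    records within each participant; positive and negative clusters get
    separate null distributions (critical values at 97.5% / 2.5%).
    """
    if len(results_a) != len(results_b):
        raise ValueError("conditions must be paired within participants")
    rng = np.random.default_rng(seed)
    times, mats_a = _correct_matrices(results_a, window)
    _, mats_b = _correct_matrices(results_b, window)
    n_sub = len(results_a)
    acc_a = np.stack([c.mean(axis=1) for c, _, _ in mats_a])
    acc_b = np.stack([c.mean(axis=1) for c, _, _ in mats_b])
    threshold = stats.t.ppf(1 - cluster_alpha / 2, df=n_sub - 1)
    observed = one_sample_t(acc_a - acc_b)
    pooled = [
        np.concatenate([ca, cb], axis=1)
        for (ca, _, _), (cb, _, _) in zip(mats_a, mats_b)
    ]
    n_a = [c.shape[1] for c, _, _ in mats_a]

    def nulls():
        for _ in range(n_perm):
            diff = np.empty_like(acc_a)
            for p, pool in enumerate(pooled):
                sel = rng.permutation(pool.shape[1])
                diff[p] = (
                    pool[:, sel[: n_a[p]]].mean(axis=1)
                    - pool[:, sel[n_a[p]:]].mean(axis=1)
                )
            yield one_sample_t(diff)

    return _run_cluster_test(
        observed, nulls(), threshold, "1d", 2, n_perm, cluster_alpha, times
    )


def perm_test_group_diff(
    results,
    group_labels,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    window=DEFAULT_WINDOW,
    seed=None,
) -> ClusterTestResult:
    """Two-tailed independent-samples cluster test between two groups.

    ``group_labels`` holds exactly two distinct values; the null shuffles
    group membership across participants (group sizes preserved).
    Accepts DecodingResults or a precomputed (participants, timepoints)
    accuracy array (then ``window`` must be None or times unknown).
    """
    rng = np.random.default_rng(seed)
    group_labels = np.asarray(group_labels)
    levels = np.unique(group_labels)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if np.min([(group_labels == g).sum() for g in levels]) < 2:
        raise ValueError("each group needs at least 2 participants")
    if isinstance(results, np.ndarray):
        acc, times = results, None
    else:
        times, mats = _correct_matrices(results, window)
        acc = np.stack([c.mean(axis=1) for c, _, _ in mats])
    ga = group_labels == levels[0]
    df = acc.shape[0] - 2
    threshold = stats.t.ppf(1 - cluster_alpha / 2, df=df)
    observed = independent_t(acc[ga], acc[~ga])

    def nulls():
        for _ in range(n_perm):
            sel = rng.permutation(acc.shape[0])[: ga.sum()]
            m = np.zeros(acc.shape[0], dtype=bool)
            m[sel] = True
            yield independent_t(acc[m], acc[~m])

    return _run_cluster_test(
        observed, nulls(), threshold, "1d", 2, n_perm, cluster_alpha, times
    )


def rho_to_t(rho: np.ndarray, n: int) -> np.ndarray:
    """Spearman rho to t: ``t = rho * sqrt((n - 2) / (1 - rho^2))``.

    |rho| = 1 would be infinite and is capped (with a warning).
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho) >= 1.0):
        warnings.warn("|rho| = 1 capped for the t transform", stacklevel=2)
        rho = np.clip(rho, -1.0 + 1e-12, 1.0 - 1e-12)
    return rho * np.sqrt((n - 2) / (1.0 - rho**2))


def _spearman_timecourse(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of y against each column of x; x is (P, T), y is (P,)."""
    rx = stats.rankdata(x, axis=0)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    denom = np.where(denom == 0, np.inf, denom)
    return (rx * ry[:, None]).sum(axis=0) / denom


def corr_cluster_timecourse(
    x_timecourse: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    times: np.ndarray | None = None,
    seed=None,
) -> ClusterTestResult:
    """Cluster-corrected Spearman correlation timecourse.

    ``x_timecourse`` is (participants, timepoints), ``y`` one value per
    participant.  Rho is transformed to t per timepoint, clustered on
    both tails, and compared against a null that permutes the pairing of
    the two variables across participants.
    """
    x = np.asarray(x_timecourse, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 participants")
    rng = np.random.default_rng(seed)
    threshold = stats.t.ppf(1 - cluster_alpha / 2, df=n - 2)
    observed = rho_to_t(_spearman_timecourse(x, y), n)

    def nulls():
        for _ in range(n_perm):
            yield rho_to_t(_spearman_timecourse(x, rng.permutation(y)), n)

    return _run_cluster_test(
        observed, nulls(), threshold, "1d", 2, n_perm, cluster_alpha, times
    )


# ---------------------------------------------------------------------------
# spatial (channel-graph) paired test, and 2-D time-frequency test
# ---------------------------------------------------------------------------

def perm_test_paired_maps(
    diffs: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed=None,
) -> ClusterTestResult:
    """Two-tailed paired test of per-channel differences with graph clusters.

    ``diffs`` is (participants, channels); the null flips each
    participant's condition assignment (sign of the difference).
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    rng = np.random.default_rng(seed)
    threshold = stats.t.ppf(1 - cluster_alpha / 2, df=n - 1)
    observed = one_sample_t(diffs)

    def nulls():
        for _ in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)
            yield one_sample_t(diffs * signs[:, None])

    return _run_cluster_test(
        observed, nulls(), threshold, adjacency, 2, n_perm, cluster_alpha
    )


def perm_test_tf_vs_chance(
    tf_results,
    chance: float | None = None,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    window=DEFAULT_WINDOW,
    seed=None,
) -> ClusterTestResult:
    """One-tailed cluster test of a time-frequency accuracy map vs chance.

    ``tf_results`` is one TimeFrequencyDecoding per participant; clusters
    form on the 2-D frequency x time grid and observed clusters are
    compared with null clusters of the same rank (k-th largest observed
    mass against the distribution of k-th largest null masses).
    """
    rng = np.random.default_rng(seed)
    chance = tf_results[0].per_freq[0].chance if chance is None else chance
    times = tf_results[0].times
    mask = _window_mask(times, window)
    n_sub = len(tf_results)
    n_freq = len(tf_results[0].freqs)
    acc = np.stack([r.accuracy[:, mask] for r in tf_results])  # (P, F, T)
    threshold = stats.t.ppf(1 - cluster_alpha, df=n_sub - 1)
    observed = one_sample_t(acc, popmean=chance)
    preds = [[r.per_freq[f].pred[mask] for f in range(n_freq)] for r in tf_results]
    trues = [[r.per_freq[f].true for f in range(n_freq)] for r in tf_results]

    def nulls():
        for _ in range(n_perm):
            acc_b = np.empty_like(acc)
            for p in range(n_sub):
                for f in range(n_freq):
                    pt = rng.permutation(trues[p][f])
                    acc_b[p, f] = (preds[p][f] == pt[None, :]).mean(axis=1)
            yield one_sample_t(acc_b, popmean=chance)

    return _run_cluster_test(
        observed, nulls(), threshold, "grid", 1, n_perm, cluster_alpha,
        times[mask], rank_matched=True,
    )
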