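"""Representational similarity analysis.

Subjective rater matrices are averaged into perceptual / conceptual RDMs
(representational dissimilarity matrices); pairwise-decoding accuracies
form the neural RDM at every timepoint; the two are compared by Spearman
rank correlation of their lower triangles, one-sided (positive tail),
inside the time window where item-level decoding was itself significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: the rating scale runs 1 (extremely dissimilar) to 9 (extremely similar),
#: so dissimilarity = RATING_FLIP - mean rating
RATING_FLIP = 10.0


def average_subjective_rdm(
    rating_stack: np.ndarray, direction: str = "similarity"
) -> np.ndarray:
    """Average per-rater item x item matrices into one dissimilarity RDM.

    ``direction`` declares how the input is oriented: ``"similarity"``
    (the 1-9 scale anchored at 9 = extremely similar; converted to
    dissimilarity as ``10 - rating``) or ``"dissimilarity"`` (used as
    is).  Output is symmetrized by averaging with its transpose; the
    diagonal is NaN and excluded from all statistics.
    """
    stack = np.asarray(rating_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("rating stack must be (n_raters, n_items, n_items)")
    if direction not in ("similarity", "dissimilarity"):
        raise ValueError("direction must be 'similarity' or 'dissimilarity'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
        mean = np.nanmean(stack, axis=0)
    if direction == "similarity":
        mean = RATING_FLIP - mean
    rdm = (mean + mean.T) / 2.0
    np.fill_diagonal(rdm, np.nan)
    off = ~np.eye(rdm.shape[0], dtype=bool)
    if not np.all(np.isfinite(rdm[off])):
        raise ValueError("non-finite off-diagonal entries after averaging")
    return rdm


def rdm_vector(rdm: np.ndarray) -> np.ndarray:
    """Lower-triangle vectorization, row-major over i < j (fixed order)."""
    rdm = np.asarray(rdm)
    n = rdm.shape[0]
    iu = np.triu_indices(n, k=1)
    return rdm[iu]


@dataclass
class RSATimecourse:
    """Spearman rho of neural vs subjective RDM at every timepoint."""

    times: np.ndarray
    rho: np.ndarray
    p: np.ndarray        # one-sided (positive), NaN outside the mask
    mask: np.ndarray     # where significance was evaluated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.times, "rho": self.rho, "p_one_sided": self.p,
             "in_mask": self.mask}
        )


def rsa_timecourse(
    neural_rdms: np.ndarray,
    subjective_rdm: np.ndarray,
    times: np.ndarray,
    mask: np.ndarray | None = None,
) -> RSATimecourse:
    """Correlate a neural RDM timeseries with one subjective RDM.

    ``neural_rdms`` is (timepoints, items, items); ``mask`` restricts
    where one-sided p-values are reported (typically the significant
    item-decoding window; uncorrected by design).  Rho itself is computed
    everywhere — pre-stimulus values are informative as a sanity band but
    should be read with caution.  A constant triangle yields NaN with a
    warning.
    """
    neural_rdms = np.asarray(neural_rdms, dtype=float)
    subjective_rdm = np.asarray(subjective_rdm, dtype=float)
    if neural_rdms.shape[1:] != subjective_rdm.shape:
        raise ValueError("item sets of neural and subjective RDMs differ")
    if mask is None:
        mask = np.ones(len(times), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sub_vec = rdm_vector(subjective_rdm)
    rho = np.full(len(times), np.nan)
    p = np.full(len(times), np.nan)
    warned = False
    for t in range(len(times)):
        vec = rdm_vector(neural_rdms[t])
        if np.ptp(vec) == 0 or np.ptp(sub_vec) == 0:
            if not warned:
                warnings.warn("constant RDM triangle: rho undefined", stacklevel=2)
                warned = True
            continue
        res = stats.spearmanr(vec, sub_vec, alternative="greater")
        rho[t] = res.statistic
        if mask[t]:
            p[t] = res.pvalue
    return RSATimecourse(times=np.asarray(times), rho=rho, p=p, mask=mask)
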