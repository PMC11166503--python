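"""Time-resolved multivariate decoding of EEG epochs.

The engine follows the sub-ERP scheme common in EEG MVPA: trials of each
class are randomly partitioned into near-equal bins and averaged into
sub-ERPs (raising SNR), which are the classifier exemplars in a k-fold
cross-validation with ``n_folds == n_bins``.  Decoding runs at every
``step_ms`` (default 20 ms) timepoint on features averaged over a
+/- 10 ms window, is repeated over random iterations, and uses a linear
SVM: one-vs-one for condition decoding (a single binary problem per
condition pair) and one-vs-all for item decoding, with ties resolved by
the summed decision values (argmax), the error-correcting-output-codes
convention.  Train and test sets are z-scored with *training* statistics
only.

Every classified unit's (true class, assigned class) is retained per
timepoint: these trial-level records are the substrate for the
permutation nulls in :mod:`tntdecode.cluster_stats` and re-aggregate
exactly to the reported accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from .epochs import EpochSet
from .spectral import ALPHA_BAND, THETA_BAND, default_freqs


# ---------------------------------------------------------------------------
# feature reduction
# ---------------------------------------------------------------------------

@dataclass
class FeatureEpochs:
    """Spatially PCA-reduced epochs: trials x components x times."""

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    trial_table: pd.DataFrame
    explained_variance_ratio: np.ndarray
    pca: object | None = None

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def time_mask(self, start: float, end: float) -> np.ndarray:
        return (self.times >= start) & (self.times < end)


def pca_reduce(epochs: EpochSet, n_components: int = 15) -> FeatureEpochs:
    """Spatial PCA fitted on all trials and timepoints pooled.

    The first ``n_components`` components (default 15) become the decoding
    features; explained variance is non-increasing by construction.  The
    PCA is deliberately fitted before any train/test split, mirroring the
    standard order of operations in EEG decoding pipelines; a strict
    per-fold refit is available via ``decode_timecourse(..., pca_per_fold=True)``
    on raw epochs.
    """
    n_trials, n_ch, n_times = epochs.data.shape
    if n_ch < n_components:
        raise ValueError(f"only {n_ch} channels for {n_components} components")
    x = epochs.data.transpose(0, 2, 1).reshape(-1, n_ch)
    pca = PCA(n_components=n_components, svd_solver="covariance_eigh")
    scores = pca.fit_transform(x)
    total_var = x.var(axis=0, ddof=1).sum()
    rank = int(np.sum(pca.explained_variance_ > 1e-10 * max(total_var, 1e-30)))
    if rank < n_components:
        raise ValueError(
            f"input has spatial rank {rank}, below n_components={n_components}"
        )
    data = scores.reshape(n_trials, n_times, n_components).transpose(0, 2, 1)
    return FeatureEpochs(
        data=data,
        times=epochs.times.copy(),
        sfreq=epochs.sfreq,
        trial_table=epochs.trial_table.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        pca=pca,
    )


# ---------------------------------------------------------------------------
# specs and results
# ---------------------------------------------------------------------------

@dataclass
class DecodeSpec:
    """Cross-validation scheme for one decoding analysis.

    ``mode`` is ``"condition"`` (pairwise, 10 sub-ERP bins / 10 folds) or
    ``"item"`` (one-vs-all, 3 bins / 3 folds).  ``subset_size`` enables
    resampled item decoding (e.g. 6 of 12 items per iteration).
    """

    mode: str = "condition"
    n_bins: int = 10
    n_folds: int = 10
    n_iterations: int = 10
    step_ms: float = 20.0
    smooth_halfwidth_ms: float = 10.0
    subset_size: int | None = None
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("condition", "item"):
            raise ValueError("mode must be 'condition' or 'item'")
        if self.n_folds != self.n_bins:
            raise ValueError("n_folds must equal n_bins (leave-one-bin-out)")
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")


def condition_spec(**kw) -> DecodeSpec:
    """Condition-level default: 10 bins, 10-fold CV, 10 iterations."""
    kw = {"n_bins": 10, "n_folds": 10, "n_iterations": 10, **kw}
    return DecodeSpec(mode="condition", **kw)


def item_spec(**kw) -> DecodeSpec:
    """Item-level default: 3 bins, 3-fold CV, 10 iterations."""
    kw = {"n_bins": 3, "n_folds": 3, "n_iterations": 10, **kw}
    return DecodeSpec(mode="item", **kw)


@dataclass
class DecodingResult:
    """Per-timepoint accuracy plus the retained classification records.

    ``pred[t, u]`` is the class assigned to unit ``u`` (a tested sub-ERP)
    at timepoint ``t``; ``true[u]`` its class.  ``accuracy`` equals
    ``(pred == true).mean(axis=1)`` exactly.
    """

    times: np.ndarray
    accuracy: np.ndarray
    true: np.ndarray
    pred: np.ndarray
    unit_iteration: np.ndarray
    classes: np.ndarray
    mode: str
    chance: float

    @property
    def n_units(self) -> int:
        return len(self.true)

    def recompute_accuracy(self) -> np.ndarray:
        return (self.pred == self.true[None, :]).mean(axis=1)

    def confusion(self) -> np.ndarray:
        """Counts, classes x classes x timepoints (rows: true class)."""
        k = len(self.classes)
        lut = {c: i for i, c in enumerate(self.classes)}
        ti = np.array([lut[c] for c in self.true])
        out = np.zeros((k, k, len(self.times)), dtype=int)
        for t in range(len(self.times)):
            pi = np.array([lut[c] for c in self.pred[t]])
            np.add.at(out[:, :, t], (ti, pi), 1)
        return out

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("times", "accuracy", "true", "pred", "unit_iteration", "classes"):
                arr = np.asarray(getattr(self, name))
                if arr.dtype.kind in ("U", "O"):  # condition labels are strings
                    arr = arr.astype("S")
                f.create_dataset(name, data=arr)
            f.attrs["mode"] = self.mode
            f.attrs["chance"] = self.chance

    @classmethod
    def from_hdf5(cls, path) -> "DecodingResult":
        def _load(ds):
            arr = ds[()]
            return arr.astype("U") if arr.dtype.kind == "S" else arr

        with h5py.File(path, "r") as f:
            return cls(
                times=f["times"][()], accuracy=f["accuracy"][()],
                true=_load(f["true"]), pred=_load(f["pred"]),
                unit_iteration=f["unit_iteration"][()], classes=_load(f["classes"]),
                mode=str(f.attrs["mode"]), chance=float(f.attrs["chance"]),
            )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def bin_average(x: np.ndarray, n_bins: int, rng) -> tuple[np.ndarray, list[np.ndarray]]:
    """Random partition of trials into near-equal bins, averaged per bin.

    Bin sizes differ by at most one (e.g. 56 trials into 10 bins gives six
    bins of 6 and four of 5).  Returns ``(sub_erps, assignments)``;
    deterministic given the generator state.
    """
    n = x.shape[0]
    if n < n_bins:
        raise ValueError(f"cannot split {n} trials into {n_bins} bins")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    order = rng.permutation(n)
    groups = np.array_split(order, n_bins)
    subs = np.stack([x[g].mean(axis=0) for g in groups])
    return subs, groups


def timepoint_centers(
    times: np.ndarray, step_ms: float, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Decoding grid: every ``step_ms`` from the epoch start (sample-aligned)."""
    if len(times) == 1:
        return times.copy() if window is None else times[
            (times >= window[0]) & (times < window[1])
        ]
    dt = times[1] - times[0]
    stride = max(1, int(round(step_ms / dt)))
    centers = times[::stride]
    if window is not None:
        centers = centers[(centers >= window[0]) & (centers < window[1])]
    if len(centers) == 0:
        raise ValueError("no decoding timepoints inside the requested window")
    return centers


def _smoothed_features(features: FeatureEpochs, centers, halfwidth_ms) -> np.ndarray:
    """(n_centers, n_trials, n_features): mean over [c - hw, c + hw) per center."""
    t = features.times
    out = np.empty((len(centers), features.data.shape[0], features.data.shape[1]))
    for i, c in enumerate(centers):
        mask = (t >= c - halfwidth_ms) & (t < c + halfwidth_ms)
        if not mask.any():
            raise ValueError(f"timepoint {c} ms has no samples in the epoch")
        out[i] = features.data[:, :, mask].mean(axis=2)
    return out


def _fit_predict(xtr, ytr, xte, c_reg):
    """Linear SVM; multiclass via one-vs-all decision values (ECOC argmax)."""
    clf = LinearSVC(C=c_reg, dual=True, max_iter=5000)
    clf.fit(xtr, ytr)
    scores = np.asarray(clf.decision_function(xte))
    if scores.ndim == 1:  # binary: sign of the margin
        return clf.classes_[(scores > 0).astype(int)]
    return clf.classes_[scores.argmax(axis=1)]


def features_from_epochs(epochs: EpochSet) -> FeatureEpochs:
    """Wrap raw channel data as features (no PCA), e.g. for per-fold PCA."""
    return FeatureEpochs(
        data=epochs.data.copy(),
        times=epochs.times.copy(),
        sfreq=epochs.sfreq,
        trial_table=epochs.trial_table.copy(),
        explained_variance_ratio=np.array([]),
        pca=None,
    )


def _cv_engine(smoothed, y, spec, rng, leakage_probe_offset=0.0, pca_per_fold=None):
    """Run the binned CV decode over all centers of a smoothed feature stack.

    smoothed : (n_centers, n_trials, n_feat); y : (n_trials,) class codes.
    Returns (pred (n_centers, n_units), true (n_units,), iter_id (n_units,)).
    Bin assignments are drawn once per iteration and shared across centers,
    so the time course is internally consistent.
    """
    n_centers, _, n_feat = smoothed.shape
    classes, y_codes = np.unique(y, return_inverse=True)
    class_trials = [np.flatnonzero(y_codes == k) for k in range(len(classes))]
    preds, trues, iters = [], [], []
    for it in range(spec.n_iterations):
        # one sub-ERP bin assignment per class for this iteration
        groups = []  # (class_code, trial indices) per bin
        for k, trials_k in enumerate(class_trials):
            order = rng.permutation(trials_k)
            for b, g in enumerate(np.array_split(order, spec.n_bins)):
                groups.append((k, b, g))
        labels = np.array([k for k, _, _ in groups])
        bin_of = np.array([b for _, b, _ in groups])
        binned = np.empty((len(groups), n_centers, n_feat))
        for j, (_, _, g) in enumerate(groups):
            binned[j] = smoothed[:, g, :].mean(axis=1)
        for fold in range(spec.n_folds):
            te = bin_of == fold
            tr = ~te
            ytr, yte = labels[tr], labels[te]
            if pca_per_fold is not None:
                # strict mode: spatial PCA refit on training folds only
                p = PCA(n_components=pca_per_fold, svd_solver="covariance_eigh")
                p.fit(binned[tr].reshape(-1, n_feat))
                fold_tr = np.einsum("gcf,fk->gck", binned[tr], p.components_.T)
                fold_te = np.einsum("gcf,fk->gck", binned[te], p.components_.T)
            else:
                fold_tr, fold_te = binned[tr], binned[te]
            pred_fold = np.empty((n_centers, te.sum()), dtype=int)
            for ci in range(n_centers):
                xtr = fold_tr[:, ci, :]
                xte = fold_te[:, ci, :]
                mu = xtr.mean(axis=0)
                sd = xtr.std(axis=0)
                sd[sd == 0] = 1.0
                xtr = (xtr - mu) / sd
                xte = (xte + leakage_probe_offset - mu) / sd
                pred_fold[ci] = _fit_predict(xtr, ytr, xte, spec.C)
            preds.append(pred_fold)
            trues.append(yte)
            iters.append(np.full(te.sum(), it))
    pred = np.concatenate(preds, axis=1)
    true = np.concatenate(trues)
    return classes[pred], classes[true], np.concatenate(iters)


def _labels_for(features: FeatureEpochs, spec: DecodeSpec, labels):
    if labels is not None:
        return np.asarray(labels)
    col = "condition" if spec.mode == "condition" else "item_id"
    return features.trial_table[col].to_numpy()


def _equalize_classes(y, rng):
    """Match per-class trial counts to the smallest class (random subset)."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# public decodes
# ---------------------------------------------------------------------------

def decode_timecourse(
    features: FeatureEpochs,
    spec: DecodeSpec,
    labels=None,
    window: tuple[float, float] | None = None,
    seed=None,
    leakage_probe_offset: float = 0.0,
    pca_per_fold: int | None = None,
) -> DecodingResult:
    """Cross-validated decoding accuracy at every grid timepoint.

    ``labels`` defaults to the trial table's condition (condition mode) or
    item id (item mode).  In item mode per-class trial counts are first
    matched to the smallest class.  ``leakage_probe_offset`` corrupts
    *test* features by a constant after the train/test split — a
    diagnostic that must leave null-data accuracy at chance if
    normalization truly uses training statistics only.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    y = _labels_for(features, spec, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    counts = pd.Series(y).value_counts()
    if counts.min() < spec.n_bins:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} trials, "
            f"fewer than n_bins={spec.n_bins}"
        )
    if spec.mode == "item":
        keep = _equalize_classes(y, rng)
        feats = replace(
            features,
            data=features.data[keep],
            trial_table=features.trial_table.iloc[keep].reset_index(drop=True),
        )
        y = y[keep]
    else:
        feats = features
    centers = timepoint_centers(feats.times, spec.step_ms, window)
    smoothed = _smoothed_features(feats, centers, spec.smooth_halfwidth_ms)
    pred, true, iter_id = _cv_engine(
        smoothed, y, spec, rng, leakage_probe_offset, pca_per_fold
    )
    acc = (pred == true[None, :]).mean(axis=1)
    classes = np.unique(y)
    return DecodingResult(
        times=centers, accuracy=acc, true=true, pred=pred,
        unit_iteration=iter_id, classes=classes, mode=spec.mode,
        chance=1.0 / len(classes),
    )


def estimate_chance(
    features: FeatureEpochs,
    spec: DecodeSpec,
    labels=None,
    baseline_window: tuple[float, float] = (-500.0, 0.0),
    seed=None,
) -> float:
    """Empirical chance: mean decoding accuracy over the pre-stimulus baseline.

    The baseline period carries no task information, so classification
    there calibrates the true chance level of the full pipeline.
    """
    if not ((features.times >= baseline_window[0]) & (features.times < baseline_window[1])).any():
        raise ValueError("baseline window outside the epoch")
    res = decode_timecourse(features, spec, labels=labels, window=baseline_window, seed=seed)
    return float(res.accuracy.mean())


def decode_resampled_items(
    features: FeatureEpochs,
    spec: DecodeSpec | None = None,
    subset_size: int = 6,
    n_iterations: int = 20,
    window: tuple[float, float] | None = None,
    seed=None,
) -> DecodingResult:
    """Item decoding over random item subsets (class-count matching).

    Each iteration decodes a fresh random subset of ``subset_size`` items
    (one-vs-all), making accuracies directly comparable with a condition
    that has only ``subset_size`` items; accuracies average over
    iterations.  With ``subset_size`` equal to the item count this is
    plain item decoding.
    """
    spec = item_spec() if spec is None else spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    y = _labels_for(features, spec, None)
    items = np.unique(y)
    if subset_size > len(items):
        raise ValueError(f"subset_size {subset_size} exceeds item count {len(items)}")
    one_iter = replace(spec, n_iterations=1)
    preds, trues, iters = [], [], []
    centers = None
    for it in range(n_iterations):
        chosen = rng.choice(items, size=subset_size, replace=False)
        keep = np.flatnonzero(np.isin(y, chosen))
        feats = replace(
            features,
            data=features.data[keep],
            trial_table=features.trial_table.iloc[keep].reset_index(drop=True),
        )
        res = decode_timecourse(feats, one_iter, window=window, seed=rng)
        centers = res.times
        preds.append(res.pred)
        trues.append(res.true)
        iters.append(np.full(res.n_units, it))
    pred = np.concatenate(preds, axis=1)
    true = np.concatenate(trues)
    acc = (pred == true[None, :]).mean(axis=1)
    return DecodingResult(
        times=centers, accuracy=acc, true=true, pred=pred,
        unit_iteration=np.concatenate(iters), classes=items, mode="item",
        chance=1.0 / subset_size,
    )


# ---------------------------------------------------------------------------
# time-frequency decoding
# ---------------------------------------------------------------------------

@dataclass
class TimeFrequencyDecoding:
    """Frequency x time accuracy map with per-frequency records."""

    freqs: np.ndarray
    times: np.ndarray
    accuracy: np.ndarray  # (n_freqs, n_centers)
    per_freq: list  # DecodingResult per frequency bin

    def band_summary(self, band: tuple[float, float]) -> np.ndarray:
        """Mean accuracy over frequency bins with centers inside ``band``."""
        mask = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not mask.any():
            raise ValueError(f"no frequency bins inside {band}")
        return self.accuracy[mask].mean(axis=0)

    @property
    def theta(self) -> np.ndarray:
        return self.band_summary(THETA_BAND)

    @property
    def alpha(self) -> np.ndarray:
        return self.band_summary(ALPHA_BAND)


def decode_timefrequency(
    features: FeatureEpochs,
    spec: DecodeSpec,
    freqs: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
    seed=None,
) -> TimeFrequencyDecoding:
    """Decode each Morlet frequency bin of the PCA components across time.

    The PCA-reduced time series is wavelet transformed (components in
    place of channels) and the time-domain procedure is applied
    independently per frequency bin, yielding a 2-D accuracy map.
    """
    from mne.time_frequency import tfr_array_morlet

    from .spectral import n_cycles

    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    power = tfr_array_morlet(
        features.data, sfreq=features.sfreq, freqs=freqs,
        n_cycles=n_cycles(freqs), output="power", zero_mean=True,
    )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    results, acc = [], []
    for fi in range(len(freqs)):
        feats_f = replace(features, data=power[:, :, fi, :])
        res = decode_timecourse(feats_f, spec, window=window, seed=rng)
        results.append(res)
        acc.append(res.accuracy)
    return TimeFrequencyDecoding(
        freqs=freqs, times=results[0].times, accuracy=np.stack(acc), per_freq=results
    )


# ---------------------------------------------------------------------------
# pairwise decoding (neural RDM)
# ---------------------------------------------------------------------------

@dataclass
class NeuralRDMSeries:
    """Item x item pairwise decoding accuracy per timepoint."""

    times: np.ndarray
    items: np.ndarray
    rdm: np.ndarray  # (n_centers, n_items, n_items), NaN diagonal

    def at(self, time_ms: float) -> np.ndarray:
        return self.rdm[int(np.argmin(np.abs(self.times - time_ms)))]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("items", data=self.items)
            f.create_dataset("rdm", data=self.rdm)


def pairwise_item_decode(
    features: FeatureEpochs,
    spec: DecodeSpec | None = None,
    window: tuple[float, float] | None = None,
    seed=None,
) -> NeuralRDMSeries:
    """Binary decoding of every item pair: the neural RDM time series.

    Higher pairwise accuracy means more discriminable neural patterns,
    i.e. larger neural dissimilarity.
    """
    spec = item_spec() if spec is None else spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    y = _labels_for(features, spec, None)
    items = np.unique(y)
    if len(items) < 3:
        raise ValueError("need at least 3 items for an informative RDM")
    centers = timepoint_centers(features.times, spec.step_ms, window)
    rdm = np.full((len(centers), len(items), len(items)), np.nan)
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            keep = np.flatnonzero(np.isin(y, [items[a], items[b]]))
            feats = replace(
                features,
                data=features.data[keep],
                trial_table=features.trial_table.iloc[keep].reset_index(drop=True),
            )
            res = decode_timecourse(feats, spec, window=window, seed=rng)
            rdm[:, a, b] = rdm[:, b, a] = res.accuracy
    return NeuralRDMSeries(times=centers, items=items, rdm=rdm)
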