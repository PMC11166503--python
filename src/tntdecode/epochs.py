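"""Core data containers for epoched EEG and minimal preprocessing.

The analyses in this package operate on already-cleaned, epoched EEG:
trials x channels x time arrays with a per-trial table of condition and
item labels, and a fixed 61-channel scalp montage.  Epochs are stored in
milliseconds relative to cue onset; every time window in the package uses
the half-open ``[start, end)`` convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

CONDITIONS = ("Think", "NoThink", "PerceptualBaseline")

#: Channels excluded from analysis on the 64-channel cap: mastoids and the
#: online reference (the ground AFz and EOG are never data channels).
EXCLUDED_CHANNELS = ("M1", "M2", "CPz")


@dataclass
class Montage:
    """Scalp electrode montage: names, 3-D template positions, 2-D projection.

    Positions follow the standard 10-5 template (unit: meters, head frame).
    The 2-D projection is azimuthal equidistant from the best-fit sphere
    center, the common EEG flattening used for topographies and channel
    triangulation.
    """

    channel_names: list[str]
    pos3d: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        self.channel_names = list(self.channel_names)
        self.pos3d = np.asarray(self.pos3d, dtype=float)
        if self.pos3d.shape != (len(self.channel_names), 3):
            raise ValueError("pos3d must be (n_channels, 3)")
        if not np.all(np.isfinite(self.pos3d)):
            raise ValueError("montage positions must be finite")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @classmethod
    def standard_61(cls) -> "Montage":
        """The packaged 61-channel analysis montage (10-5 template)."""
        with resources.files("tntdecode.data").joinpath(
            "montage_61ch_1005.csv"
        ).open() as fh:
            tab = pd.read_csv(fh)
        return cls(tab["name"].tolist(), tab[["x", "y", "z"]].to_numpy())

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def sphere_center(self) -> np.ndarray:
        """Least-squares best-fit sphere center of the electrode cloud."""
        p = self.pos3d
        a = np.column_stack([2.0 * p, np.ones(len(p))])
        b = (p**2).sum(axis=1)
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        return sol[:3]

    def projected_2d(self) -> np.ndarray:
        """Azimuthal equidistant projection of the 3-D positions.

        Electrodes are re-centered on the best-fit sphere center; the
        planar radius equals the polar angle from the vertex, so arc
        length on the scalp is preserved along meridians.
        """
        p = self.pos3d - self.sphere_center()
        r = np.linalg.norm(p, axis=1)
        elevation = np.arcsin(np.clip(p[:, 2] / r, -1.0, 1.0))
        azimuth = np.arctan2(p[:, 1], p[:, 0])
        rad = np.pi / 2 - elevation
        return np.column_stack([rad * np.cos(azimuth), rad * np.sin(azimuth)])

    def index(self, names) -> np.ndarray:
        """Indices of the given channel names (raises on unknown names)."""
        lut = {c: i for i, c in enumerate(self.channel_names)}
        try:
            return np.array([lut[n] for n in names], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in montage") from None


@dataclass
class EpochSet:
    """Labeled EEG epochs: trials x channels x time, with montage and labels.

    Parameters
    ----------
    data : (n_trials, n_channels, n_times) array, microvolts.
    times : (n_times,) ms axis relative to cue onset, uniform at 1000/sfreq.
    sfreq : sampling frequency in Hz.
    channel_names : channel labels matching ``data``'s second axis.
    montage : the scalp montage (channel order may be a superset ordering).
    trial_table : per-trial DataFrame with columns ``condition`` (one of
        Think / NoThink / PerceptualBaseline), ``item_id``, ``participant_id``.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channel_names: list[str]
    montage: Montage
    trial_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_names = list(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x times")
        n_trials, n_ch, n_times = self.data.shape
        if len(self.times) != n_times:
            raise ValueError("times length mismatch")
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length mismatch")
        if len(set(self.channel_names)) != n_ch:
            raise ValueError("channel names must be unique")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1000.0 / self.sfreq, atol=1e-6)):
            raise ValueError("times must increase uniformly at 1/sfreq")
        if len(self.trial_table) != n_trials:
            raise ValueError("trial_table length mismatch")
        for col in ("condition", "item_id"):
            if col not in self.trial_table.columns:
                raise ValueError(f"trial_table missing column {col!r}")
        bad = set(self.trial_table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        self.trial_table = self.trial_table.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask of samples with ``start <= t < end`` (ms)."""
        return (self.times >= start) & (self.times < end)

    def select_trials(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx],
            trial_table=self.trial_table.iloc[idx].reset_index(drop=True),
        )

    def select_condition(self, condition: str) -> "EpochSet":
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        mask = (self.trial_table["condition"] == condition).to_numpy()
        return self.select_trials(np.flatnonzero(mask))

    def copy(self) -> "EpochSet":
        return replace(
            self, data=self.data.copy(), trial_table=self.trial_table.copy()
        )

    # -- persistence -------------------------------------------------------
    def to_hdf5(self, path) -> None:
        """Write the epoch set to the package HDF5 layout (one file/participant)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("times", data=self.times)
            tab = self.trial_table
            f.create_dataset(
                "trial_table", data=np.bytes_(tab.to_json(orient="split"))
            )
            f.attrs["sfreq"] = self.sfreq
            f.attrs["channel_names"] = json.dumps(self.channel_names)
            f.attrs["montage_names"] = json.dumps(self.montage.channel_names)
            f.attrs["montage_pos3d"] = json.dumps(self.montage.pos3d.tolist())

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            from io import StringIO

            tab = pd.read_json(
                StringIO(f["trial_table"][()].decode()), orient="split"
            )
            montage = Montage(
                json.loads(f.attrs["montage_names"]),
                np.array(json.loads(f.attrs["montage_pos3d"])),
            )
            return cls(
                data=f["data"][()],
                times=f["times"][()],
                sfreq=float(f.attrs["sfreq"]),
                channel_names=json.loads(f.attrs["channel_names"]),
                montage=montage,
                trial_table=tab,
            )

    @classmethod
    def from_array_dir(cls, path) -> "EpochSet":
        """Import adapter: ``data.npy`` plus ``sidecar.json`` in a directory.

        The sidecar carries times, sfreq, channel names, montage positions
        and the trial table (records orient), so externally preprocessed
        epochs can be mounted without any raw-EEG format reader.
        """
        path = Path(path)
        data = np.load(path / "data.npy")
        meta = json.loads((path / "sidecar.json").read_text())
        montage = Montage(meta["montage_names"], np.array(meta["montage_pos3d"]))
        return cls(
            data=data,
            times=np.asarray(meta["times"], dtype=float),
            sfreq=float(meta["sfreq"]),
            channel_names=meta["channel_names"],
            montage=montage,
            trial_table=pd.DataFrame.from_records(meta["trial_table"]),
        )

    def to_array_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "data.npy", self.data)
        meta = {
            "times": self.times.tolist(),
            "sfreq": self.sfreq,
            "channel_names": self.channel_names,
            "montage_names": self.montage.channel_names,
            "montage_pos3d": self.montage.pos3d.tolist(),
            "trial_table": self.trial_table.to_dict(orient="records"),
        }
        (path / "sidecar.json").write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# preprocessing applied to already-clean epochs
# ---------------------------------------------------------------------------

def baseline_correct(epochs: EpochSet, window: tuple[float, float] = (-500.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (ms).

    Idempotent: correcting twice equals correcting once.
    """
    mask = epochs.time_mask(*window)
    if not mask.any():
        raise ValueError(f"baseline window {window} outside the epoch time axis")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_artifacts(epochs: EpochSet, threshold: float = 100.0):
    """Drop trials whose absolute amplitude exceeds ``threshold`` microvolts.

    Returns the cleaned EpochSet and a log DataFrame with the removed trial
    indices and their peak absolute values.  Raises if nothing survives.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    bad = peaks > threshold
    log = pd.DataFrame(
        {"trial": np.flatnonzero(bad), "peak_uv": peaks[bad]}
    )
    if bad.all():
        conds = sorted(set(epochs.trial_table["condition"]))
        raise ValueError(
            f"all trials rejected at threshold {threshold} uV (conditions: {conds})"
        )
    return epochs.select_trials(np.flatnonzero(~bad)), log


def subsample_to_match(
    epochs: EpochSet, condition_a: str, condition_b: str, seed
) -> EpochSet:
    """Randomly subsample ``condition_a`` trials down to ``condition_b``'s count.

    Used to equate Think / No-Think trial counts with the smaller Perceptual
    Baseline set before condition-level decoding.  Deterministic given seed;
    trials of other conditions are untouched and trial order is preserved.
    """
    tab = epochs.trial_table
    for c in (condition_a, condition_b):
        if c not in CONDITIONS:
            raise ValueError(f"unknown condition {c!r}")
    idx_a = np.flatnonzero((tab["condition"] == condition_a).to_numpy())
    n_b = int((tab["condition"] == condition_b).sum())
    if len(idx_a) < n_b:
        raise ValueError(
            f"{condition_a} has {len(idx_a)} trials, fewer than {condition_b}'s {n_b}"
        )
    rng = np.random.default_rng(seed)
    keep_a = np.sort(rng.choice(idx_a, size=n_b, replace=False))
    others = np.flatnonzero((tab["condition"] != condition_a).to_numpy())
    keep = np.sort(np.concatenate([keep_a, others]))
    return epochs.select_trials(keep)


# ---------------------------------------------------------------------------
# behavior table helpers
# ---------------------------------------------------------------------------

BEHAVIOR_COLUMNS = ("participant", "condition", "identification", "gist", "detail")


def validate_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Check a behavioral recall table (Identification/Gist proportions, Detail counts)."""
    missing = set(BEHAVIOR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"behavior table missing columns {sorted(missing)}")
    if ((table["identification"] < 0) | (table["identification"] > 1)).any():
        raise ValueError("identification must be in [0, 1]")
    if ((table["gist"] < 0) | (table["gist"] > 1)).any():
        raise ValueError("gist must be in [0, 1]")
    if (table["detail"] < 0).any():
        raise ValueError("detail must be non-negative")
    return table


def save_behavior(table: pd.DataFrame, path) -> None:
    validate_behavior(table).to_csv(path, index=False)


def load_behavior(path) -> pd.DataFrame:
    return validate_behavior(pd.read_csv(path))
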