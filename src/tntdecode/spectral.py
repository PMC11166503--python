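"""Morlet time-frequency decomposition, dB baselining and ERP measures.

Power is computed with Morlet wavelets at 22 geometrically spaced
frequencies between 2.8 and 30 Hz, with cycle counts increasing linearly
from 3 (at 2.8 Hz) to 7 (at 30 Hz).  Decibel baselining divides by the
condition-pooled mean power over a pre-stimulus window, per channel and
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
from mne.time_frequency import tfr_array_morlet

from .epochs import EpochSet

FREQ_MIN, FREQ_MAX, N_FREQS = 2.8, 30.0, 22
CYCLES_MIN, CYCLES_MAX = 3.0, 7.0

THETA_BAND = (4.0, 8.0)
ALPHA_BAND = (9.0, 12.0)


def default_freqs() -> np.ndarray:
    """22 geometrically spaced frequencies, endpoints 2.8 and 30 Hz."""
    return np.geomspace(FREQ_MIN, FREQ_MAX, N_FREQS)


def n_cycles(freqs: np.ndarray) -> np.ndarray:
    """Wavelet cycles, linear in frequency: 3 at 2.8 Hz up to 7 at 30 Hz."""
    freqs = np.asarray(freqs, dtype=float)
    return CYCLES_MIN + (CYCLES_MAX - CYCLES_MIN) * (freqs - FREQ_MIN) / (
        FREQ_MAX - FREQ_MIN
    )


@dataclass
class TFRSet:
    """Trial-level time-frequency power: trials x channels x freqs x times.

    ``baseline_state`` records whether power is raw (uV^2) or decibel
    baselined; ``valid`` flags time-frequency samples whose wavelet is
    fully supported by the epoch (edge samples are excluded from
    statistics, never zero-padded silently).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    channel_names: list[str]
    trial_table: object
    baseline_state: str = "raw"  # "raw" | "dB"
    valid: np.ndarray | None = None  # (n_freqs, n_times) bool

    def __post_init__(self) -> None:
        if self.power.ndim != 4:
            raise ValueError("power must be trials x channels x freqs x times")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.baseline_state not in ("raw", "dB"):
            raise ValueError("baseline_state must be 'raw' or 'dB'")
        if self.valid is None:
            self.valid = np.ones((len(self.freqs), len(self.times)), dtype=bool)

    def time_mask(self, start: float, end: float) -> np.ndarray:
        return (self.times >= start) & (self.times < end)

    def freq_mask(self, lo: float, hi: float) -> np.ndarray:
        """Frequency bins whose center lies in [lo, hi]."""
        return (self.freqs >= lo) & (self.freqs <= hi)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("power", data=self.power)
            f.create_dataset("freqs", data=self.freqs)
            f.create_dataset("times", data=self.times)
            f.create_dataset("valid", data=self.valid)
            f.attrs["sfreq"] = self.sfreq
            f.attrs["baseline_state"] = self.baseline_state
            f.attrs["channel_names"] = list(self.channel_names)
            f.create_dataset(
                "trial_table", data=np.bytes_(self.trial_table.to_json(orient="split"))
            )

    @classmethod
    def from_hdf5(cls, path) -> "TFRSet":
        from io import StringIO

        import pandas as pd

        with h5py.File(path, "r") as f:
            return cls(
                power=f["power"][()],
                freqs=f["freqs"][()],
                times=f["times"][()],
                sfreq=float(f.attrs["sfreq"]),
                channel_names=list(f.attrs["channel_names"]),
                trial_table=pd.read_json(
                    StringIO(f["trial_table"][()].decode()), orient="split"
                ),
                baseline_state=str(f.attrs["baseline_state"]),
                valid=f["valid"][()],
            )


def morlet_tfr(epochs: EpochSet, freqs: np.ndarray | None = None) -> TFRSet:
    """Morlet wavelet power of every trial.

    Edge samples whose wavelet support (full width ``n_cycles / f``)
    extends beyond the epoch are flagged invalid per frequency.
    """
    freqs = default_freqs() if freqs is None else np.asarray(freqs, dtype=float)
    cycles = n_cycles(freqs)
    longest = cycles[0] / freqs[0]
    if (epochs.times[-1] - epochs.times[0]) / 1000.0 < longest:
        raise ValueError(
            f"epoch too short for the {freqs[0]:.3g} Hz wavelet ({longest:.2f} s)"
        )
    power = tfr_array_morlet(
        epochs.data,
        sfreq=epochs.sfreq,
        freqs=freqs,
        n_cycles=cycles,
        output="power",
        zero_mean=True,
    )
    half_ms = 1000.0 * cycles / freqs / 2.0
    t = epochs.times
    valid = (t[None, :] >= t[0] + half_ms[:, None]) & (
        t[None, :] <= t[-1] - half_ms[:, None]
    )
    return TFRSet(
        power=power,
        freqs=freqs,
        times=t.copy(),
        sfreq=epochs.sfreq,
        channel_names=list(epochs.channel_names),
        trial_table=epochs.trial_table.copy(),
        baseline_state="raw",
        valid=valid,
    )


def db_baseline(tfr: TFRSet, window: tuple[float, float] = (-500.0, -200.0)) -> TFRSet:
    """Decibel baseline: ``10 * log10(power / baseline_mean)``.

    The baseline is the mean over trials and over the window's samples,
    per channel x frequency (condition-pooled), applied to every trial —
    the standard averaged-baseline convention for dB normalization.
    """
    if tfr.baseline_state != "raw":
        raise ValueError("power is already dB baselined")
    mask = tfr.time_mask(*window)
    if not mask.any():
        raise ValueError(f"baseline window {window} outside the time axis")
    base = tfr.power[:, :, :, mask].mean(axis=(0, 3), keepdims=True)
    if np.any(base <= 0):
        raise ValueError("nonpositive baseline power")
    out = 10.0 * np.log10(tfr.power / base)
    return replace(tfr, power=out, baseline_state="dB")


def band_power(
    tfr: TFRSet, band: tuple[float, float], window: tuple[float, float]
) -> np.ndarray:
    """Mean power over a frequency band and time window: (trials, channels).

    Averages frequency bins whose center is inside ``band`` and samples in
    ``[start, end)``; invalid (edge) samples are excluded.
    """
    fmask = tfr.freq_mask(*band)
    tmask = tfr.time_mask(*window)
    if not fmask.any() or not tmask.any():
        raise ValueError("empty band or window selection")
    sel = tfr.power[:, :, fmask][:, :, :, tmask]
    vmask = tfr.valid[np.ix_(fmask, tmask)]
    if not vmask.any():
        raise ValueError("selection contains no valid (edge-free) samples")
    return np.nansum(sel * vmask, axis=(2, 3)) / vmask.sum()


# ---------------------------------------------------------------------------
# ERP components
# ---------------------------------------------------------------------------

#: a-priori electrode clusters used for ERP and band contrasts
ELECTRODE_CLUSTERS = {
    "left_parietal": ("CP3", "CP5", "P3", "P5"),
    "parietal": ("Pz", "CP1", "CP2", "P1", "P2"),
    "right_parietal": ("CP2", "CP4", "P2", "P4"),
    "frontocentral": ("FC1", "FC2", "C1", "C2", "FCz", "Cz"),
    "left_prefrontal": ("AF3", "F3", "F5"),
    "right_prefrontal": ("AF4", "F4", "F6"),
}


@dataclass(frozen=True)
class ERPComponentSpec:
    """A named ERP component: electrode cluster plus measurement window."""

    name: str
    electrodes: tuple[str, ...]
    window: tuple[float, float]


ERP_COMPONENTS = {
    # frontocentral negativity tied to inhibitory control
    "N450": ERPComponentSpec("N450", ELECTRODE_CLUSTERS["frontocentral"], (300.0, 500.0)),
    # parietal positivity tied to episodic recollection
    "P300": ERPComponentSpec("P300", ELECTRODE_CLUSTERS["parietal"], (300.0, 800.0)),
    # left-prefrontal negative slow wave (maintenance period)
    "NSW": ERPComponentSpec("NSW", ELECTRODE_CLUSTERS["left_prefrontal"], (1000.0, 3000.0)),
}


def erp_amplitude(epochs: EpochSet, spec: ERPComponentSpec) -> dict[str, float]:
    """Mean amplitude (uV) over cluster, window and trials, per condition."""
    missing = set(spec.electrodes) - set(epochs.channel_names)
    if missing:
        raise ValueError(f"missing electrodes: {sorted(missing)}")
    ch_idx = [epochs.channel_names.index(e) for e in spec.electrodes]
    tmask = epochs.time_mask(*spec.window)
    if not tmask.any():
        raise ValueError(f"window {spec.window} outside the epoch")
    out = {}
    for cond, group in epochs.trial_table.groupby("condition", sort=False):
        sub = epochs.data[np.ix_(group.index.to_numpy(), ch_idx, np.flatnonzero(tmask))]
        out[cond] = float(sub.mean())
    return out
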