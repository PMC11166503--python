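"""Synthetic Think/No-Think EEG experiment generator.

Emulates the statistical structure the downstream analyses assume, with
known ground truth, so that every pipeline stage can be exercised against
a recoverable signal and a calibrated null:

* 12 Think and 12 No-Think items at 10 repetitions each, 6 Perceptual
  Baseline items at 10 repetitions, 61 channels, 250 Hz, epochs
  -1000..3500 ms around cue onset;
* an early (0-500 ms) item-specific *cue* pattern concentrated over
  occipital channels and carried by a theta-band (6 Hz) envelope, present
  in every condition;
* a late (500-3000 ms) item-specific *scene* pattern distributed over
  frontal-parietal-occipital channels and carried by an alpha-band (10 Hz)
  envelope, present at full gain during retrieval (Think), scaled by
  ``1 - suppression`` during suppression (No-Think) and absent in
  Perceptual Baseline;
* a frontocentral theta burst at 200-400 ms in No-Think only (the
  condition-level control signature);
* sustained posterior alpha activity at 500-3000 ms whose amplitude is
  reduced by ``alpha_mod`` in No-Think;
* spatially smoothed 1/f background noise;
* behavioral recall scores with a suppression-induced forgetting effect
  of target size ``forgetting_dz``, monotonically coupled to each
  participant's true suppression score;
* per-rater subjective (dis)similarity matrices correlated with the
  embedded item-pattern geometry.

Everything is a pure function of ``(config.seed, participant_id)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .epochs import CONDITIONS, EpochSet, Montage

OCCIPITAL = ("O1", "Oz", "O2", "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8")
FRONTOCENTRAL = ("FC1", "FC2", "FCz", "Cz", "C1", "C2", "Fz", "F1", "F2")
#: broad frontal + parietal + occipital region carrying the scene pattern
SCENE_REGION = (
    "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "AF3", "AF4",
    "CP5", "CP3", "CP1", "CP2", "CP4", "CP6",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8", "O1", "Oz", "O2",
)

_CUE_WINDOW = (0.0, 500.0)
_SCENE_WINDOW = (500.0, 3000.0)
_COND_THETA_WINDOW = (200.0, 400.0)
_THETA_HZ = 6.0
_ALPHA_HZ = 10.0
#: fraction of item-signal energy in the slow evoked (envelope) component
_DC_MIX = 0.4


@dataclass
class SimulationConfig:
    """Parameters of the simulated Think/No-Think EEG experiment.

    Amplitudes are in microvolts and scale unit-norm spatial patterns;
    ``suppression_factor`` is the population suppression strength in [0, 1]
    (1 = the scene pattern is fully abolished during No-Think trials).
    ``noise_exponent`` is the spectral slope of the 1/f background.
    """

    n_participants: int = 20
    n_items_tnt: int = 12
    n_items_pb: int = 6
    n_reps: int = 10
    sfreq: float = 250.0
    epoch_window: tuple[float, float] = (-1000.0, 3500.0)
    cue_pattern_amp: float = 8.0
    scene_pattern_amp: float = 8.0
    suppression_factor: float = 1.0
    cond_theta_amp: float = 3.0
    alpha_mod: float = 0.3
    alpha_background_amp: float = 3.0
    noise_sd: float = 8.0
    noise_exponent: float = 1.0
    n_raters: int = 22
    rating_noise_sd: float = 1.5
    forgetting_dz: float = 0.34
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cue_pattern_amp", "scene_pattern_amp", "cond_theta_amp",
            "alpha_background_amp", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValueError("suppression_factor must be in [0, 1]")
        if not 0.0 <= self.alpha_mod <= 1.0:
            raise ValueError("alpha_mod must be in [0, 1]")
        lo, hi = self.epoch_window
        if lo > -500.0 or hi < 3000.0:
            raise ValueError(
                "epoch window must contain the signal masks (at least -500..3000 ms)"
            )
        if self.n_reps < 1 or self.n_items_tnt < 2 or self.n_items_pb < 2:
            raise ValueError("need >=2 items per condition and >=1 repetition")

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sfreq
        return np.arange(self.epoch_window[0], self.epoch_window[1], step)


@dataclass
class GroundTruth:
    """What was planted for one simulated participant.

    ``cue_patterns`` / ``scene_patterns`` are items x channels unit-norm
    spatial maps (cue: occipital-concentrated; scene: distributed).
    ``suppression`` is the participant's true suppression score in [0, 1].
    """

    participant_id: int
    channel_names: list[str]
    item_ids: np.ndarray          # global item ids, grouped by condition
    item_condition: list[str]     # condition owning each item
    cue_patterns: np.ndarray      # (n_items, n_channels)
    scene_patterns: np.ndarray    # (n_items, n_channels)
    suppression: float
    cue_window: tuple[float, float] = _CUE_WINDOW
    scene_window: tuple[float, float] = _SCENE_WINDOW
    cond_theta_window: tuple[float, float] = _COND_THETA_WINDOW

    def items_of(self, condition: str) -> np.ndarray:
        sel = [i for i, c in enumerate(self.item_condition) if c == condition]
        return self.item_ids[sel]

    def to_json(self, path) -> None:
        d = asdict(self)
        d["item_ids"] = self.item_ids.tolist()
        d["cue_patterns"] = self.cue_patterns.tolist()
        d["scene_patterns"] = self.scene_patterns.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["item_ids"] = np.array(d["item_ids"])
        d["cue_patterns"] = np.array(d["cue_patterns"])
        d["scene_patterns"] = np.array(d["scene_patterns"])
        d["cue_window"] = tuple(d["cue_window"])
        d["scene_window"] = tuple(d["scene_window"])
        d["cond_theta_window"] = tuple(d["cond_theta_window"])
        return cls(**d)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _region_pattern(rng, montage, region, concentration=0.85, smooth=None) -> np.ndarray:
    """Random unit vector with `concentration` of squared weight in `region`.

    When a spatial smoothing matrix is given the draw is smoothed first
    (scalp patterns of cortical sources are spatially smooth under volume
    conduction) and the regional concentration re-imposed afterwards.
    """
    n = montage.n_channels
    idx = montage.index(region)
    rest = np.setdiff1d(np.arange(n), idx)
    raw = np.zeros(n)
    raw[idx] = rng.standard_normal(len(idx))
    if smooth is not None:
        raw = smooth @ raw
    inside = np.zeros(n)
    inside[idx] = raw[idx]
    inside /= np.linalg.norm(inside)
    outside = np.zeros(n)
    outside[rest] = raw[rest] if smooth is not None else rng.standard_normal(len(rest))
    nrm = np.linalg.norm(outside)
    if nrm == 0:
        outside[rest] = rng.standard_normal(len(rest))
        nrm = np.linalg.norm(outside)
    outside /= nrm
    return np.sqrt(concentration) * inside + np.sqrt(1 - concentration) * outside


def _item_pattern_set(
    rng, montage, region, n_items, concentration=0.85,
    latent_dim=4, uniqueness=0.3,
) -> np.ndarray:
    """Item spatial patterns with shared low-dimensional geometry.

    Each pattern mixes coordinates in a ``latent_dim``-dimensional shared
    basis with an item-unique component (weight ``uniqueness``), then gets
    its regional weight concentration enforced.  The latent structure
    gives the item set a wide, meaningful (dis)similarity geometry — as
    real stimuli have — while the unique parts keep the patterns linearly
    independent; pure i.i.d. draws would make all pairwise distances
    nearly equal and representational geometry untrackable.
    """
    n = montage.n_channels
    idx = montage.index(region)
    rest = np.setdiff1d(np.arange(n), idx)
    basis = rng.standard_normal((latent_dim, n)) / np.sqrt(n)
    coords = rng.standard_normal((n_items, latent_dim))
    unique = rng.standard_normal((n_items, n)) / np.sqrt(n)
    raw = np.sqrt(1 - uniqueness) * coords @ basis + np.sqrt(uniqueness) * unique
    out = np.empty_like(raw)
    for k in range(n_items):
        inside = np.zeros(n)
        inside[idx] = raw[k, idx]
        inside /= np.linalg.norm(inside)
        outside = np.zeros(n)
        outside[rest] = raw[k, rest]
        outside /= np.linalg.norm(outside)
        out[k] = np.sqrt(concentration) * inside + np.sqrt(1 - concentration) * outside
    return out


def _block_rotation(rng, montage, region) -> np.ndarray:
    """Random orthogonal map preserving the region / non-region split.

    Used to derive each item's quadrature partner pattern: the planted
    oscillation is a *rotating* source (cosine on the primary pattern,
    sine on the rotated one), so the item-specific signal subspace has a
    constant envelope instead of vanishing at carrier zero crossings.
    Being orthogonal within each block, the rotation preserves both the
    regional weight concentration and all pairwise pattern distances.
    """
    n = montage.n_channels
    idx = montage.index(region)
    rest = np.setdiff1d(np.arange(n), idx)
    out = np.zeros((n, n))
    for block in (idx, rest):
        q, r = np.linalg.qr(rng.standard_normal((len(block), len(block))))
        q *= np.sign(np.diag(r))
        out[np.ix_(block, block)] = q
    return out


def _hann_window(times, start, end) -> np.ndarray:
    """Hann envelope on [start, end) ms, zero elsewhere."""
    env = np.zeros_like(times)
    mask = (times >= start) & (times < end)
    x = (times[mask] - start) / (end - start)
    env[mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * x))
    return env


def _oscillation(times, freq_hz, phase, start, end) -> np.ndarray:
    return _hann_window(times, start, end) * np.sin(
        2.0 * np.pi * freq_hz * times / 1000.0 + phase
    )


def one_over_f_noise(rng, n_trials, n_channels, n_times, sfreq, sd, exponent):
    """Gaussian noise with a 1/f^exponent amplitude spectrum, unit-free shape.

    White noise is shaped in the frequency domain, renormalized to standard
    deviation ``sd`` per channel.
    """
    white = rng.standard_normal((n_trials, n_channels, n_times))
    if exponent == 0 or sd == 0:
        return sd * white
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = scale[1]
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n_times, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    return sd * shaped


def spatial_smoothing_matrix(montage: Montage, length_scale: float = 0.03) -> np.ndarray:
    """Row-normalized Gaussian mixing over scalp distance (meters).

    Makes neighboring channels share noise, the minimal stand-in for
    volume conduction.
    """
    p = montage.pos3d
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    w = np.exp(-d2 / (2.0 * length_scale**2))
    return w / w.sum(axis=1, keepdims=True)


def _suppression_score(config: SimulationConfig, rng) -> float:
    """Participant-level true suppression score around the population factor.

    Jitter vanishes at the endpoints so that factor 0 / 1 are exact."""
    f = config.suppression_factor
    sd = 0.6 * f * (1.0 - f)
    return float(np.clip(f + sd * rng.standard_normal(), 0.0, 1.0))


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def _item_layout(config: SimulationConfig):
    """Global item ids grouped as Think, NoThink, PerceptualBaseline."""
    n_t, n_pb = config.n_items_tnt, config.n_items_pb
    ids = np.arange(2 * n_t + n_pb)
    conds = (["Think"] * n_t) + (["NoThink"] * n_t) + (["PerceptualBaseline"] * n_pb)
    return ids, conds


def simulate_participant(config: SimulationConfig, participant_id: int):
    """Simulate one participant's epochs and the planted ground truth.

    Returns ``(EpochSet, GroundTruth)``; bit-identical for identical
    ``(config, participant_id)``.
    """
    rng = np.random.default_rng([config.seed, 1, participant_id])
    montage = Montage.standard_61()
    times = config.times
    n_times = len(times)
    n_ch = montage.n_channels

    item_ids, item_conds = _item_layout(config)
    n_items = len(item_ids)

    smooth = spatial_smoothing_matrix(montage)
    cue_patterns = _item_pattern_set(rng, montage, OCCIPITAL, n_items)
    scene_patterns = _item_pattern_set(
        rng, montage, SCENE_REGION, n_items, concentration=0.8
    )
    cue_quad = cue_patterns @ _block_rotation(rng, montage, OCCIPITAL).T
    scene_quad = scene_patterns @ _block_rotation(rng, montage, SCENE_REGION).T
    cue_phase = rng.uniform(0, 2 * np.pi, n_items)
    scene_phase = rng.uniform(0, 2 * np.pi, n_items)
    cond_theta_phase = rng.uniform(0, 2 * np.pi)
    suppression = _suppression_score(config, rng)

    fc_vec = np.zeros(n_ch)
    fc_idx = montage.index(FRONTOCENTRAL)
    fc_vec[fc_idx] = 1.0 / np.sqrt(len(fc_idx))
    alpha_vec = _posterior_profile(montage)

    # trial table: items nested in conditions, n_reps each
    rows = []
    for gid, cond in zip(item_ids, item_conds):
        for _ in range(config.n_reps):
            rows.append((cond, int(gid), participant_id))
    table = pd.DataFrame(rows, columns=["condition", "item_id", "participant_id"])
    n_trials = len(table)

    data = one_over_f_noise(
        rng, n_trials, n_ch, n_times, config.sfreq,
        config.noise_sd, config.noise_exponent,
    )
    data = np.einsum("cd,tdn->tcn", smooth, data)

    scene_gain = {
        "Think": 1.0,
        "NoThink": 1.0 - suppression,
        "PerceptualBaseline": 0.0,
    }
    cond_theta_env = config.cond_theta_amp * _oscillation(
        times, _THETA_HZ, cond_theta_phase, *_COND_THETA_WINDOW
    )
    alpha_env = _hann_window(times, *_SCENE_WINDOW)

    # Per-item signal templates (identical across repetitions).  Each item
    # contributes a slow evoked deflection (the envelope itself, weight
    # _DC_MIX) plus a band-limited oscillation in quadrature (a rotating
    # source), so item information survives both time-window averaging
    # (searchlight, ERP measures) and narrowband analyses.
    cue_env = _hann_window(times, *_CUE_WINDOW)
    arg_cue = 2 * np.pi * _THETA_HZ * times / 1000.0
    scene_env = _hann_window(times, *_SCENE_WINDOW)
    arg_scene = 2 * np.pi * _ALPHA_HZ * times / 1000.0
    osc, dc = np.sqrt(1.0 - _DC_MIX), np.sqrt(_DC_MIX)
    cue_sig, scene_sig = [], []
    for k in range(n_items):
        cue_sig.append(
            config.cue_pattern_amp
            * (
                np.outer(cue_patterns[k],
                         cue_env * (dc + osc * np.cos(arg_cue + cue_phase[k])))
                + np.outer(cue_quad[k], osc * cue_env * np.sin(arg_cue + cue_phase[k]))
            )
        )
        scene_sig.append(
            config.scene_pattern_amp
            * (
                np.outer(scene_patterns[k],
                         scene_env * (dc + osc * np.cos(arg_scene + scene_phase[k])))
                + np.outer(scene_quad[k],
                           osc * scene_env * np.sin(arg_scene + scene_phase[k]))
            )
        )

    item_row = {int(g): k for k, g in enumerate(item_ids)}
    for t in range(n_trials):
        cond = table.at[t, "condition"]
        k = item_row[int(table.at[t, "item_id"])]
        trial = data[t]
        trial += cue_sig[k]
        g = scene_gain[cond]
        if g:
            trial += g * scene_sig[k]
        if cond == "NoThink":
            trial += np.outer(fc_vec, cond_theta_env)
        # ongoing (non-item-specific) posterior alpha, random phase per trial
        amp = config.alpha_background_amp
        if cond == "NoThink":
            amp *= 1.0 - config.alpha_mod
        if amp:
            phase = rng.uniform(0, 2 * np.pi)
            trial += amp * np.outer(
                alpha_vec,
                alpha_env * np.sin(2 * np.pi * _ALPHA_HZ * times / 1000.0 + phase),
            )

    epochs = EpochSet(
        data=data,
        times=times,
        sfreq=config.sfreq,
        channel_names=montage.channel_names,
        montage=montage,
        trial_table=table,
    )
    truth = GroundTruth(
        participant_id=participant_id,
        channel_names=montage.channel_names,
        item_ids=item_ids,
        item_condition=list(item_conds),
        cue_patterns=cue_patterns,
        scene_patterns=scene_patterns,
        suppression=suppression,
    )
    return epochs, truth


def _posterior_profile(montage: Montage) -> np.ndarray:
    """Fixed smooth posterior weighting for the ongoing alpha rhythm."""
    y = montage.pos3d[:, 1] - montage.sphere_center()[1]
    w = np.exp(-((y - y.min()) / (0.6 * (y.max() - y.min()))) ** 2)
    return w / np.linalg.norm(w)


def simulate_dataset(config: SimulationConfig):
    """All participants: returns (list of EpochSet, list of GroundTruth)."""
    pairs = [
        simulate_participant(config, pid) for pid in range(config.n_participants)
    ]
    return [p[0] for p in pairs], [p[1] for p in pairs]


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(truths, config: SimulationConfig) -> pd.DataFrame:
    """Cued-recall scores (Identification/Gist proportions, Detail counts).

    The Baseline-minus-No-Think Detail difference has population effect
    size ``forgetting_dz`` and is monotone (in expectation) in each
    participant's true suppression score: the deficit is a linear function
    ``a + b * suppression`` plus noise, with ``(a, b)`` solved so that the
    standardized mean difference hits the target.
    """
    if len(truths) < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng([config.seed, 2])
    s = np.array([t.suppression for t in truths])
    sd_tot, coupling = 1.2, 0.6  # detail-count units; corr(suppression, deficit)
    s_sd = s.std()
    if s_sd > 0:
        b = coupling * sd_tot / s_sd
        noise_sd = sd_tot * np.sqrt(1.0 - coupling**2)
    else:
        b, noise_sd = 0.0, sd_tot
    a = config.forgetting_dz * sd_tot - b * s.mean()

    rows = []
    for truth, s_p in zip(truths, s):
        bl_detail = max(0.0, 6.0 + 1.5 * rng.standard_normal())
        deficit = a + b * s_p + noise_sd * rng.standard_normal()
        nt_detail = max(0.0, bl_detail - deficit)
        th_detail = max(0.0, bl_detail + 0.5 + 0.8 * rng.standard_normal())
        bl_ident = np.clip(0.75 + 0.10 * rng.standard_normal(), 0, 1)
        scores = {
            "Baseline": (bl_ident, bl_detail),
            "NoThink": (np.clip(bl_ident - 0.04 * deficit, 0, 1), nt_detail),
            "Think": (np.clip(bl_ident + 0.03, 0, 1), th_detail),
        }
        for cond, (ident, detail) in scores.items():
            gist = np.clip(0.08 * detail + 0.08 * rng.standard_normal(), 0, 1)
            rows.append(
                {
                    "participant": truth.participant_id,
                    "condition": cond,
                    "identification": float(ident),
                    "gist": float(gist),
                    "detail": float(detail),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subjective ratings
# ---------------------------------------------------------------------------

def simulate_subjective_ratings(
    truth: GroundTruth, config: SimulationConfig, condition: str = "Think"
):
    """Per-rater item x item similarity matrices on the 1-9 scale.

    Conceptual ratings are a noisy monotone transform of *scene*-pattern
    distances, perceptual ratings of *cue*-pattern distances (9 = extremely
    similar, matching the rating-scale anchors).  Returns
    ``(perceptual_stack, conceptual_stack)`` of shape (n_raters, n, n);
    diagonals are NaN and stacks are symmetric per rater.
    """
    if config.n_raters < 2:
        raise ValueError("need at least 2 raters")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng([config.seed, 3, truth.participant_id])
    sel = [i for i, c in enumerate(truth.item_condition) if c == condition]
    stacks = []
    for patterns in (truth.cue_patterns[sel], truth.scene_patterns[sel]):
        n = len(patterns)
        d = np.linalg.norm(patterns[:, None, :] - patterns[None, :, :], axis=-1)
        off = ~np.eye(n, dtype=bool)
        lo, hi = d[off].min(), d[off].max()
        d_norm = (d - lo) / (hi - lo) if hi > lo else np.zeros_like(d)
        target = 1.0 + 8.0 * (1.0 - d_norm)  # similarity: near items rate high
        stack = np.empty((config.n_raters, n, n))
        for r in range(config.n_raters):
            noise = rng.standard_normal((n, n)) * config.rating_noise_sd
            noise = (noise + noise.T) / np.sqrt(2.0)
            mat = np.clip(target + noise, 1.0, 9.0)
            np.fill_diagonal(mat, np.nan)
            stack[r] = mat
        stacks.append(stack)
    perceptual, conceptual = stacks
    return perceptual, conceptual


def ratings_to_frame(stack: np.ndarray) -> pd.DataFrame:
    """Long-format (rater, item_i, item_j, rating) for the upper triangle."""
    n_raters, n, _ = stack.shape
    rows = []
    for r in range(n_raters):
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((r, i, j, stack[r, i, j]))
    return pd.DataFrame(rows, columns=["rater", "item_i", "item_j", "rating"])
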