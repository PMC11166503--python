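"""Simulate one Think/No-Think participant and inspect what was planted.

The generator emulates the task design (12 Think + 12 No-Think items at
10 repetitions, 6 Perceptual Baseline items, 61 channels, 250 Hz) with an
early occipital item-specific cue pattern, a late distributed scene
pattern present only under retrieval, and 1/f background noise.
"""

import numpy as np

import tntdecode as td

cfg = td.SimulationConfig(seed=1)
epochs, truth = td.simulate_participant(cfg, participant_id=0)

print("trials x channels x samples:", epochs.data.shape)
print(epochs.trial_table.groupby("condition").size())
print(f"epoch spans {epochs.times[0]:.0f}..{epochs.times[-1]:.0f} ms at {epochs.sfreq:.0f} Hz")

occ = epochs.montage.index(td.synth.OCCIPITAL)
conc = (truth.cue_patterns[:, occ] ** 2).sum(axis=1)
print(f"cue-pattern occipital weight: {conc.mean():.2f} (>= 0.70 by construction)")
print(f"participant's true suppression score: {truth.suppression:.2f}")
print("RMS amplitude (uV):", np.sqrt((epochs.data**2).mean()).round(2))
# The suppression score scales how strongly the late scene pattern is
# removed from No-Think trials; 1.0 means full abolition.
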